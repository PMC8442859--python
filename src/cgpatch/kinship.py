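"""Pairwise genomic relatedness estimation and kinship classification.

Two complementary estimators are implemented on biallelic dosage data:

* a method-of-moments IBD decomposition given reference allele frequencies,
  yielding the probabilities ``Z0, Z1, Z2`` that a pair shares 0, 1 or 2
  alleles identical by descent and the overall IBD proportion
  ``PI_HAT = Z2 + Z1/2`` (the classic PLINK-style estimator); and
* the allele-frequency-free robust kinship coefficient
  ``phi = (N_AaAa - 2 N_AAaa) / (N_Aa_i + N_Aa_j)`` built from shared
  heterozygote and opposite-homozygote counts (the KING-robust estimator).

Pairs are then assigned to relatedness degrees by the powers-of-two phi
thresholds of Manichaikul et al.'s scheme, with ``Z0 < 0.1`` separating
parent-offspring from full siblings within the first degree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import DataError
from .genotypes import GenotypeMatrix
from .synth import FULL_SIB, HALF_SIB, PARENT_OFFSPRING, UNRELATED

DUPLICATE = "duplicate"
THIRD_DEGREE = "third-degree"
FOURTH_DEGREE = "fourth-degree"
UNCLASSIFIED = "unclassified"

# half-open phi boundaries at 2^(-3/2), 2^(-5/2), ... (Manichaikul-style degrees)
_PHI_BOUNDS = [2 ** (-(2 * d + 1) / 2) for d in range(1, 6)]  # d = 1..5


@dataclass
class IbsCounts:
    """Identity-by-state summary of one pair over jointly non-missing loci."""

    ibs0: int
    ibs1: int
    ibs2: int
    n_het_het: int       # both heterozygous (N_AaAa)
    n_opp_hom: int       # opposite homozygotes (N_AAaa); == ibs0
    n_het_i: int
    n_het_j: int
    n_loci: int


@dataclass
class PairKinship:
    """Estimated relatedness of one pair."""

    z0: float
    z1: float
    z2: float
    pi_hat: float
    phi: float
    n_loci: int
    category: str
    reliable: bool = True


def _joint_mask(gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    if gi.shape != gj.shape:
        raise DataError("genotype vectors have different lengths")
    return (gi >= 0) & (gj >= 0)


def ibs_counts(gi: np.ndarray, gj: np.ndarray) -> IbsCounts:
    """IBS class and heterozygosity counts for one pair (missing excluded)."""
    mask = _joint_mask(gi, gj)
    a, b = np.asarray(gi)[mask], np.asarray(gj)[mask]
    diff = np.abs(a - b)
    ibs0 = int((diff == 2).sum())
    ibs1 = int((diff == 1).sum())
    ibs2 = int((diff == 0).sum())
    return IbsCounts(
        ibs0=ibs0,
        ibs1=ibs1,
        ibs2=ibs2,
        n_het_het=int(((a == 1) & (b == 1)).sum()),
        n_opp_hom=ibs0,
        n_het_i=int((a == 1).sum()),
        n_het_j=int((b == 1).sum()),
        n_loci=int(mask.sum()),
    )


def _ibs_given_ibd(p: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-locus P(IBS class | IBD state) under HWE at frequency p."""
    q = 1.0 - p
    p0_i0 = 2 * p**2 * q**2
    p1_i0 = 4 * p**3 * q + 4 * p * q**3
    p2_i0 = p**4 + q**4 + 4 * p**2 * q**2
    p1_i1 = 2 * p**2 * q + 2 * p * q**2
    p2_i1 = p**3 + q**3 + p**2 * q + p * q**2
    return p0_i0, p1_i0, p2_i0, p1_i1, p2_i1


def ibd_moments(
    gi: np.ndarray,
    gj: np.ndarray,
    allele_freqs: np.ndarray,
    min_loci: int = 100,
    maf_min: float = 0.01,
) -> tuple[float, float, float, float, int, bool]:
    """Method-of-moments (Z0, Z1, Z2, PI_HAT) given reference allele frequencies.

    Allele frequencies should come from the pooled analysis sample (within a
    family cohort the cohort's own frequencies are badly biased). Loci with
    pooled minor-allele frequency below ``maf_min`` are excluded. Expected IBS
    class counts are linear in (Z0, Z1, Z2); the triangular system is solved
    exactly, then the estimate is clamped to the probability simplex and
    renormalized. Returns ``(z0, z1, z2, pi_hat, n_loci, reliable)`` where
    ``reliable`` is False when fewer than ``min_loci`` jointly non-missing loci
    survive the filters.
    """
    allele_freqs = np.asarray(allele_freqs, dtype=float)
    informative = (
        np.isfinite(allele_freqs)
        & (np.minimum(allele_freqs, 1 - allele_freqs) >= maf_min)
    )
    mask = _joint_mask(gi, gj) & informative
    n_loci = int(mask.sum())
    if n_loci == 0:
        return np.nan, np.nan, np.nan, np.nan, 0, False
    a, b = np.asarray(gi)[mask], np.asarray(gj)[mask]
    p = allele_freqs[mask]
    diff = np.abs(a - b)
    n0, n1, n2 = float((diff == 2).sum()), float((diff == 1).sum()), float((diff == 0).sum())
    p0_i0, p1_i0, p2_i0, p1_i1, p2_i1 = _ibs_given_ibd(p)
    e0_i0, e1_i0, e2_i0 = p0_i0.sum(), p1_i0.sum(), p2_i0.sum()
    e1_i1, e2_i1 = p1_i1.sum(), p2_i1.sum()

    z0 = n0 / e0_i0 if e0_i0 > 0 else 0.0
    z1 = (n1 - z0 * e1_i0) / e1_i1 if e1_i1 > 0 else 0.0
    z2 = (n2 - z0 * e2_i0 - z1 * e2_i1) / n_loci

    z = np.clip([z0, z1, z2], 0.0, 1.0)
    total = z.sum()
    z = z / total if total > 0 else np.array([0.0, 1.0, 0.0])  # degenerate: lean on Z1
    pi_hat = float(z[2] + z[1] / 2)
    return float(z[0]), float(z[1]), float(z[2]), pi_hat, n_loci, n_loci >= min_loci


def robust_kinship(gi: np.ndarray, gj: np.ndarray, min_loci: int = 100) -> tuple[float, int, bool]:
    """Robust within-pair kinship coefficient phi (no allele frequencies needed).

    ``phi = (N_AaAa - 2 N_AAaa) / (N_Aa_i + N_Aa_j)`` over jointly non-missing
    loci. Returns ``(phi, n_loci, reliable)``; ``phi`` is nan (and the estimate
    flagged) when neither individual carries a heterozygous locus.
    """
    c = ibs_counts(gi, gj)
    denom = c.n_het_i + c.n_het_j
    if denom == 0:
        return np.nan, c.n_loci, False
    phi = (c.n_het_het - 2.0 * c.n_opp_hom) / denom
    return float(phi), c.n_loci, c.n_loci >= min_loci


def classify_kinship(z0: float, z1: float, z2: float, phi: float) -> str:
    """Relatedness category from phi degree bounds, with Z0 splitting the first
    degree into parent-offspring (Z0 < 0.1) and full siblings."""
    if not (np.isfinite(phi) and np.isfinite(z0)):
        return UNCLASSIFIED
    if phi > _PHI_BOUNDS[0]:
        return DUPLICATE
    if phi > _PHI_BOUNDS[1]:
        return PARENT_OFFSPRING if z0 < 0.1 else FULL_SIB
    if phi > _PHI_BOUNDS[2]:
        return HALF_SIB  # second degree, reported as the study's half-sib class
    if phi > _PHI_BOUNDS[3]:
        return THIRD_DEGREE
    if phi > _PHI_BOUNDS[4]:
        return FOURTH_DEGREE
    return UNRELATED


def estimate_pair(
    gi: np.ndarray,
    gj: np.ndarray,
    allele_freqs: np.ndarray,
    min_loci: int = 100,
    maf_min: float = 0.01,
) -> PairKinship:
    """Full relatedness estimate (moments + robust phi + category) for one pair."""
    z0, z1, z2, pi_hat, n_ibd, ok_ibd = ibd_moments(gi, gj, allele_freqs, min_loci, maf_min)
    phi, n_phi, ok_phi = robust_kinship(gi, gj, min_loci)
    reliable = ok_ibd and ok_phi
    category = classify_kinship(z0, z1, z2, phi) if reliable else UNCLASSIFIED
    return PairKinship(
        z0=z0, z1=z1, z2=z2, pi_hat=pi_hat, phi=phi,
        n_loci=min(n_ibd, n_phi), category=category, reliable=reliable,
    )


def estimate_cohort_pairs(
    gm: GenotypeMatrix, cohort: str, min_loci: int = 100, maf_min: float = 0.01
) -> pd.DataFrame:
    """Relatedness estimates for all unordered pairs within one cohort.

    Allele frequencies are taken from the pooled analysis sample (all cohorts).
    """
    idx = gm.cohort_indices(cohort)
    if idx.size < 2:
        raise DataError(f"cohort {cohort!r} has fewer than 2 members")
    freqs = gm.allele_frequencies()
    rows = []
    for i, j in combinations(idx.tolist(), 2):
        pk = estimate_pair(gm.dosages[i], gm.dosages[j], freqs, min_loci, maf_min)
        rows.append(
            {
                "sample_i": gm.samples[i],
                "sample_j": gm.samples[j],
                "cohort": cohort,
                "n_loci": pk.n_loci,
                "Z0": pk.z0, "Z1": pk.z1, "Z2": pk.z2,
                "PI_HAT": pk.pi_hat, "phi": pk.phi,
                "category": pk.category,
            }
        )
    return pd.DataFrame(rows)


#: mapping of fine categories onto the study's three reported classes
_SUMMARY_CLASS = {
    PARENT_OFFSPRING: FULL_SIB,  # first degree; cannot occur within a single-cohort sample of one generation
    FULL_SIB: FULL_SIB,
    HALF_SIB: HALF_SIB,
    THIRD_DEGREE: UNRELATED,
    FOURTH_DEGREE: UNRELATED,
    UNRELATED: UNRELATED,
}


def cohort_kinship_summary(
    gm: GenotypeMatrix, cohort: str, min_loci: int = 100, maf_min: float = 0.01
) -> dict[str, float]:
    """Proportions of unrelated / half-sib / full-sib pairs within a cohort.

    Third degree and beyond count as unrelated for this three-class summary;
    duplicate pairs are excluded with a warning.
    """
    pairs = estimate_cohort_pairs(gm, cohort, min_loci, maf_min)
    cats = pairs["category"]
    n_dup = int((cats == DUPLICATE).sum())
    if n_dup:
        warnings.warn(f"cohort {cohort!r}: excluding {n_dup} duplicate/MZ pair(s) from summary")
    kept = cats[(cats != DUPLICATE) & (cats != UNCLASSIFIED)]
    if len(kept) == 0:
        raise DataError(f"cohort {cohort!r}: no classifiable pairs")
    mapped = kept.map(_SUMMARY_CLASS)
    out = {UNRELATED: 0.0, HALF_SIB: 0.0, FULL_SIB: 0.0}
    out.update((mapped.value_counts() / len(mapped)).to_dict())
    return out
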