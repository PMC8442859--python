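"""Cohort-level diversity and differentiation statistics.

Nucleotide diversity (pi), composite linkage-disequilibrium r^2, pairwise
Weir-Cockerham F_st with bootstrap significance, and empirical folded
site-frequency spectra, all on cohort-labelled dosage matrices.

pi is averaged over the fixed pooled SNP panel (per SNP, not per base pair),
so cohorts genotyped on the same panel are directly comparable — the relevant
quantity in a SNP-only dataset is relative diversity across cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import DataError
from .genotypes import GenotypeMatrix
from .spectra import SpectrumCounts


def _cohort_freq_stats(dos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (allele count n, alt frequency p, het frequency h) with
    missing genotypes reducing n locally."""
    called = dos >= 0
    n_ind = called.sum(axis=0)
    n = 2 * n_ind
    alt = np.where(called, dos, 0).sum(axis=0)
    het = ((dos == 1) & called).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        h = np.where(n_ind > 0, het / np.maximum(n_ind, 1), np.nan)
    return n, p, h


def nucleotide_diversity(gm: GenotypeMatrix, cohort: str) -> float:
    """Mean per-SNP nucleotide diversity of a cohort over the pooled panel.

    Per SNP segregating in the pooled dataset, with cohort allele count n_s and
    frequency p_s: ``pi_s = n_s/(n_s - 1) * 2 p_s (1 - p_s)`` (the unbiased
    per-site heterozygosity); pi is the mean over those SNPs. Sites monomorphic
    within the cohort contribute zero, keeping cohorts comparable on the fixed
    panel.
    """
    idx = gm.cohort_indices(cohort)
    if idx.size < 2:
        raise DataError(f"cohort {cohort!r} has fewer than 2 individuals")
    pooled = gm.allele_frequencies()
    panel = np.isfinite(pooled) & (pooled > 0) & (pooled < 1)
    if not panel.any():
        raise DataError("no segregating sites in the pooled dataset")
    n, p, _ = _cohort_freq_stats(gm.dosages[idx][:, panel])
    ok = n >= 2
    pi = np.zeros(int(panel.sum()))
    pi[ok] = n[ok] / (n[ok] - 1) * 2.0 * p[ok] * (1.0 - p[ok])
    return float(pi.mean())


def ld_r2(gm: GenotypeMatrix, cohort: str, max_pairs: int = 50000, seed: int = 0) -> np.ndarray:
    """Squared dosage correlation (composite LD) over locus pairs in a cohort.

    All pairs of loci segregating within the cohort are evaluated, or a seeded
    uniform subsample of ``max_pairs`` pairs when there are more. Pairs with
    zero variance (after pairwise missing-data removal) are skipped.
    """
    dos = gm.cohort_dosages(cohort).astype(float)
    dos[dos < 0] = np.nan
    with np.errstate(invalid="ignore"):
        var = np.nanvar(dos, axis=0)
    seg = np.flatnonzero(var > 0)
    if seg.size < 2:
        raise DataError(f"cohort {cohort!r} has fewer than 2 segregating loci")
    n_pairs_total = seg.size * (seg.size - 1) // 2
    rng = np.random.default_rng(seed)
    if n_pairs_total <= max_pairs:
        pairs = [(i, j) for a, i in enumerate(seg) for j in seg[a + 1 :]]
    else:
        # sample unordered pairs uniformly (with negligible collision mass)
        ii = rng.integers(seg.size, size=2 * max_pairs)
        jj = rng.integers(seg.size, size=2 * max_pairs)
        keep = ii < jj
        pairs = list(zip(seg[ii[keep][:max_pairs]], seg[jj[keep][:max_pairs]]))
    out = []
    for i, j in pairs:
        x, y = dos[:, i], dos[:, j]
        m = np.isfinite(x) & np.isfinite(y)
        if m.sum() < 3:
            continue
        xm, ym = x[m] - x[m].mean(), y[m] - y[m].mean()
        denom = (xm**2).sum() * (ym**2).sum()
        if denom == 0:
            continue
        out.append((xm * ym).sum() ** 2 / denom)
    return np.asarray(out)


@dataclass
class FstResult:
    """Pairwise Weir-Cockerham F_st with bootstrap significance."""

    cohorts: list[str]
    fst: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray  # after Bonferroni over the number of pairs
    n_bootstrap: int

    def pair(self, a: str, b: str) -> tuple[float, float, bool]:
        i, j = self.cohorts.index(a), self.cohorts.index(b)
        return float(self.fst[i, j]), float(self.p_values[i, j]), bool(self.significant[i, j])


def _wc_components(dos_a: np.ndarray, dos_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham (a, a+b+c) variance components for two cohorts."""
    n1, p1, h1 = _cohort_freq_stats(dos_a)
    n2, p2, h2 = _cohort_freq_stats(dos_b)
    ok = (n1 >= 2) & (n2 >= 2)
    if not ok.any():
        raise DataError("no locus is genotyped in both cohorts")
    n1, p1, h1 = n1[ok] / 2.0, p1[ok], h1[ok]  # W&C n_i counts individuals
    n2, p2, h2 = n2[ok] / 2.0, p2[ok], h2[ok]
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0))
    b = nbar / (nbar - 1.0) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, a + b + c


def pairwise_fst(
    gm: GenotypeMatrix,
    cohorts: list[str] | None = None,
    n_boot: int = 10000,
    seed: int = 0,
) -> FstResult:
    """Pairwise multilocus Weir-Cockerham theta with bootstrap p-values.

    Theta per pair is the ratio of summed variance components over loci
    (negative multilocus estimates are reported as computed). The one-sided
    p-value is the proportion of bootstrap replicates (loci resampled with
    replacement) with F_st <= 0; significance flags are Bonferroni-corrected
    over the number of cohort pairs.
    """
    cohorts = cohorts or gm.cohort_names()
    if len(cohorts) < 2:
        raise DataError("need at least two cohorts")
    k = len(cohorts)
    fst = np.zeros((k, k))
    pvals = np.zeros((k, k))
    rng = np.random.default_rng(seed)
    n_pairs = k * (k - 1) // 2
    for i, j in combinations(range(k), 2):
        dos_a = gm.cohort_dosages(cohorts[i])
        dos_b = gm.cohort_dosages(cohorts[j])
        if dos_a.shape[0] < 2 or dos_b.shape[0] < 2:
            raise DataError("each cohort needs >= 2 individuals for F_st")
        a, denom = _wc_components(dos_a, dos_b)
        theta = a.sum() / denom.sum()
        fst[i, j] = fst[j, i] = theta
        L = a.size
        n_le = 0
        chunk = max(1, min(n_boot, 8_000_000 // max(L, 1)))
        done = 0
        while done < n_boot:
            m = min(chunk, n_boot - done)
            idx = rng.integers(L, size=(m, L))
            boot = a[idx].sum(axis=1) / denom[idx].sum(axis=1)
            n_le += int((boot <= 0).sum())
            done += m
        pvals[i, j] = pvals[j, i] = n_le / n_boot
    sig = (pvals * n_pairs < 0.05) & ~np.eye(k, dtype=bool)
    return FstResult(cohorts=list(cohorts), fst=fst, p_values=pvals, significant=sig, n_bootstrap=n_boot)


def folded_sfs(gm: GenotypeMatrix, cohort: str) -> SpectrumCounts:
    """Folded minor-allele site-frequency spectrum of one cohort.

    Sites with any missing genotype within the cohort are excluded; each site
    segregating in the cohort increments the class of its minor-allele count
    ``j`` in 1..floor(n/2), with ``n = 2 x cohort size`` sequences.
    """
    dos = gm.cohort_dosages(cohort)
    n = 2 * dos.shape[0]
    if n < 2:
        raise DataError(f"cohort {cohort!r} too small for a spectrum")
    complete = (dos >= 0).all(axis=0)
    alt = dos[:, complete].sum(axis=0)
    seg = (alt > 0) & (alt < n)
    if not seg.any():
        raise DataError(f"cohort {cohort!r} has no fully genotyped segregating sites")
    minor = np.minimum(alt[seg], n - alt[seg])
    y = np.bincount(minor, minlength=n // 2 + 1)[1 : n // 2 + 1]
    return SpectrumCounts(n=n, Y=y.astype(float))
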