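"""Synthetic genotype datasets with known pedigree structure.

This module emulates the structure of a RAD-seq SNP panel from a hierarchically
sampled broadcast spawner: many cohorts of ~10 diploid individuals genotyped at
thousands of biallelic SNPs, where at most a few cohorts descend from a single
sweepstake reproduction event (one mother, a handful of fathers — so entirely
full- and half-siblings with depressed diversity) and the remaining cohorts are
random draws from a common founder gene pool.

Founder genotypes are drawn under Hardy-Weinberg equilibrium from a per-locus
allele-frequency pool; offspring genotypes follow Mendelian transmission with
free recombination (loci unlinked). The true pedigree kinship category of every
within-cohort pair is recorded alongside the genotypes, so downstream
relatedness estimators can be benchmarked without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError
from .genotypes import MISSING, GenotypeMatrix
from .seeding import stage_rng

#: pedigree kinship categories used throughout the package
UNRELATED = "unrelated"
HALF_SIB = "half-sib"
FULL_SIB = "full-sib"
PARENT_OFFSPRING = "parent-offspring"


@dataclass
class FounderPool:
    """Per-locus alternative-allele frequencies of an idealized gene pool."""

    frequencies: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.ndim != 1 or self.frequencies.size < 1:
            raise ConfigurationError("founder pool needs >= 1 locus")
        if np.any(self.frequencies <= 0.0) or np.any(self.frequencies >= 1.0):
            raise ConfigurationError("founder frequencies must lie strictly in (0,1)")

    @property
    def n_loci(self) -> int:
        return self.frequencies.size


@dataclass
class PedigreeSpec:
    """Pedigree layout of one cohort.

    ``families`` lists ``(mother_id, father_id, n_offspring)`` triples;
    ``unrelated_count`` founders are added as cohort members with no recorded
    parents. Parent ids are arbitrary hashable labels; sharing a label across
    families is what creates half-siblings.
    """

    cohort: str
    families: list[tuple[str, str, int]] = field(default_factory=list)
    unrelated_count: int = 0

    def __post_init__(self) -> None:
        if self.unrelated_count < 0:
            raise ConfigurationError("unrelated_count must be non-negative")
        for fam in self.families:
            if len(fam) != 3 or fam[2] < 0:
                raise ConfigurationError(f"malformed family spec: {fam!r}")
        if self.total_individuals() == 0:
            raise ConfigurationError("cohort spec describes zero individuals")

    def total_individuals(self) -> int:
        return self.unrelated_count + sum(n for _, _, n in self.families)

    def parent_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for m, f, _ in self.families:
            seen.setdefault(m)
            seen.setdefault(f)
        return list(seen)


@dataclass
class SyntheticDataset:
    """Genotypes plus the ground-truth pedigree kinship of within-cohort pairs."""

    genotypes: GenotypeMatrix
    truth_kinship: dict[frozenset, str]
    pool: FounderPool | None = None

    def truth_category(self, a: str, b: str) -> str:
        return self.truth_kinship[frozenset((a, b))]


def draw_founder_frequencies(L, dist="uniform", params=(0.05, 0.95), seed=0) -> FounderPool:
    """Draw a founder allele-frequency pool.

    Parameters
    ----------
    L
        Number of biallelic loci (>= 1).
    dist
        ``"uniform"`` with params ``(a, b)``; ``"beta"`` with shape params
        ``(s1, s2)``; or ``"neutral"`` with params ``(eps,)`` giving the
        standing neutral frequency spectrum, density proportional to 1/p on
        ``(eps, 1 - eps)`` — the distribution under which a sample's folded
        site-frequency spectrum matches the Kingman expectation.
    seed
        Integer seed; identical calls reproduce identical pools.

    Monomorphic draws are impossible by construction (all supported
    distributions are truncated away from 0 and 1).
    """
    if L < 1:
        raise ConfigurationError("L must be >= 1")
    rng = stage_rng(seed, f"founder-frequencies:{dist}")
    if dist == "uniform":
        a, b = params
        if not (0.0 < a <= b < 1.0):
            raise ConfigurationError(f"uniform bounds must satisfy 0 < a <= b < 1, got {params}")
        freqs = rng.uniform(a, b, size=L) if a < b else np.full(L, a)
    elif dist == "beta":
        s1, s2 = params
        if s1 <= 0 or s2 <= 0:
            raise ConfigurationError(f"beta shapes must be positive, got {params}")
        freqs = rng.beta(s1, s2, size=L)
        # redraw draws that underflow to the boundary in float
        bad = (freqs <= 0.0) | (freqs >= 1.0)
        while bad.any():
            freqs[bad] = rng.beta(s1, s2, size=int(bad.sum()))
            bad = (freqs <= 0.0) | (freqs >= 1.0)
    elif dist == "neutral":
        (eps,) = params if isinstance(params, (tuple, list)) else (params,)
        if not 0.0 < eps < 0.5:
            raise ConfigurationError("neutral truncation eps must be in (0, 0.5)")
        lo, hi = eps, 1.0 - eps
        u = rng.random(L)
        freqs = lo * (hi / lo) ** u  # inverse CDF of density ∝ 1/p on (lo, hi)
    else:
        raise ConfigurationError(f"unknown frequency distribution: {dist!r}")
    return FounderPool(frequencies=freqs, seed=int(seed))


def sample_founders(pool: FounderPool, n: int, seed: int = 0, prefix: str = "F") -> np.ndarray:
    """Draw ``n`` founder dosage vectors under Hardy-Weinberg equilibrium.

    Each genotype at a locus with alt frequency ``p`` is Binomial(2, p);
    no missing data. Returns an ``(n, L)`` int8 dosage array.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = stage_rng(seed, "sample-founders")
    return rng.binomial(2, pool.frequencies, size=(n, pool.n_loci)).astype(np.int8)


def breed_offspring(mother: np.ndarray, father: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mendelian transmission with free recombination.

    One allele is drawn uniformly from each parent's two alleles, independently
    across loci. A locus missing in a parent transmits missing.
    """
    mother = np.asarray(mother, dtype=np.int8)
    father = np.asarray(father, dtype=np.int8)
    if mother.shape != father.shape:
        raise DataError("parent genotype lengths differ")
    am = (rng.random(mother.shape) < mother / 2.0).astype(np.int8)
    af = (rng.random(father.shape) < father / 2.0).astype(np.int8)
    child = am + af
    child[(mother == MISSING) | (father == MISSING)] = MISSING
    return child


def _pairwise_truth(parents: dict[str, tuple[str | None, str | None]]) -> dict[frozenset, str]:
    """Truth kinship for every unordered pair given per-individual parent labels."""
    truth: dict[frozenset, str] = {}
    names = list(parents)
    for i, a in enumerate(names):
        ma, fa = parents[a]
        for b in names[i + 1 :]:
            mb, fb = parents[b]
            if ma is None or mb is None:  # at least one founder in the pair
                cat = UNRELATED
            else:
                shared = int(ma == mb) + int(fa == fb)
                cat = (UNRELATED, HALF_SIB, FULL_SIB)[shared]
            truth[frozenset((a, b))] = cat
    return truth


def make_family_cohort(spec: PedigreeSpec, pool: FounderPool, seed: int = 0) -> SyntheticDataset:
    """Build one cohort from a pedigree spec over a founder pool.

    Named parents are drawn as HWE founders; offspring are bred from them by
    Mendelian transmission; ``unrelated_count`` extra founders join the cohort
    directly. Truth categories come from parent-label overlap: both parents
    shared = full-sib, exactly one = half-sib, otherwise unrelated.
    """
    parent_names = spec.parent_ids()
    n_parents = len(parent_names)
    if n_parents == 0 and spec.unrelated_count == 0:
        raise ConfigurationError("empty pedigree spec")
    rng = stage_rng(seed, f"family-cohort:{spec.cohort}")
    n_founders = n_parents + spec.unrelated_count
    founder_g = sample_founders(pool, max(n_founders, 1), seed=int(rng.integers(2**31)))
    parent_g = {name: founder_g[i] for i, name in enumerate(parent_names)}

    rows: list[np.ndarray] = []
    names: list[str] = []
    parent_of: dict[str, tuple[str | None, str | None]] = {}
    for mother_id, father_id, n_off in spec.families:
        for _ in range(n_off):
            child = breed_offspring(parent_g[mother_id], parent_g[father_id], rng)
            name = f"{spec.cohort}_o{len(names):03d}"
            rows.append(child)
            names.append(name)
            parent_of[name] = (mother_id, father_id)
    for u in range(spec.unrelated_count):
        name = f"{spec.cohort}_u{u:03d}"
        rows.append(founder_g[n_parents + u])
        names.append(name)
        parent_of[name] = (None, None)

    gm = GenotypeMatrix(
        dosages=np.vstack(rows),
        samples=names,
        cohorts=np.array([spec.cohort] * len(names), dtype=object),
    )
    return SyntheticDataset(genotypes=gm, truth_kinship=_pairwise_truth(parent_of), pool=pool)


DEFAULT_STUDY_CONFIG = {
    "n_cohorts": 14,
    "cohort_size": 10,
    "sweepstake_cohorts": ["coh05"],
    "n_fathers": 5,
    "L": 5000,
    "founder_dist": "neutral",
    "founder_params": (1e-3,),
    "missing_rate": 0.0,
}


def make_study_like_dataset(config: dict | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate a dataset shaped like the study's SNP panel, at reduced scale.

    Default: 14 cohorts of 10 diploid individuals at L=5000 SNPs drawn from a
    neutral founder pool. Exactly the cohorts tagged as sweepstake cohorts are
    single-mother families (one mother, ``n_fathers`` candidate fathers, each
    offspring's father uniform among them — a mixture of full- and
    half-siblings); all other cohorts are unrelated HWE founders. An optional
    per-genotype missingness rate knocks out calls uniformly at random.
    """
    cfg = dict(DEFAULT_STUDY_CONFIG)
    if config:
        unknown = set(config) - set(cfg) - {"cohorts"}
        if unknown:
            raise ConfigurationError(f"unknown study-config keys: {sorted(unknown)}")
        cfg.update(config)
    if not 0.0 <= float(cfg["missing_rate"]) < 1.0:
        raise ConfigurationError("missing_rate must be in [0, 1)")

    cohorts = cfg.get("cohorts")
    if cohorts is None:
        cohorts = [
            {
                "name": f"coh{i + 1:02d}",
                "size": cfg["cohort_size"],
                "structure": "sweepstake" if f"coh{i + 1:02d}" in cfg["sweepstake_cohorts"] else "unrelated",
            }
            for i in range(cfg["n_cohorts"])
        ]
    for c in cohorts:
        if c.get("structure") not in ("unrelated", "sweepstake"):
            raise ConfigurationError(f"cohort structure must be unrelated|sweepstake: {c!r}")
        if int(c.get("size", 0)) < 2:
            raise ConfigurationError(f"cohort size must be >= 2: {c!r}")

    rng = stage_rng(seed, "study-like-dataset")
    pool = draw_founder_frequencies(
        int(cfg["L"]), dist=cfg["founder_dist"], params=cfg["founder_params"],
        seed=int(rng.integers(2**31)),
    )

    blocks: list[GenotypeMatrix] = []
    truth: dict[frozenset, str] = {}
    for c in cohorts:
        name, size = str(c["name"]), int(c["size"])
        if c["structure"] == "sweepstake":
            n_f = int(cfg["n_fathers"])
            father_of = rng.integers(n_f, size=size)
            fams = [
                (f"{name}_mom", f"{name}_dad{j}", int((father_of == j).sum()))
                for j in range(n_f)
                if (father_of == j).sum() > 0
            ]
            spec = PedigreeSpec(cohort=name, families=fams)
        else:
            spec = PedigreeSpec(cohort=name, unrelated_count=size)
        ds = make_family_cohort(spec, pool, seed=int(rng.integers(2**31)))
        blocks.append(ds.genotypes)
        truth.update(ds.truth_kinship)

    dosages = np.vstack([b.dosages for b in blocks])
    samples = [s for b in blocks for s in b.samples]
    labels = np.concatenate([b.cohorts for b in blocks])
    miss = float(cfg["missing_rate"])
    if miss > 0:
        dosages = dosages.copy()
        dosages[rng.random(dosages.shape) < miss] = MISSING
    gm = GenotypeMatrix(dosages=dosages, samples=samples, cohorts=labels)
    return SyntheticDataset(genotypes=gm, truth_kinship=truth, pool=pool)
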