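"""Forward simulation of sweepstake reproduction in spawning stacks.

The model: limpets spawn in "stacks" of up to 20 individuals with a 1:1 sex
ratio. At the start of a generation the population is randomly partitioned
into stacks of size ``St``. Under *sweepstake* reproduction one focal stack is
chosen at random, ``F`` of its females breed, and exactly ``K`` offspring are
produced (mother uniform among the F breeders, father uniform among the
stack's males, independently per offspring). Under *relaxed* reproduction all
complete stacks breed and every stacked female is an eligible mother.

The metapopulation is a linear chain of five demes with a source and a sink:
the source reproduces by sweepstake, the rest relaxed; a proportion ``CD`` of
the source's offspring collectively disperses to the sink (displacing an equal
number of sink-born offspring, with the source refilled to carrying capacity
from the same breeders); all demes then exchange a fraction ``m`` of offspring
with each adjacent deme (stepping-stone migration). Every deme ends each
generation at exactly ``K`` individuals.

Kinship is tracked through the pedigree with one-generation memory: full-sib =
both parents shared, half-sib = exactly one, otherwise unrelated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .genotypes import MISSING
from .seeding import stage_rng
from .synth import FULL_SIB, HALF_SIB, UNRELATED, draw_founder_frequencies


@dataclass
class SweepstakeParams:
    """Sweepstake reproduction parameters: F breeding females, carrying
    capacity K, stack size St."""

    F: int = 1
    K: int = 1000
    St: int = 10

    def __post_init__(self) -> None:
        if self.St % 2 != 0:
            raise ConfigurationError("St must be even (1:1 sex ratio within a stack)")
        if not 2 <= self.St <= 20:
            raise ConfigurationError("St must be in [2, 20]")
        if not 1 <= self.F <= self.St // 2:
            raise ConfigurationError("F must satisfy 1 <= F <= St/2")
        if self.K < 1:
            raise ConfigurationError("K must be >= 1")


@dataclass
class MetapopParams:
    """Five-deme stepping-stone metapopulation with collective dispersal.

    ``CD`` is the proportion of source offspring dispersing en bloc to the
    sink; ``m`` the per-adjacent-pair migration fraction. Deme indices are
    0-based positions on the chain (defaults: sink at position 3 of 5 — two
    neighbours — and source at the end of the chain).
    """

    CD: float = 1.0
    m: float = 0.1
    n_demes: int = 5
    source_index: int = 4
    sink_index: int = 2
    post_event_generations: int = 3

    def __post_init__(self) -> None:
        if self.n_demes != 5:
            raise ConfigurationError("the metapopulation model is defined for 5 demes")
        if not 0.0 <= self.CD <= 1.0:
            raise ConfigurationError("CD must be in [0, 1]")
        if not 0.0 <= self.m < 0.5:
            raise ConfigurationError("m must be in [0, 0.5)")
        if self.source_index == self.sink_index:
            raise ConfigurationError("source and sink must differ")
        for ix in (self.source_index, self.sink_index):
            if not 0 <= ix < self.n_demes:
                raise ConfigurationError("deme index out of range")


@dataclass
class Population:
    """One generation of one deme: ids, sexes, parent ids, optional genotypes."""

    ids: np.ndarray
    female: np.ndarray
    mother: np.ndarray
    father: np.ndarray
    genotypes: np.ndarray | None = None

    @property
    def size(self) -> int:
        return self.ids.size

    def take(self, idx: np.ndarray) -> "Population":
        return Population(
            ids=self.ids[idx],
            female=self.female[idx],
            mother=self.mother[idx],
            father=self.father[idx],
            genotypes=None if self.genotypes is None else self.genotypes[idx],
        )


class IdAllocator:
    """Globally unique individual ids across demes and generations."""

    def __init__(self) -> None:
        self._next = 0

    def take(self, n: int) -> np.ndarray:
        ids = np.arange(self._next, self._next + n, dtype=np.int64)
        self._next += n
        return ids


@dataclass
class SimExperimentResult:
    """Replicate-level outcomes of a simulation experiment."""

    table: pd.DataFrame  # one row per replicate (x condition x deme x generation)
    replicates: int
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def success_proportion(self) -> float:
        return float(self.table["success"].mean())


def founder_population(n, rng, alloc, pool=None, founder_seed=None) -> Population:
    """Fresh founders: random 1:1-expected sexes, no recorded parents, and
    optional HWE genotypes drawn from a founder pool."""
    genotypes = None
    if pool is not None:
        seed = int(rng.integers(2**31)) if founder_seed is None else founder_seed
        g_rng = np.random.default_rng(seed)
        genotypes = g_rng.binomial(2, pool.frequencies, size=(n, pool.n_loci)).astype(np.int8)
    return Population(
        ids=alloc.take(n),
        female=rng.random(n) < 0.5,
        mother=np.full(n, -1, dtype=np.int64),
        father=np.full(n, -1, dtype=np.int64),
        genotypes=genotypes,
    )


def build_stacks(pop: Population, St: int, rng) -> list[tuple[np.ndarray, np.ndarray]]:
    """Randomly partition a population into balanced stacks.

    Full stacks hold St/2 females and St/2 males drawn without replacement;
    leftovers form one final smaller balanced stack (equal sexes); any
    unpairable remainder stays unstacked.
    """
    if St % 2 != 0:
        raise ConfigurationError("St must be even (balanced 1:1 stacks impossible otherwise)")
    if pop.size == 0:
        raise DataError("cannot build stacks from an empty population")
    half = St // 2
    females = rng.permutation(np.flatnonzero(pop.female))
    males = rng.permutation(np.flatnonzero(~pop.female))
    n_full = min(len(females), len(males)) // half
    stacks = [
        (females[i * half : (i + 1) * half], males[i * half : (i + 1) * half])
        for i in range(n_full)
    ]
    rest = min(len(females), len(males)) - n_full * half
    if rest >= 1:
        stacks.append(
            (females[n_full * half : n_full * half + rest], males[n_full * half : n_full * half + rest])
        )
    return stacks


def _transmit(parent_dosages: np.ndarray, rng, mutation_rate: float = 0.0) -> np.ndarray:
    """One gamete per row: allele count Bernoulli(dosage/2); missing stays missing.

    ``mutation_rate`` is the per-allele per-transmission probability of a
    symmetric flip (0 <-> 1), used by long multi-generation runs where the
    site-frequency spectrum must reflect mutations arising on the genealogy.
    """
    allele = (rng.random(parent_dosages.shape) < parent_dosages / 2.0).astype(np.int8)
    if mutation_rate > 0.0:
        flip = rng.random(parent_dosages.shape) < mutation_rate
        allele[flip] = 1 - allele[flip]
    allele[parent_dosages == MISSING] = np.int8(-64)  # sentinel; recombined below
    return allele


def _make_offspring(pop, mother_idx, father_idx, rng, alloc, mutation_rate: float = 0.0) -> Population:
    K = mother_idx.size
    genotypes = None
    if pop.genotypes is not None:
        gm = _transmit(pop.genotypes[mother_idx], rng, mutation_rate)
        gf = _transmit(pop.genotypes[father_idx], rng, mutation_rate)
        genotypes = gm + gf
        genotypes[(gm < 0) | (gf < 0)] = MISSING
    return Population(
        ids=alloc.take(K),
        female=rng.random(K) < 0.5,
        mother=pop.ids[mother_idx],
        father=pop.ids[father_idx],
        genotypes=genotypes,
    )


def sweepstake_generation(
    pop, params: SweepstakeParams, rng, alloc, n_offspring=None, mutation_rate: float = 0.0
) -> Population:
    """One sweepstake generation: a single focal stack produces all K offspring."""
    stacks = build_stacks(pop, params.St, rng)
    complete = [s for s in stacks if s[0].size == params.St // 2]
    if not complete:
        raise DataError("no complete stack available for sweepstake reproduction")
    f_idx, m_idx = complete[rng.integers(len(complete))]
    if params.F > f_idx.size:
        raise ConfigurationError("F exceeds the females available in the focal stack")
    breeders = rng.choice(f_idx, size=params.F, replace=False)
    K = params.K if n_offspring is None else int(n_offspring)
    mothers = breeders[rng.integers(params.F, size=K)]
    fathers = m_idx[rng.integers(m_idx.size, size=K)]
    return _make_offspring(pop, mothers, fathers, rng, alloc, mutation_rate)


def relaxed_generation(pop, St, K, rng, alloc) -> Population:
    """One relaxed generation: all complete stacks breed; mothers uniform over
    stacked females, father uniform over the mother's stack's males."""
    stacks = build_stacks(pop, St, rng)
    complete = [s for s in stacks if s[0].size == St // 2] or stacks[-1:]
    all_f = np.concatenate([s[0] for s in complete])
    stack_of_f = np.concatenate([np.full(s[0].size, i) for i, s in enumerate(complete)])
    pick = rng.integers(all_f.size, size=K)
    mothers = all_f[pick]
    fathers = np.empty(K, dtype=np.int64)
    for i, s in enumerate(complete):
        sel = stack_of_f[pick] == i
        fathers[sel] = s[1][rng.integers(s[1].size, size=int(sel.sum()))]
    return _make_offspring(pop, mothers, fathers, rng, alloc)


def pedigree_kinship(pop: Population, i: int, j: int) -> str:
    """Kinship category of two same-generation individuals by parental overlap."""
    if pop.mother[i] < 0 or pop.mother[j] < 0 or pop.father[i] < 0 or pop.father[j] < 0:
        raise DataError("pedigree kinship requires recorded parents for both individuals")
    shared = int(pop.mother[i] == pop.mother[j]) + int(pop.father[i] == pop.father[j])
    return (UNRELATED, HALF_SIB, FULL_SIB)[shared]


def sample_kinship_composition(pop: Population, sample_idx: np.ndarray) -> dict[str, float]:
    """Pedigree kinship fractions over all pairs of a sampled set."""
    pairs = list(combinations(sample_idx.tolist(), 2))
    counts = {UNRELATED: 0, HALF_SIB: 0, FULL_SIB: 0}
    for i, j in pairs:
        counts[pedigree_kinship(pop, i, j)] += 1
    total = len(pairs)
    return {k: v / total for k, v in counts.items()}


def mean_pi(dosages: np.ndarray) -> float:
    """Mean per-SNP nucleotide diversity over the full locus panel.

    Per locus with sample allele count n and alt frequency p:
    pi = n/(n-1) * 2 p (1-p); loci with fewer than two called alleles
    contribute nothing.
    """
    called = dosages >= 0
    n = 2 * called.sum(axis=0)
    alt = np.where(called, dosages, 0).sum(axis=0)
    ok = n >= 2
    p = alt[ok] / n[ok]
    pi = n[ok] / (n[ok] - 1) * 2.0 * p * (1.0 - p)
    return float(np.mean(pi)) if pi.size else 0.0


def _classify_replicate(offspring, sample_size, rng) -> tuple[bool, dict[str, float]]:
    sample = rng.choice(offspring.size, size=sample_size, replace=False)
    comp = sample_kinship_composition(offspring, sample)
    success = comp[UNRELATED] == 0.0
    return success, comp


def run_single_pop_experiment(
    params: SweepstakeParams,
    replicates: int = 100,
    sample_size: int = 10,
    seed: int = 0,
    mode: str = "sweepstake",
    L: int = 0,
    founder_dist=("uniform", (0.05, 0.95)),
) -> SimExperimentResult:
    """Replicated single-population experiment.

    Per replicate: fresh K founders, one generation of reproduction
    (``mode="sweepstake"`` for the focal-stack model, ``"relaxed"`` for all
    stacks / all females), a random sample of ``sample_size`` offspring, and
    pedigree classification of every sampled pair. A replicate succeeds when
    the sample contains only full- and half-siblings. Set ``L > 0`` to also
    track genotypes and report offspring vs founder nucleotide diversity.
    """
    if sample_size > params.K:
        raise ConfigurationError("sample_size cannot exceed K")
    if mode not in ("sweepstake", "relaxed"):
        raise ConfigurationError(f"unknown reproduction mode: {mode!r}")
    rng = stage_rng(seed, f"single-pop:{mode}")
    rows = []
    for rep in range(replicates):
        alloc = IdAllocator()
        pool = None
        if L > 0:
            dist, dist_params = founder_dist
            pool = draw_founder_frequencies(L, dist=dist, params=dist_params, seed=int(rng.integers(2**31)))
        founders = founder_population(params.K, rng, alloc, pool=pool)
        if mode == "sweepstake":
            offspring = sweepstake_generation(founders, params, rng, alloc)
        else:
            offspring = relaxed_generation(founders, params.St, params.K, rng, alloc)
        success, comp = _classify_replicate(offspring, sample_size, rng)
        row = {
            "replicate": rep,
            "success": success,
            "frac_unrelated": comp[UNRELATED],
            "frac_half_sib": comp[HALF_SIB],
            "frac_full_sib": comp[FULL_SIB],
        }
        if L > 0:
            row["pi_offspring"] = mean_pi(offspring.genotypes)
            row["pi_founders"] = mean_pi(founders.genotypes)
        rows.append(row)
    return SimExperimentResult(
        table=pd.DataFrame(rows),
        replicates=replicates,
        seed=seed,
        params={"F": params.F, "K": params.K, "St": params.St, "mode": mode, "L": L},
    )


def sample_recurrent_sweepstake_cohort(
    params: SweepstakeParams | None = None,
    generations: int = 30,
    L: int = 30000,
    mutation_rate: float = 1e-3,
    sample_size: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Cohort genotypes from a population under recurrent sweepstake reproduction.

    Runs a single population forward for ``generations`` generations with one
    sweepstake event per generation (a single focal stack produces all K
    offspring) and symmetric per-transmission mutation, starting from a
    monomorphic founder state so that every segregating site arose as a
    mutation on the genealogy. Returns the dosage matrix of a random sample of
    ``sample_size`` offspring — the forward analog of a sample whose
    site-frequency spectrum reflects a multiple-merger genealogy.
    """
    params = params or SweepstakeParams()
    rng = stage_rng(seed, "recurrent-sweepstake")
    alloc = IdAllocator()
    pop = founder_population(params.K, rng, alloc)
    pop.genotypes = np.zeros((params.K, L), dtype=np.int8)
    for _ in range(generations):
        pop = sweepstake_generation(pop, params, rng, alloc, mutation_rate=mutation_rate)
    sample = rng.choice(pop.size, size=sample_size, replace=False)
    return pop.genotypes[sample]


def _stepping_stone(demes: list[Population], m: float, K: int, rng) -> list[Population]:
    """Simultaneous size-preserving exchange of a fraction m with each chain
    neighbour."""
    n_mig = int(round(m * K))
    if n_mig == 0:
        return demes
    perms = [rng.permutation(K) for _ in demes]
    # blocks: for deme d, slots for the (d-1,d) swap then the (d,d+1) swap
    out_idx: list[dict[int, np.ndarray]] = []
    for d in range(len(demes)):
        blocks: dict[int, np.ndarray] = {}
        start = 0
        for nb in (d - 1, d + 1):
            if 0 <= nb < len(demes):
                blocks[nb] = perms[d][start : start + n_mig]
                start += n_mig
        out_idx.append(blocks)
    new = [d.take(np.arange(d.size)) for d in demes]

    def _assign(dst: Population, slots: np.ndarray, src: Population, src_slots: np.ndarray) -> None:
        dst.ids[slots] = src.ids[src_slots]
        dst.female[slots] = src.female[src_slots]
        dst.mother[slots] = src.mother[src_slots]
        dst.father[slots] = src.father[src_slots]
        if dst.genotypes is not None:
            dst.genotypes[slots] = src.genotypes[src_slots]

    for d in range(len(demes) - 1):
        a_slots = out_idx[d][d + 1]
        b_slots = out_idx[d + 1][d]
        _assign(new[d], a_slots, demes[d + 1], b_slots)
        _assign(new[d + 1], b_slots, demes[d], a_slots)
    return new


def metapop_generation(
    demes: list[Population],
    mp: MetapopParams,
    sw: SweepstakeParams,
    rng,
    alloc,
    source_mode: str = "sweepstake",
) -> list[Population]:
    """One metapopulation generation: reproduction, collective dispersal,
    stepping-stone migration. Every deme ends at exactly K.

    With ``source_mode="relaxed"`` (post-event generations) the source deme
    also reproduces in relaxed mode and ``CD`` is ignored.
    """
    if len(demes) != mp.n_demes:
        raise ConfigurationError("deme count does not match MetapopParams")
    K = sw.K
    n_cd = int(round(mp.CD * K)) if source_mode == "sweepstake" else 0
    offspring: list[Population] = []
    dispersers: Population | None = None
    for d, pop in enumerate(demes):
        if d == mp.source_index and source_mode == "sweepstake":
            # the focal stack breeds K offspring retained at the source plus the
            # collectively dispersing cohort, so the source stays at carrying capacity
            off = sweepstake_generation(pop, sw, rng, alloc, n_offspring=K + n_cd)
            dispersers = off.take(np.arange(n_cd))
            off = off.take(np.arange(n_cd, n_cd + K))
        else:
            off = relaxed_generation(pop, sw.St, K, rng, alloc)
        offspring.append(off)

    # diffuse stepping-stone migration first; the collectively dispersing cohort
    # arrives at the sink en bloc, undiluted (its kin only spread to adjacent
    # demes in the following generation's migration)
    offspring = _stepping_stone(offspring, mp.m, K, rng)

    if n_cd > 0 and dispersers is not None:
        sink = offspring[mp.sink_index]
        displaced = rng.choice(K, size=n_cd, replace=False)
        keep_mask = np.ones(K, dtype=bool)
        keep_mask[displaced] = False
        kept = sink.take(np.flatnonzero(keep_mask))
        offspring[mp.sink_index] = Population(
            ids=np.concatenate([kept.ids, dispersers.ids]),
            female=np.concatenate([kept.female, dispersers.female]),
            mother=np.concatenate([kept.mother, dispersers.mother]),
            father=np.concatenate([kept.father, dispersers.father]),
            genotypes=None
            if kept.genotypes is None
            else np.vstack([kept.genotypes, dispersers.genotypes]),
        )

    return offspring


def _fresh_metapop(sw, mp, rng, alloc, pool) -> list[Population]:
    return [founder_population(sw.K, rng, alloc, pool=pool) for _ in range(mp.n_demes)]


def run_cd_experiment(
    cd_grid,
    sw: SweepstakeParams | None = None,
    mp: MetapopParams | None = None,
    replicates: int = 100,
    sample_size: int = 10,
    L: int = 1000,
    seed: int = 0,
) -> SimExperimentResult:
    """Collective-dispersal sweep: success, kinship composition and
    pi_sink/pi_source of the sink cohort across a grid of CD values."""
    sw = sw or SweepstakeParams()
    mp = mp or MetapopParams()
    for cd in cd_grid:
        if not 0.0 <= cd <= 1.0:
            raise ConfigurationError(f"CD value out of [0,1]: {cd}")
    rng = stage_rng(seed, "cd-experiment")
    rows = []
    for cd in cd_grid:
        mp_cd = MetapopParams(
            CD=float(cd), m=mp.m, source_index=mp.source_index,
            sink_index=mp.sink_index, post_event_generations=mp.post_event_generations,
        )
        for rep in range(replicates):
            alloc = IdAllocator()
            pool = draw_founder_frequencies(L, "uniform", (0.05, 0.95), seed=int(rng.integers(2**31)))
            demes = _fresh_metapop(sw, mp_cd, rng, alloc, pool)
            demes = metapop_generation(demes, mp_cd, sw, rng, alloc)
            sink = demes[mp_cd.sink_index]
            success, comp = _classify_replicate(sink, sample_size, rng)
            rows.append(
                {
                    "CD": float(cd),
                    "replicate": rep,
                    "success": success,
                    "frac_unrelated": comp[UNRELATED],
                    "frac_half_sib": comp[HALF_SIB],
                    "frac_full_sib": comp[FULL_SIB],
                    "pi_sink": mean_pi(sink.genotypes),
                    "pi_source": mean_pi(demes[mp_cd.source_index].genotypes),
                }
            )
    return SimExperimentResult(
        table=pd.DataFrame(rows),
        replicates=replicates,
        seed=seed,
        params={"cd_grid": list(map(float, cd_grid)), "L": L, "m": mp.m},
    )


def run_decay_experiment(
    sw: SweepstakeParams | None = None,
    mp: MetapopParams | None = None,
    replicates: int = 50,
    sample_size: int = 10,
    L: int = 1000,
    seed: int = 0,
) -> SimExperimentResult:
    """Decay of sweepstake signatures over post-event generations.

    Generation 0 is a sweepstake event at the source with collective dispersal
    ``mp.CD`` (the successful regime, CD >= 0.95, by default); the following
    ``mp.post_event_generations`` generations run all demes in relaxed mode
    with CD = 0 and stepping-stone migration active. Reports per-generation,
    per-deme nucleotide diversity and sampled kinship composition.
    """
    sw = sw or SweepstakeParams()
    mp = mp or MetapopParams()
    if mp.CD < 0.95:
        raise ConfigurationError("decay experiment starts from the successful regime (CD >= 0.95)")
    rng = stage_rng(seed, "decay-experiment")
    rows = []
    for rep in range(replicates):
        alloc = IdAllocator()
        pool = draw_founder_frequencies(L, "uniform", (0.05, 0.95), seed=int(rng.integers(2**31)))
        demes = _fresh_metapop(sw, mp, rng, alloc, pool)
        pi_baseline = mean_pi(demes[mp.source_index].genotypes)
        demes = metapop_generation(demes, mp, sw, rng, alloc)
        for gen in range(mp.post_event_generations + 1):
            if gen > 0:
                demes = metapop_generation(demes, mp, sw, rng, alloc, source_mode="relaxed")
            for d, pop in enumerate(demes):
                success, comp = _classify_replicate(pop, sample_size, rng)
                rows.append(
                    {
                        "replicate": rep,
                        "generation": gen,
                        "deme": d,
                        "is_sink": d == mp.sink_index,
                        "is_source": d == mp.source_index,
                        "frac_unrelated": comp[UNRELATED],
                        "frac_half_sib": comp[HALF_SIB],
                        "frac_full_sib": comp[FULL_SIB],
                        "pi": mean_pi(pop.genotypes),
                        "pi_source_baseline": pi_baseline,
                    }
                )
    return SimExperimentResult(
        table=pd.DataFrame(rows),
        replicates=replicates,
        seed=seed,
        params={"CD": mp.CD, "m": mp.m, "L": L},
    )
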