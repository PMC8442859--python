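"""Expected site-frequency spectra under Kingman and Xi-Beta coalescents.

Sweepstakes reproduction in a diploid population generates genealogies in
which many ancestral lineages can merge at once: at a large reproduction event
the participating lineages fall into up to four parental groups (the four
genome copies of the single pair of diploid parents), and each group merges
simultaneously. The resulting genealogy is a simultaneous multiple-merger
Xi-Beta(2-alpha, alpha) coalescent with 1 < alpha < 2; alpha -> 2 recovers the
Kingman coalescent.

The model's prediction for the normalized expected spectrum E[B_i]/E[B] is
estimated here by Monte-Carlo simulation of the genealogy (with per-class
standard errors), verified against an independent exact first-step-analysis
oracle for n <= 5. Model comparison against an empirical normalized folded
spectrum uses the l2 metric, the sum of squared coordinate-wise differences.

Event semantics: with ``b`` active lineages, a candidate event with ``k``
participants occurs at rate ``4 C(b,k) lambda_{b,k}`` where
``lambda_{b,k} = B(k - alpha, b - k + alpha) / B(2 - alpha, alpha)``; each
participant is dropped independently and uniformly into one of 4 parental
groups and every group with >= 2 members merges. Candidate events in which no
group reaches size 2 change nothing but still consume their exponential
holding time. The global factor 4 sets the effective pair-coalescence rate at
b = 2 to exactly ``lambda_{2,2} = 1`` (the classical timescale; a k = 2
candidate lands both participants in one group with probability 1/4).
Normalized spectra are invariant to this choice of timescale.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from itertools import combinations, product
from math import comb, exp

import numpy as np
from scipy.special import betaln

from .errors import ConfigurationError, DataError
from .seeding import stage_pyrandom
from .spectra import BranchSpectrum, SpectrumCounts, fold

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(1.05, 1.951, 0.05), 2))
_N_GROUPS = 4
_TIMESCALE = 4.0  # sets the b=2 effective pair rate to lambda_{2,2} = 1


def kingman_expected_nsfs(n: int, folded: bool = True) -> BranchSpectrum:
    """Closed-form Kingman branch spectrum: E[B_i] = 2/i.

    The normalized unfolded spectrum is (1/i)/H_{n-1}; folding gives
    Y_j = X_j + X_{n-j} for j < n/2 and Y_{n/2} = X_{n/2}. The ``folded``
    flag is kept for interface symmetry; both pathways hang off the returned
    :class:`BranchSpectrum`.
    """
    if n < 2:
        raise ConfigurationError("n must be >= 2")
    i = np.arange(1, n)
    return BranchSpectrum(n=n, B=2.0 / i)


def beta_merger_rate(b: int, k: int, alpha: float) -> float:
    """Lambda-coalescent merger rate lambda_{b,k} of the Beta(2-alpha, alpha)
    measure: B(k - alpha, b - k + alpha) / B(2 - alpha, alpha)."""
    if not 1.0 < alpha < 2.0:
        raise ConfigurationError("alpha must lie in the open interval (1, 2)")
    if not 2 <= k <= b:
        raise ConfigurationError("merger size must satisfy 2 <= k <= b")
    return exp(betaln(k - alpha, b - k + alpha) - betaln(2.0 - alpha, alpha))


def _rate_tables(n: int, alpha: float) -> list:
    """Per lineage-count b: (total candidate rate, cumulative rates over k=2..b,
    per-subset rates). Candidate rate for k participants: 4 C(b,k) lambda_{b,k}."""
    tables: list = [None, None]
    for b in range(2, n + 1):
        rates = [_TIMESCALE * comb(b, k) * beta_merger_rate(b, k, alpha) for k in range(2, b + 1)]
        cum = np.cumsum(rates)
        tables.append((float(cum[-1]), cum.tolist()))
    return tables


def simulate_xi_beta_genealogy(n: int, alpha: float, rng, tables=None) -> np.ndarray:
    """Simulate one Xi-Beta genealogy; return its branch-length spectrum.

    ``rng`` is a stdlib ``random.Random``. The returned vector ``B`` holds the
    total length of branches supporting i leaves, i = 1..n-1, for this tree.
    """
    if n < 2:
        raise ConfigurationError("n must be >= 2")
    tables = tables if tables is not None else _rate_tables(n, alpha)
    supports = [1] * n
    B = [0.0] * (n - 1)
    b = n
    while b > 1:
        total, cum = tables[b]
        t = rng.expovariate(total)
        for s in supports:
            B[s - 1] += t
        k = 2 + bisect_right(cum, rng.random() * total)
        k = min(k, b)  # guard float edge at the top of the cumulative table
        participants = rng.sample(range(b), k)
        groups: dict[int, list[int]] = {}
        for p in participants:
            groups.setdefault(rng.randrange(_N_GROUPS), []).append(p)
        merged = [g for g in groups.values() if len(g) >= 2]
        if merged:
            dead = {x for g in merged for x in g}
            new_supports = [s for idx, s in enumerate(supports) if idx not in dead]
            new_supports.extend(sum(supports[x] for x in g) for g in merged)
            supports = new_supports
            b = len(supports)
    return np.asarray(B)


def simulate_xi_beta_branch_spectra(
    n: int, alpha: float, replicates: int, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo sample of per-tree branch spectra, shape (replicates, n-1)."""
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    rng = stage_pyrandom(seed, f"xi-beta:{n}:{alpha}")
    tables = _rate_tables(n, alpha)
    out = np.empty((replicates, n - 1))
    for r in range(replicates):
        out[r] = simulate_xi_beta_genealogy(n, alpha, rng, tables)
    return out


def normalized_with_se(B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized unfolded spectrum mean(B_i)/mean(B) with delta-method SEs,
    from a (replicates, n-1) matrix of per-tree branch spectra."""
    m = B.shape[0]
    tot = B.sum(axis=1)
    ratio = B.mean(axis=0) / tot.mean()
    resid = B - ratio[None, :] * tot[:, None]
    se = resid.std(axis=0, ddof=1) / (tot.mean() * np.sqrt(m))
    return ratio, se


def _folded_normalized_with_se(B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized folded spectrum mean(Bf)/mean(Btot) with delta-method SEs."""
    m, nm1 = B.shape
    n = nm1 + 1
    tot = B.sum(axis=1)
    folded = np.stack([fold(B[r]) for r in range(m)]) if m < 512 else _fold_rows(B)
    ratio = folded.mean(axis=0) / tot.mean()
    resid = folded - ratio[None, :] * tot[:, None]
    se = resid.std(axis=0, ddof=1) / (tot.mean() * np.sqrt(m))
    return ratio, se


def _fold_rows(B: np.ndarray) -> np.ndarray:
    n = B.shape[1] + 1
    half = n // 2
    out = np.empty((B.shape[0], half))
    for j in range(1, half + 1):
        out[:, j - 1] = B[:, j - 1] if 2 * j == n else B[:, j - 1] + B[:, n - j - 1]
    return out


def xi_beta_expected_nsfs(
    n: int, alpha: float, replicates: int = 20000, seed: int = 0
) -> BranchSpectrum:
    """Monte-Carlo estimate of the Xi-Beta expected branch spectrum.

    Returns mean per-class branch lengths with delta-method Monte-Carlo
    standard errors on the normalized folded spectrum.
    """
    B = simulate_xi_beta_branch_spectra(n, alpha, replicates, seed)
    _, se = _folded_normalized_with_se(B)
    return BranchSpectrum(n=n, B=B.mean(axis=0), mc_se=se, replicates=replicates)


def _state_transitions(state: tuple, lam_cache: dict, alpha: float) -> dict:
    """Effective (state-changing) transition rates out of one configuration."""
    b = len(state)
    out: dict[tuple, float] = {}
    for k in range(2, b + 1):
        lam = lam_cache.setdefault((b, k), beta_merger_rate(b, k, alpha))
        subset_rate = _TIMESCALE * lam  # rate of a candidate event for one specific subset
        assign_p = 1.0 / _N_GROUPS**k
        for S in combinations(range(b), k):
            for assignment in product(range(_N_GROUPS), repeat=k):
                groups: dict[int, list[int]] = {}
                for member, g in zip(S, assignment):
                    groups.setdefault(g, []).append(member)
                merged = [g for g in groups.values() if len(g) >= 2]
                if not merged:
                    continue  # no-op: consumes time but does not change state
                dead = {x for g in merged for x in g}
                new = [s for idx, s in enumerate(state) if idx not in dead]
                new.extend(sum(state[x] for x in g) for g in merged)
                key = tuple(sorted(new))
                out[key] = out.get(key, 0.0) + subset_rate * assign_p
    return out


def small_n_exact_oracle(n: int, alpha: float) -> BranchSpectrum:
    """Exact expected branch spectrum for n <= 5 by first-step analysis.

    Enumerates every configuration (multiset of leaf-support counts), sums the
    exact 4-group merger transition rates over participant subsets and group
    assignments, and solves the linear occupation-time equations of the
    continuous-time chain. Independent of the Monte-Carlo pathway; refuses
    n > 5 (state-space growth).
    """
    if not 2 <= n <= 5:
        raise ConfigurationError("exact oracle is defined for n in {2,3,4,5}")
    if not 1.0 < alpha < 2.0:
        raise ConfigurationError("alpha must lie in (1, 2)")
    lam_cache: dict = {}
    start = tuple([1] * n)
    # breadth-first enumeration of reachable transient states
    transitions: dict[tuple, dict[tuple, float]] = {}
    frontier = [start]
    while frontier:
        s = frontier.pop()
        if s in transitions or len(s) == 1:
            continue
        trans = _state_transitions(s, lam_cache, alpha)
        transitions[s] = trans
        frontier.extend(t for t in trans if len(t) > 1 and t not in transitions)
    states = sorted(transitions, key=lambda s: (-len(s), s))
    index = {s: i for i, s in enumerate(states)}
    q = np.zeros((len(states), len(states)))
    for s, trans in transitions.items():
        i = index[s]
        for t, rate in trans.items():
            q[i, i] -= rate
            if len(t) > 1:
                q[i, index[t]] += rate
    occupancy = np.linalg.solve(-q.T, np.eye(len(states))[index[start]])
    B = np.zeros(n - 1)
    for s, time in zip(states, occupancy):
        for part in s:
            B[part - 1] += time
    return BranchSpectrum(n=n, B=B)


def l2_distance(x, y) -> float:
    """Sum of squared coordinate-wise differences between two spectra."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("spectra have different lengths")
    return float(((x - y) ** 2).sum())


@dataclass
class FitResult:
    """l2 model comparison of an empirical folded spectrum against coalescent
    expectations."""

    n: int
    l2_kingman: float
    l2_xi_by_alpha: dict[float, float]
    best_alpha: float
    best_model: str
    mc_tolerance: float = 0.0
    mc_se_by_alpha: dict[float, np.ndarray] = field(default_factory=dict)

    @property
    def l2_best_xi(self) -> float:
        return self.l2_xi_by_alpha[self.best_alpha]

    @property
    def decisively_xi(self) -> bool:
        """True when the Xi-Beta improvement exceeds the Monte-Carlo tolerance
        on the best Xi-Beta l2."""
        return self.best_model == "xi_beta" and (self.l2_kingman - self.l2_best_xi) > self.mc_tolerance


def _l2_mc_tolerance(z: np.ndarray, model: np.ndarray, se: np.ndarray) -> float:
    """Bound on the Monte-Carlo error of l2(z, model_hat): with per-class
    3-SE deviations delta_j, |l2 - l2_hat| <= sum(2|z - model_hat| 3 se + (3 se)^2)."""
    d = 3.0 * se
    return float((2.0 * np.abs(z - model) * d + d**2).sum())


def fit_models(
    empirical: SpectrumCounts,
    alpha_grid=DEFAULT_ALPHA_GRID,
    replicates: int = 20000,
    seed: int = 0,
    cache: dict | None = None,
) -> FitResult:
    """Compare an empirical folded spectrum to Kingman and Xi-Beta expectations.

    l2 is computed against the Kingman closed form and against the Monte-Carlo
    Xi-Beta expectation at each grid alpha; the best model minimizes l2, with
    ties (within 1e-12) resolved to Kingman by parsimony. ``cache`` (keyed by
    ``(n, alpha, replicates, seed)``) lets a caller reuse expected spectra
    across cohorts of equal sample size.
    """
    grid = [float(a) for a in alpha_grid]
    if not grid:
        raise ConfigurationError("alpha grid is empty")
    for a in grid:
        if not 1.0 < a < 2.0:
            raise ConfigurationError(f"alpha {a} outside (1, 2)")
    z = empirical.Z
    n = empirical.n
    king = kingman_expected_nsfs(n).normalized_folded
    l2_king = l2_distance(z, king)
    l2_xi: dict[float, float] = {}
    se_by_alpha: dict[float, np.ndarray] = {}
    for a in grid:
        key = (n, a, replicates, seed)
        if cache is not None and key in cache:
            spec = cache[key]
        else:
            spec = xi_beta_expected_nsfs(n, a, replicates=replicates, seed=seed)
            if cache is not None:
                cache[key] = spec
        l2_xi[a] = l2_distance(z, spec.normalized_folded)
        se_by_alpha[a] = spec.mc_se
    best_alpha = min(grid, key=lambda a: l2_xi[a])
    best_model = "kingman" if l2_king <= l2_xi[best_alpha] + 1e-12 else "xi_beta"
    # tolerance evaluated at the best-fitting Xi spectrum
    best_spec_key = (n, best_alpha, replicates, seed)
    best_model_spec = (
        cache[best_spec_key].normalized_folded
        if cache is not None
        else xi_beta_expected_nsfs(n, best_alpha, replicates=replicates, seed=seed).normalized_folded
    )
    tol = _l2_mc_tolerance(z, best_model_spec, se_by_alpha[best_alpha])
    return FitResult(
        n=n,
        l2_kingman=l2_king,
        l2_xi_by_alpha=l2_xi,
        best_alpha=best_alpha,
        best_model=best_model,
        mc_tolerance=tol,
        mc_se_by_alpha=se_by_alpha,
    )
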