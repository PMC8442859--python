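"""Relatedness estimators: IBS counts, moments IBD, robust phi, classification."""

import numpy as np
import pytest

from cgpatch import kinship, synth
from cgpatch.errors import DataError
from cgpatch.seeding import stage_rng

PAIR_KINDS = ["parent-offspring", "full-sib", "half-sib", "unrelated"]
EXPECTED_Z = {
    "parent-offspring": (0.0, 1.0, 0.0),
    "full-sib": (0.25, 0.5, 0.25),
    "half-sib": (0.5, 0.5, 0.0),
    "unrelated": (1.0, 0.0, 0.0),
}
EXPECTED_PHI = {"parent-offspring": 0.25, "full-sib": 0.25, "half-sib": 0.125, "unrelated": 0.0}


def _pedigreed_pair(kind, pool, rng):
    founders = synth.sample_founders(pool, 3, seed=int(rng.integers(2**31)))
    a, b, c = founders
    if kind == "parent-offspring":
        return a, synth.breed_offspring(a, b, rng)
    if kind == "full-sib":
        return synth.breed_offspring(a, b, rng), synth.breed_offspring(a, b, rng)
    if kind == "half-sib":
        return synth.breed_offspring(a, b, rng), synth.breed_offspring(a, c, rng)
    return a, b


@pytest.fixture(scope="module")
def common_pool():
    return synth.draw_founder_frequencies(2000, "uniform", (0.05, 0.95), seed=42)


class TestIbsCounts:
    def test_identical_genotypes(self):
        g = np.array([0, 1, 2, 1, 0], np.int8)
        c = kinship.ibs_counts(g, g)
        assert c.ibs2 == 5 and c.ibs0 == 0 and c.n_opp_hom == 0

    def test_opposite_homozygotes(self):
        c = kinship.ibs_counts(np.array([0], np.int8), np.array([2], np.int8))
        assert c.ibs0 == 1 and c.n_opp_hom == 1

    def test_double_heterozygote(self):
        c = kinship.ibs_counts(np.array([1], np.int8), np.array([1], np.int8))
        assert c.ibs2 == 1 and c.n_het_het == 1

    def test_missing_excluded(self):
        c = kinship.ibs_counts(np.array([-1, 1], np.int8), np.array([1, 1], np.int8))
        assert c.n_loci == 1

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            kinship.ibs_counts(np.zeros(3, np.int8), np.zeros(4, np.int8))


class TestEstimators:
    def test_duplicate_limit(self, common_pool):
        g = synth.sample_founders(common_pool, 1, seed=1)[0]
        z0, z1, z2, pi_hat, _, ok = kinship.ibd_moments(g, g, common_pool.frequencies)
        phi, _, _ = kinship.robust_kinship(g, g)
        assert ok and z2 > 0.95 and pi_hat > 0.97
        assert phi == pytest.approx(0.5)
        assert kinship.classify_kinship(z0, z1, z2, phi) == kinship.DUPLICATE

    @pytest.mark.parametrize("kind", PAIR_KINDS)
    def test_pedigree_expectations_recovered(self, kind, common_pool):
        rng = stage_rng(7, f"pairs:{kind}")
        zs, phis, cats = [], [], []
        for _ in range(10):
            gi, gj = _pedigreed_pair(kind, common_pool, rng)
            pk = kinship.estimate_pair(gi, gj, common_pool.frequencies)
            zs.append([pk.z0, pk.z1, pk.z2])
            phis.append(pk.phi)
            cats.append(pk.category)
        z_mean = np.mean(zs, axis=0)
        # reduced-size check (L=2000, 10 pairs); clamping at the simplex boundary
        # biases the unrelated Z0 slightly below 1
        assert np.abs(z_mean - EXPECTED_Z[kind]).max() < 0.07
        assert abs(np.mean(phis) - EXPECTED_PHI[kind]) < 0.03
        assert np.mean([c == kind for c in cats]) >= 0.9

    def test_symmetry(self, common_pool):
        rng = stage_rng(8, "sym")
        gi, gj = _pedigreed_pair("full-sib", common_pool, rng)
        a = kinship.estimate_pair(gi, gj, common_pool.frequencies)
        b = kinship.estimate_pair(gj, gi, common_pool.frequencies)
        assert (a.z0, a.z1, a.z2, a.phi) == (b.z0, b.z1, b.z2, b.phi)

    def test_missingness_robustness(self, common_pool):
        """Deleting 10% of genotypes changes phi by < 0.02 on average."""
        rng = stage_rng(9, "miss")
        deltas = []
        for _ in range(15):
            gi, gj = _pedigreed_pair("full-sib", common_pool, rng)
            phi0, _, _ = kinship.robust_kinship(gi, gj)
            gi2, gj2 = gi.copy(), gj.copy()
            gi2[rng.random(gi.size) < 0.1] = -1
            gj2[rng.random(gj.size) < 0.1] = -1
            phi1, _, _ = kinship.robust_kinship(gi2, gj2)
            deltas.append(phi1 - phi0)
        assert abs(np.mean(deltas)) < 0.02

    def test_phi_pihat_strongly_correlated(self, common_pool):
        from scipy.stats import spearmanr

        rng = stage_rng(10, "corr")
        phis, pihats = [], []
        for kind in PAIR_KINDS:
            for _ in range(8):
                gi, gj = _pedigreed_pair(kind, common_pool, rng)
                pk = kinship.estimate_pair(gi, gj, common_pool.frequencies)
                phis.append(pk.phi)
                pihats.append(pk.pi_hat)
        rho = spearmanr(phis, pihats).statistic
        assert rho > 0.9

    def test_too_few_loci_flagged(self):
        g = np.array([1, 0, 2], np.int8)
        f = np.array([0.5, 0.5, 0.5])
        pk = kinship.estimate_pair(g, g, f, min_loci=100)
        assert not pk.reliable and pk.category == kinship.UNCLASSIFIED

    def test_no_heterozygotes_flagged(self):
        gi = np.zeros(200, np.int8)
        gj = np.full(200, 2, np.int8)
        phi, _, ok = kinship.robust_kinship(gi, gj)
        assert np.isnan(phi) and not ok


class TestClassification:
    @pytest.mark.parametrize(
        "z0,phi,expected",
        [
            (0.0, 0.25, "parent-offspring"),
            (0.25, 0.25, "full-sib"),
            (0.5, 0.125, "half-sib"),
            (0.9, 0.06, kinship.THIRD_DEGREE),
            (0.95, 0.03, kinship.FOURTH_DEGREE),
            (1.0, 0.0, "unrelated"),
            (0.0, 0.45, kinship.DUPLICATE),
        ],
    )
    def test_degree_boundaries(self, z0, phi, expected):
        assert kinship.classify_kinship(z0, 1 - z0, 0.0, phi) == expected

    def test_boundaries_are_half_open(self):
        # exactly 2^(-5/2) is NOT first degree; infinitesimally above is
        b = 2 ** (-5 / 2)
        assert kinship.classify_kinship(0.5, 0.5, 0.0, b) == "half-sib"
        assert kinship.classify_kinship(0.25, 0.5, 0.25, b * 1.001) == "full-sib"


class TestCohortSummary:
    def test_pair_count(self, small_study):
        pairs = kinship.estimate_cohort_pairs(small_study.genotypes, "coh01")
        assert len(pairs) == 28  # C(8,2)

    def test_family_cohort_is_all_close_kin(self, small_study):
        comp = kinship.cohort_kinship_summary(small_study.genotypes, "coh02")
        assert comp["full-sib"] + comp["half-sib"] == pytest.approx(1.0)

    def test_unrelated_cohort(self, small_study):
        comp = kinship.cohort_kinship_summary(small_study.genotypes, "coh01")
        assert comp["unrelated"] >= 0.95

    def test_singleton_cohort_is_error(self, small_study):
        gm = small_study.genotypes
        solo = gm.dosages[:1]
        single = type(gm)(dosages=solo, samples=["x"], cohorts=np.array(["only"], dtype=object))
        with pytest.raises(DataError):
            kinship.estimate_cohort_pairs(single, "only")
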