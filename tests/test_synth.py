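"""Synthetic-data generator: founder draws, Mendelian transmission, pedigrees."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgpatch import synth
from cgpatch.errors import ConfigurationError
from cgpatch.seeding import stage_rng


class TestFounderFrequencies:
    def test_degenerate_uniform_is_constant(self):
        pool = synth.draw_founder_frequencies(5, "uniform", (0.5, 0.5), seed=0)
        assert np.all(pool.frequencies == 0.5)

    def test_law_of_large_numbers_mean(self):
        pool = synth.draw_founder_frequencies(1000, "uniform", (0.05, 0.95), seed=1)
        se = 0.26 / np.sqrt(1000)
        assert abs(pool.frequencies.mean() - 0.5) < 3 * se

    def test_seed_determinism(self):
        a = synth.draw_founder_frequencies(200, "beta", (0.5, 0.5), seed=7)
        b = synth.draw_founder_frequencies(200, "beta", (0.5, 0.5), seed=7)
        np.testing.assert_array_equal(a.frequencies, b.frequencies)

    def test_neutral_distribution_is_rare_skewed(self):
        pool = synth.draw_founder_frequencies(20000, "neutral", (1e-3,), seed=2)
        # density ∝ 1/p: mass below 0.1 is log(100)/log(999/... ) >> uniform's 0.1
        assert (pool.frequencies < 0.1).mean() > 0.5

    @pytest.mark.parametrize(
        "dist,params",
        [("uniform", (0.0, 0.5)), ("uniform", (0.9, 0.1)), ("beta", (0, 1)), ("neutral", (0.7,)), ("gamma", (1, 1))],
    )
    def test_invalid_parameters_rejected(self, dist, params):
        with pytest.raises(ConfigurationError):
            synth.draw_founder_frequencies(10, dist, params, seed=0)

    def test_frequencies_strictly_polymorphic(self):
        pool = synth.draw_founder_frequencies(5000, "beta", (0.2, 0.2), seed=3)
        assert pool.frequencies.min() > 0.0 and pool.frequencies.max() < 1.0


class TestFounderSampling:
    def test_hwe_genotype_frequencies(self):
        pool = synth.draw_founder_frequencies(1, "uniform", (0.5, 0.5), seed=0)
        g = synth.sample_founders(pool, 1000, seed=4)[:, 0]
        for dosage, expected in [(0, 0.25), (1, 0.5), (2, 0.25)]:
            se = np.sqrt(expected * (1 - expected) / 1000)
            assert abs((g == dosage).mean() - expected) < 3 * se

    def test_mean_dosage_matches_binomial(self):
        pool = synth.draw_founder_frequencies(1, "uniform", (0.5, 0.5), seed=0)
        g = synth.sample_founders(pool, 1000, seed=5)
        assert abs(g.mean() - 1.0) < 3 * np.sqrt(0.5 / 1000)

    def test_determinism_and_no_missing(self):
        pool = synth.draw_founder_frequencies(50, "uniform", (0.1, 0.9), seed=1)
        a = synth.sample_founders(pool, 10, seed=6)
        b = synth.sample_founders(pool, 10, seed=6)
        np.testing.assert_array_equal(a, b)
        assert (a >= 0).all()


class TestMendelianTransmission:
    def test_opposite_homozygotes_give_heterozygote(self):
        rng = stage_rng(0, "t")
        child = synth.breed_offspring(np.full(100, 2, np.int8), np.zeros(100, np.int8), rng)
        assert (child == 1).all()

    def test_double_het_offspring_distribution(self):
        rng = stage_rng(1, "t")
        child = synth.breed_offspring(np.ones(10000, np.int8), np.ones(10000, np.int8), rng)
        assert abs((child == 1).mean() - 0.5) < 0.015

    def test_missing_locus_transmits_missing(self):
        rng = stage_rng(2, "t")
        mother = np.array([-1, 1], np.int8)
        child = synth.breed_offspring(mother, np.array([1, 1], np.int8), rng)
        assert child[0] == -1 and child[1] >= 0

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=1, max_size=30),
        st.integers(0, 2**31 - 1),
    )
    def test_mendelian_consistency(self, parent_pairs, seed):
        """Offspring dosage is always compatible with its parents' dosages."""
        mother = np.array([m for m, _ in parent_pairs], np.int8)
        father = np.array([f for _, f in parent_pairs], np.int8)
        child = synth.breed_offspring(mother, father, np.random.default_rng(seed))
        for m, f, c in zip(mother, father, child):
            allowed = {am + af for am in ({0} if m == 0 else {1} if m == 2 else {0, 1})
                       for af in ({0} if f == 0 else {1} if f == 2 else {0, 1})}
            assert int(c) in allowed


class TestFamilyCohorts:
    def test_one_mother_two_fathers_all_close_kin(self):
        pool = synth.draw_founder_frequencies(200, seed=1)
        spec = synth.PedigreeSpec("fam", families=[("mom", "dad1", 5), ("mom", "dad2", 5)])
        ds = synth.make_family_cohort(spec, pool, seed=2)
        assert len(ds.truth_kinship) == 45
        assert set(ds.truth_kinship.values()) <= {synth.FULL_SIB, synth.HALF_SIB}

    def test_unrelated_cohort_truth(self):
        pool = synth.draw_founder_frequencies(100, seed=1)
        ds = synth.make_family_cohort(synth.PedigreeSpec("u", unrelated_count=10), pool, seed=3)
        assert set(ds.truth_kinship.values()) == {synth.UNRELATED}

    def test_truth_symmetry(self):
        pool = synth.draw_founder_frequencies(50, seed=1)
        spec = synth.PedigreeSpec("fam", families=[("m", "d", 3)], unrelated_count=2)
        ds = synth.make_family_cohort(spec, pool, seed=4)
        for pair in ds.truth_kinship:
            a, b = sorted(pair)
            assert ds.truth_category(a, b) == ds.truth_category(b, a)

    def test_family_cohort_diversity_depressed(self):
        """A single-mother cohort has lower mean heterozygosity than equal-size
        founder samples from the same pool (10-replicate mean)."""
        from cgpatch.forward import mean_pi

        pool = synth.draw_founder_frequencies(2000, seed=5)
        fam_pi, unrel_pi = [], []
        for rep in range(10):
            spec = synth.PedigreeSpec("f", families=[("m", f"d{j}", 2) for j in range(5)])
            fam = synth.make_family_cohort(spec, pool, seed=100 + rep)
            unrel = synth.sample_founders(pool, 10, seed=200 + rep)
            fam_pi.append(mean_pi(fam.genotypes.dosages))
            unrel_pi.append(mean_pi(unrel))
        assert np.mean(fam_pi) < np.mean(unrel_pi)

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            synth.PedigreeSpec("bad", families=[("m", "d", -1)])
        with pytest.raises(ConfigurationError):
            synth.PedigreeSpec("empty")


class TestStudyLikeDataset:
    def test_default_shape(self, small_study):
        gm = small_study.genotypes
        assert len(gm.cohort_names()) == 4
        assert gm.n_samples == 32
        family = [
            c for c in gm.cohort_names()
            if set(
                small_study.truth_kinship[frozenset(p)]
                for p in _cohort_pairs(gm, c)
            ) <= {synth.FULL_SIB, synth.HALF_SIB}
        ]
        assert family == ["coh02"]

    def test_default_config_has_14_cohorts(self):
        ds = synth.make_study_like_dataset({"L": 50}, seed=1)
        assert len(ds.genotypes.cohort_names()) == 14

    def test_no_missingness_by_default(self, small_study):
        assert (small_study.genotypes.dosages >= 0).all()

    def test_missingness_rate_applied(self):
        ds = synth.make_study_like_dataset(
            {"n_cohorts": 2, "cohort_size": 4, "sweepstake_cohorts": [], "L": 400, "missing_rate": 0.1},
            seed=9,
        )
        frac = (ds.genotypes.dosages < 0).mean()
        assert 0.05 < frac < 0.15

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ConfigurationError):
            synth.make_study_like_dataset({"bogus": 1}, seed=0)

    def test_determinism(self):
        a = synth.make_study_like_dataset({"n_cohorts": 2, "cohort_size": 3, "L": 100}, seed=5)
        b = synth.make_study_like_dataset({"n_cohorts": 2, "cohort_size": 3, "L": 100}, seed=5)
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)


def _cohort_pairs(gm, cohort):
    from itertools import combinations

    idx = gm.cohort_indices(cohort)
    return [(gm.samples[i], gm.samples[j]) for i, j in combinations(idx.tolist(), 2)]
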