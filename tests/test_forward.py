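"""Forward simulator: stacks, sweepstake and relaxed reproduction, metapopulation."""

import numpy as np
import pytest

from cgpatch import forward
from cgpatch.errors import ConfigurationError, DataError
from cgpatch.seeding import stage_rng


def _pop(n_f, n_m, L=0):
    alloc = forward.IdAllocator()
    rng = stage_rng(0, "pop")
    pop = forward.founder_population(n_f + n_m, rng, alloc)
    pop.female = np.array([True] * n_f + [False] * n_m)
    return pop, alloc


class TestStacks:
    def test_exact_division(self):
        pop, _ = _pop(50, 50)
        stacks = forward.build_stacks(pop, 10, stage_rng(1, "s"))
        assert len(stacks) == 10
        assert all(f.size == 5 and m.size == 5 for f, m in stacks)

    def test_leftover_forms_smaller_balanced_stack(self):
        pop, _ = _pop(7, 5)
        stacks = forward.build_stacks(pop, 10, stage_rng(2, "s"))
        assert len(stacks) == 1
        f, m = stacks[0]
        assert f.size == 5 and m.size == 5  # 2 females left unstacked

    def test_partial_remainder(self):
        pop, _ = _pop(8, 7)
        stacks = forward.build_stacks(pop, 10, stage_rng(3, "s"))
        assert [(f.size, m.size) for f, m in stacks] == [(5, 5), (2, 2)]

    def test_odd_stack_size_rejected(self):
        pop, _ = _pop(5, 5)
        with pytest.raises(ConfigurationError):
            forward.build_stacks(pop, 9, stage_rng(0, "s"))

    def test_seeded_partition_reproducible(self):
        pop, _ = _pop(20, 20)
        a = forward.build_stacks(pop, 10, stage_rng(5, "s"))
        b = forward.build_stacks(pop, 10, stage_rng(5, "s"))
        for (fa, ma), (fb, mb) in zip(a, b):
            np.testing.assert_array_equal(fa, fb)
            np.testing.assert_array_equal(ma, mb)


class TestSweepstakeGeneration:
    def test_single_mother_all_close_kin(self):
        pop, alloc = _pop(50, 50)
        off = forward.sweepstake_generation(
            pop, forward.SweepstakeParams(F=1, K=100, St=10), stage_rng(1, "g"), alloc
        )
        assert off.size == 100
        assert np.unique(off.mother).size == 1
        comp = forward.sample_kinship_composition(off, np.arange(100))
        assert comp["unrelated"] == 0.0

    def test_offspring_count_equals_K(self):
        pop, alloc = _pop(30, 30)
        off = forward.sweepstake_generation(
            pop, forward.SweepstakeParams(F=2, K=57, St=10), stage_rng(2, "g"), alloc
        )
        assert off.size == 57

    def test_full_sib_fraction_one_fifth(self):
        """With F=1 and 5 stack males, P(shared father) = 1/5 over offspring pairs."""
        fracs = []
        for rep in range(20):
            pop, alloc = _pop(20, 20)
            off = forward.sweepstake_generation(
                pop, forward.SweepstakeParams(F=1, K=500, St=10), stage_rng(100 + rep, "g"), alloc
            )
            _, counts = np.unique(off.father, return_counts=True)
            n = off.size
            fracs.append((counts * (counts - 1)).sum() / (n * (n - 1)))
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.2) < 3 * se

    def test_param_invariants(self):
        with pytest.raises(ConfigurationError):
            forward.SweepstakeParams(F=6, K=100, St=10)  # F > St/2
        with pytest.raises(ConfigurationError):
            forward.SweepstakeParams(F=1, K=100, St=9)
        with pytest.raises(ConfigurationError):
            forward.SweepstakeParams(F=1, K=0, St=10)


class TestPedigreeKinship:
    def test_categories(self):
        pop = forward.Population(
            ids=np.arange(3),
            female=np.array([True, False, True]),
            mother=np.array([10, 10, 12]),
            father=np.array([20, 21, 22]),
        )
        assert forward.pedigree_kinship(pop, 0, 1) == "half-sib"
        assert forward.pedigree_kinship(pop, 0, 2) == "unrelated"
        pop.father[1] = 20
        assert forward.pedigree_kinship(pop, 0, 1) == "full-sib"

    def test_missing_parent_record_is_error(self):
        pop = forward.Population(
            ids=np.arange(2),
            female=np.array([True, False]),
            mother=np.array([-1, 10]),
            father=np.array([-1, 20]),
        )
        with pytest.raises(DataError):
            forward.pedigree_kinship(pop, 0, 1)


class TestSinglePopExperiment:
    def test_single_female_always_succeeds(self):
        res = forward.run_single_pop_experiment(
            forward.SweepstakeParams(F=1, K=200, St=10), replicates=20, seed=11
        )
        assert res.success_proportion == 1.0

    def test_tiny_sample_subset_of_certainty(self):
        res = forward.run_single_pop_experiment(
            forward.SweepstakeParams(F=1, K=100, St=10), replicates=10, sample_size=2, seed=12
        )
        assert res.success_proportion == 1.0

    def test_kinship_fractions_sum_to_one(self):
        res = forward.run_single_pop_experiment(
            forward.SweepstakeParams(F=3, K=200, St=10), replicates=10, seed=13
        )
        sums = res.table[["frac_unrelated", "frac_half_sib", "frac_full_sib"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0)

    def test_relaxed_mode_rarely_succeeds(self):
        res = forward.run_single_pop_experiment(
            forward.SweepstakeParams(F=5, K=500, St=10), replicates=30, seed=14, mode="relaxed"
        )
        assert res.success_proportion <= 0.05

    def test_offspring_diversity_below_founder_diversity(self):
        res = forward.run_single_pop_experiment(
            forward.SweepstakeParams(F=1, K=200, St=10), replicates=50, seed=15, L=300
        )
        assert res.table["pi_offspring"].mean() < res.table["pi_founders"].mean()

    def test_determinism(self):
        a = forward.run_single_pop_experiment(forward.SweepstakeParams(F=2, K=100, St=10), replicates=5, seed=16)
        b = forward.run_single_pop_experiment(forward.SweepstakeParams(F=2, K=100, St=10), replicates=5, seed=16)
        assert a.table.equals(b.table)


class TestMetapopulation:
    def _demes(self, sw, mp, seed=0, L=200):
        from cgpatch.synth import draw_founder_frequencies

        rng = stage_rng(seed, "mp")
        alloc = forward.IdAllocator()
        pool = draw_founder_frequencies(L, seed=seed)
        demes = [forward.founder_population(sw.K, rng, alloc, pool=pool) for _ in range(5)]
        return demes, rng, alloc

    def test_regulation_all_demes_at_K(self):
        sw, mp = forward.SweepstakeParams(F=1, K=300, St=10), forward.MetapopParams(CD=0.5)
        demes, rng, alloc = self._demes(sw, mp)
        out = forward.metapop_generation(demes, mp, sw, rng, alloc)
        assert [d.size for d in out] == [300] * 5

    def test_full_collective_dispersal_gives_family_sink(self):
        sw = forward.SweepstakeParams(F=1, K=300, St=10)
        mp = forward.MetapopParams(CD=1.0, m=0.0)
        demes, rng, alloc = self._demes(sw, mp, seed=1)
        out = forward.metapop_generation(demes, mp, sw, rng, alloc)
        comp = forward.sample_kinship_composition(out[mp.sink_index], np.arange(300))
        assert comp["unrelated"] == 0.0

    def test_no_dispersal_keeps_sink_unrelated(self):
        sw = forward.SweepstakeParams(F=1, K=300, St=10)
        mp = forward.MetapopParams(CD=0.0, m=0.0)
        demes, rng, alloc = self._demes(sw, mp, seed=2)
        out = forward.metapop_generation(demes, mp, sw, rng, alloc)
        rng2 = stage_rng(3, "sample")
        comp = forward.sample_kinship_composition(
            out[mp.sink_index], rng2.choice(300, 10, replace=False)
        )
        assert comp["unrelated"] > 0.9

    def test_ids_stay_unique_across_demes(self):
        sw = forward.SweepstakeParams(F=1, K=100, St=10)
        mp = forward.MetapopParams(CD=0.7, m=0.1)
        demes, rng, alloc = self._demes(sw, mp, seed=3)
        out = forward.metapop_generation(demes, mp, sw, rng, alloc)
        all_ids = np.concatenate([d.ids for d in out])
        assert np.unique(all_ids).size == all_ids.size

    def test_invalid_metapop_params(self):
        with pytest.raises(ConfigurationError):
            forward.MetapopParams(CD=1.2)
        with pytest.raises(ConfigurationError):
            forward.MetapopParams(m=0.6)
        with pytest.raises(ConfigurationError):
            forward.MetapopParams(source_index=2, sink_index=2)


class TestDecayExperiment:
    def test_requires_successful_regime(self):
        with pytest.raises(ConfigurationError):
            forward.run_decay_experiment(mp=forward.MetapopParams(CD=0.5), replicates=1, seed=0)

    def test_close_kin_vanish_after_event(self):
        res = forward.run_decay_experiment(
            sw=forward.SweepstakeParams(F=1, K=300, St=10), replicates=3, L=200, seed=21
        )
        sink = res.table[res.table.is_sink]
        gen0 = sink[sink.generation == 0]
        later = sink[sink.generation == 2]
        assert (gen0.frac_unrelated == 0.0).all()
        assert (later.frac_unrelated > 0.9).all()
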