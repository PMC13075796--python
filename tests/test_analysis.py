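"""Conservation, pruning, importance, divergence, robustness."""

import numpy as np
import pytest

import samdrift as sd
from samdrift.analysis import (BooleanAdjacency, bimodality_coefficient,
                               boolean_adjacency, conservation_times,
                               conserved_set, divergence, divergence_series,
                               importance, mean_fitness, prune,
                               robustness_assay)
from samdrift.config import DevConfig, MutationRates
from samdrift.genome import Gene, Genome, Interaction, Tfbs, genome_to_grn

from conftest import all_cz_fitness_config

I = Interaction


def _sets(*gens):
    """Helper: interaction sets per generation from tuples."""
    return [frozenset(I(*t) for t in g) for g in gens]


class TestConservation:
    def test_always_present_spans_trace(self):
        sets = _sets(*[[(0, 12, 1)]] * 7)
        (rec,) = conservation_times(sets)
        assert rec.max_duration == 7
        assert rec.intervals == [(0, 6)]

    def test_run_length_arithmetic(self):
        # present for generations 10..6009 inclusive: duration 6000
        sets = [frozenset()] * 10 + _sets(*[[(1, 13, -1)]] * 6000) \
            + [frozenset()] * 5
        (rec,) = conservation_times(sets)
        assert rec.max_duration == 6000
        assert conserved_set(sets, cutoff=5000) == {I(1, 13, -1)}
        assert conserved_set(sets, cutoff=6000) == frozenset()

    def test_gap_resets_run(self):
        sets = _sets([(0, 12, 1)], [], [(0, 12, 1)], [(0, 12, 1)])
        (rec,) = conservation_times(sets)
        assert rec.intervals == [(0, 0), (2, 3)]
        assert rec.max_duration == 2

    def test_empty_trace(self):
        assert conservation_times([]) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_membership_scan(self, seed):
        rng = np.random.default_rng(seed)
        universe = [I(int(r), int(t), s)
                    for r in range(3) for t in range(3) for s in (-1, 1)]
        sets = [frozenset(ia for ia in universe if rng.random() < 0.4)
                for _ in range(60)]
        records = {r.interaction: r for r in conservation_times(sets)}
        for ia in universe:
            # oracle: longest run by direct scanning
            best = cur = 0
            for s in sets:
                cur = cur + 1 if ia in s else 0
                best = max(best, cur)
            if best == 0:
                assert ia not in records
            else:
                assert records[ia].max_duration == best


class TestBooleanAdjacency:
    def test_empty(self):
        ba = boolean_adjacency([])
        assert ba.activating.sum() == 0 and ba.inhibiting.sum() == 0

    def test_sign_separation(self):
        ba = boolean_adjacency([I(0, 12, 1), I(1, 12, -1)])
        assert ba.activating[12, 0] == 1 and ba.activating.sum() == 1
        assert ba.inhibiting[12, 1] == 1 and ba.inhibiting.sum() == 1

    def test_copy_numbers_discarded(self):
        g = Genome(elements=[Tfbs(0, 1, 10.0), Tfbs(0, 1, 20.0),
                             Gene(12, 5.0, 0.1)])
        ba = boolean_adjacency(genome_to_grn(g))
        assert ba.activating.sum() == 1


class TestDivergence:
    def test_identity(self):
        s = frozenset([I(0, 12, 1), I(1, 13, -1)])
        assert divergence(s, s) == 0.0

    def test_disjoint_same_sign_sets(self):
        a = frozenset([I(0, 12, 1), I(2, 13, -1)])
        b = frozenset([I(1, 12, 1), I(3, 13, -1)])
        assert divergence(a, b) == 1.0

    def test_both_empty(self):
        assert divergence(frozenset(), frozenset()) == 0.0

    def test_hand_worked_example(self):
        # activating matrices [[1,0],[0,1]] vs [[1,0],[1,1]], identical
        # inhibiting parts: d_act = 1/5, d_inh = 0, div = 0.1
        a = frozenset([I(0, 0, 1), I(1, 1, 1), I(0, 2, -1)])
        b = frozenset([I(0, 0, 1), I(0, 1, 1), I(1, 1, 1), I(0, 2, -1)])
        assert divergence(a, b) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_set_arithmetic_oracle(self, seed):
        # brute force: divergence per sign equals symmetric difference
        # over union-with-multiplicity of the interaction-presence sets
        rng = np.random.default_rng(seed)
        universe = [(r, t, s) for r in range(4) for t in range(4)
                    for s in (-1, 1)]
        for _ in range(250):
            a = frozenset(I(*u) for u in universe if rng.random() < 0.3)
            b = frozenset(I(*u) for u in universe if rng.random() < 0.3)

            def d_oracle(x, y, sign):
                xs = {(i.regulator, i.target) for i in x if i.sign == sign}
                ys = {(i.regulator, i.target) for i in y if i.sign == sign}
                tot = len(xs) + len(ys)
                if tot == 0:
                    return 0.0
                return len(xs ^ ys) / tot
            expected = 0.5 * (d_oracle(a, b, 1) + d_oracle(a, b, -1))
            got = divergence(a, b)
            assert got == pytest.approx(expected)
            assert got == pytest.approx(divergence(b, a))
            assert 0.0 <= got <= 1.0
            if got == 0.0:
                ba, bb = boolean_adjacency(a), boolean_adjacency(b)
                assert (ba.activating == bb.activating).all()
                assert (ba.inhibiting == bb.inhibiting).all()


class TestDivergenceSeries:
    def test_zero_at_cloning_generation(self):
        ca = frozenset([I(0, 12, 1)])
        traces = [[ca, ca], [ca, frozenset([I(1, 12, 1)])]]
        out = divergence_series(traces, "full_CA", ca=ca)
        assert out["median"][0] == 0.0

    def test_mutation_free_clones_stay_flat(self):
        ca = frozenset([I(0, 12, 1), I(3, 13, -1)])
        traces = [[ca] * 5, [ca] * 5]
        for mode in ("full_CA", "core_CA", "core_pairwise"):
            out = divergence_series(traces, mode, ca=ca, conserved=ca)
            assert np.all(out["median"] == 0.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            divergence_series([[frozenset()], [frozenset()] * 2], "full_CA",
                              ca=frozenset())


@pytest.fixture(scope="module")
def essential_toy():
    """One activator chain into the CZ fitness gene on an all-CZ tissue:
    removing the single interaction abolishes all fitness."""
    genome = Genome(elements=[Tfbs(4, 1, 50.0), Gene(13, 5.0, 0.1),
                              Tfbs(0, 1, 100.0), Gene(5, 5.0, 0.1)])
    cfg = sd.desk_config(0).dev
    cfg = DevConfig(**{**cfg.__dict__})
    cfg.noise = False
    return genome, cfg, all_cz_fitness_config()


class TestImportance:
    def test_essential_interaction_scores_one(self, essential_toy,
                                              all_cz_tissue):
        genome, dev_cfg, fit_cfg = essential_toy
        rng = np.random.default_rng(0)
        i = importance(genome, Interaction(4, 13, 1), [all_cz_tissue],
                       dev_cfg, rng, n_reps=3, fitness_config=fit_cfg)
        assert i == 1.0

    def test_inert_interaction_scores_zero(self, essential_toy,
                                           all_cz_tissue):
        genome, dev_cfg, fit_cfg = essential_toy
        rng = np.random.default_rng(0)
        i = importance(genome, Interaction(0, 5, 1), [all_cz_tissue],
                       dev_cfg, rng, n_reps=3, fitness_config=fit_cfg)
        assert i == 0.0

    def test_halved_fitness_scores_half(self, essential_toy, all_cz_tissue):
        # relative to a reference twice the post-removal fitness, removal
        # "halves" fitness: Eq arithmetic gives exactly 0.5
        genome, dev_cfg, fit_cfg = essential_toy
        rng = np.random.default_rng(0)
        f_inert = mean_fitness(genome, [all_cz_tissue], dev_cfg,
                               np.random.default_rng(1), n_reps=1,
                               fitness_config=fit_cfg)
        i = importance(genome, Interaction(0, 5, 1), [all_cz_tissue],
                       dev_cfg, rng, n_reps=3, fitness_config=fit_cfg,
                       reference_fitness=2 * f_inert)
        assert i == pytest.approx(0.5)

    def test_noise_off_invariant_to_replicates(self, essential_toy,
                                               all_cz_tissue):
        genome, dev_cfg, fit_cfg = essential_toy
        vals = [importance(genome, Interaction(4, 13, 1), [all_cz_tissue],
                           dev_cfg, np.random.default_rng(s), n_reps=r,
                           fitness_config=fit_cfg)
                for s, r in ((0, 1), (1, 4))]
        assert vals[0] == vals[1]

    def test_absent_interaction_rejected(self, essential_toy,
                                         all_cz_tissue):
        genome, dev_cfg, fit_cfg = essential_toy
        with pytest.raises(ValueError):
            importance(genome, Interaction(9, 13, 1), [all_cz_tissue],
                       dev_cfg, np.random.default_rng(0), n_reps=1,
                       fitness_config=fit_cfg)

    def test_zero_reference_fitness_rejected(self, all_cz_tissue):
        genome = Genome(elements=[Tfbs(5, 1, 50.0), Gene(13, 5.0, 0.1)])
        cfg = sd.desk_config(0).dev
        cfg.noise = False
        with pytest.raises(ValueError):
            importance(genome, Interaction(5, 13, 1), [all_cz_tissue], cfg,
                       np.random.default_rng(0), n_reps=1,
                       fitness_config=all_cz_fitness_config())


class TestPrune:
    def test_inert_tfbs_removed(self, all_cz_tissue):
        genome = Genome(elements=[Tfbs(4, 1, 50.0), Gene(13, 5.0, 0.1),
                                  Tfbs(0, 1, 100.0)])  # trailing site inert
        cfg = sd.desk_config(0).dev
        cfg.noise = False
        pruned, grn = prune(genome, [all_cz_tissue], cfg,
                            np.random.default_rng(0), n_reps=1,
                            fitness_config=all_cz_fitness_config())
        kinds = [type(e).__name__ for e in pruned.elements]
        assert kinds.count("Tfbs") == 1
        assert grn == {Interaction(4, 13, 1)}

    def test_essential_genome_unchanged(self, all_cz_tissue):
        genome = Genome(elements=[Tfbs(4, 1, 50.0), Gene(13, 5.0, 0.1)])
        cfg = sd.desk_config(0).dev
        cfg.noise = False
        pruned, _ = prune(genome, [all_cz_tissue], cfg,
                          np.random.default_rng(0), n_reps=1,
                          fitness_config=all_cz_fitness_config())
        assert pruned.to_text() == genome.to_text()

    def test_never_grows_genome(self, all_cz_tissue):
        rng = np.random.default_rng(2)
        genome = sd.init_genome(rng, sd.GenomeConfig())
        cfg = sd.desk_config(0).dev
        cfg.noise = False
        pruned, _ = prune(genome, [all_cz_tissue], cfg, rng, n_reps=1,
                          fitness_config=all_cz_fitness_config())
        assert len(pruned) <= len(genome)


class TestRobustness:
    def test_zero_rates_all_unmutated(self, all_cz_tissue):
        genome = Genome(elements=[Tfbs(4, 1, 50.0), Gene(13, 5.0, 0.1)])
        cfg = sd.desk_config(0).dev
        cfg.noise = False
        res = robustness_assay(genome, 20, [all_cz_tissue], cfg,
                               MutationRates().zeroed(),
                               np.random.default_rng(0),
                               fitness_config=all_cz_fitness_config())
        assert res.unmutated.size == 20 and res.mutated.size == 0

    def test_deterministic_single_template_zero_variance(self,
                                                         all_cz_tissue):
        genome = Genome(elements=[Tfbs(4, 1, 50.0), Gene(13, 5.0, 0.1)])
        cfg = sd.desk_config(0).dev
        cfg.noise = False
        res = robustness_assay(genome, 10, [all_cz_tissue], cfg,
                               MutationRates().zeroed(),
                               np.random.default_rng(0),
                               fitness_config=all_cz_fitness_config())
        assert np.ptp(res.unmutated) == 0.0
        assert res.summary()["unmutated"]["iqr"] == 0.0


class TestBimodality:
    def test_separated_mixture_flags_bimodal(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 0.5, 400),
                            rng.normal(10, 0.5, 350)])
        assert bimodality_coefficient(x) > 5 / 9

    def test_gaussian_is_unimodal(self):
        rng = np.random.default_rng(1)
        assert bimodality_coefficient(rng.normal(0, 1, 800)) < 5 / 9
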