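import numpy as np
import pytest

from gashap import LabelAtlas
from gashap.ga import (
    ClassifierMaskEvaluator,
    GAConfig,
    GARunResult,
    PlantedRegionEvaluator,
    crossover,
    fitness,
    intersect_runs,
    mutate,
    prune_initial_regions,
    roulette_select,
    run_ga,
    tournament_select,
)
from gashap.morphology import StructuringElement, build_mask


def flat_atlas(R, reps=1):
    """Every region = `reps` consecutive voxels on a line-like grid."""
    labels = np.repeat(np.arange(1, R + 1), reps).reshape(R * reps, 1, 1)
    return LabelAtlas(
        labels=labels,
        region_ids=np.arange(1, R + 1),
        region_names=[f"r{i}" for i in range(1, R + 1)],
    )


class _FixedF1:
    """Evaluator stub returning a constant masked accuracy."""

    def __init__(self, f1):
        self.f1 = f1

    def __call__(self, mask):
        return None, self.f1


def genes_with(R, nonzero):
    g = np.zeros(R, dtype=np.uint8)
    g[:nonzero] = 2
    return g


class TestFitness:
    def test_maximum_attained_at_single_perfect_region(self):
        atlas = flat_atlas(4)
        rec = fitness(genes_with(4, 1), _FixedF1(1.0), atlas)
        assert rec.fitness == pytest.approx(1.0, abs=1e-9)
        assert rec.f2 == 1.0 and rec.n_regions == 1

    def test_weighted_combination(self):
        atlas = flat_atlas(16)
        rec = fitness(genes_with(16, 11), _FixedF1(0.85), atlas)
        assert rec.fitness == pytest.approx(0.975 * 0.85 + 0.025 / 11, abs=1e-9)
        assert rec.fitness == pytest.approx(0.8310227272727273, abs=1e-6)

    def test_worst_case_all_regions_zero_accuracy(self):
        atlas = flat_atlas(96)
        rec = fitness(genes_with(96, 96), _FixedF1(0.0), atlas)
        assert rec.fitness == pytest.approx(0.025 / 96, abs=1e-9)

    def test_literal_weight_pairing_switch(self):
        atlas = flat_atlas(8)
        cfg = GAConfig(weight_pairing="literal")
        rec = fitness(genes_with(8, 4), _FixedF1(0.8), atlas, cfg=cfg)
        assert rec.fitness == pytest.approx(0.025 * 0.8 + 0.975 * 0.25, abs=1e-9)

    def test_all_zero_chromosome_rejected(self):
        atlas = flat_atlas(4)
        with pytest.raises(ValueError, match="all-zero"):
            fitness(np.zeros(4, dtype=np.uint8), _FixedF1(1.0), atlas)

    def test_fitness_decreases_in_region_count(self):
        atlas = flat_atlas(10)
        recs = [fitness(genes_with(10, n), _FixedF1(0.9), atlas) for n in (1, 3, 7)]
        assert recs[0].fitness > recs[1].fitness > recs[2].fitness

    def test_config_requires_convex_weights(self):
        with pytest.raises(ValueError, match="alpha"):
            GAConfig(alpha=0.1, beta=0.975)


class TestSelection:
    def test_single_member_always_chosen(self, rng):
        assert roulette_select(np.array([0.4]), rng) == 0

    def test_proportional_frequencies(self, rng):
        draws = np.array([roulette_select(np.array([1.0, 3.0]), rng) for _ in range(10000)])
        freq = (draws == 1).mean()
        sigma = np.sqrt(0.75 * 0.25 / 10000)
        assert abs(freq - 0.75) < 3 * sigma

    def test_equal_fitness_is_uniform(self, rng):
        draws = np.array([roulette_select(np.ones(4), rng) for _ in range(8000)])
        freqs = np.bincount(draws, minlength=4) / 8000
        assert np.abs(freqs - 0.25).max() < 3 * np.sqrt(0.25 * 0.75 / 8000)

    def test_nonpositive_fitness_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            roulette_select(np.array([0.5, 0.0]), rng)

    def test_tournament_prefers_fitter(self, rng):
        fits = np.array([0.1, 0.9])
        draws = [tournament_select(fits, rng, size=2) for _ in range(2000)]
        assert np.mean(np.array(draws) == 1) > 0.6


class TestCrossover:
    def test_identical_parents_reproduce(self, rng):
        a = np.array([1, 2, 3, 0, 2], dtype=np.uint8)
        for _ in range(20):
            np.testing.assert_array_equal(crossover(a, a, rng), a)

    def test_offspring_is_prefix_suffix(self, rng):
        R = 8
        a = np.full(R, 3, dtype=np.uint8)
        b = np.full(R, 1, dtype=np.uint8)
        seen = set()
        for _ in range(500):
            child = crossover(a, b, rng)
            n = int((child == 3).sum())
            assert 1 <= n <= R
            np.testing.assert_array_equal(child[:n], 3)
            np.testing.assert_array_equal(child[n:], 1)
            seen.add(n)
        assert seen == set(range(1, R + 1))  # every cut point attainable

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="equal length"):
            crossover(np.zeros(3, np.uint8), np.zeros(4, np.uint8), rng)


class TestMutate:
    def test_pm_zero_is_identity(self, rng):
        g = np.array([0, 1, 2, 3], dtype=np.uint8)
        for _ in range(20):
            np.testing.assert_array_equal(mutate(g, rng, pm=0.0), g)

    def test_hamming_distance_at_most_one(self, rng):
        g = rng.integers(0, 4, size=20).astype(np.uint8)
        for _ in range(200):
            out = mutate(g, rng, pm=1.0)
            assert (out != g).sum() <= 1

    def test_single_gene_uniform_distribution(self, rng):
        g = np.array([2], dtype=np.uint8)
        draws = np.array([mutate(g, rng, pm=1.0)[0] for _ in range(8000)])
        freqs = np.bincount(draws, minlength=4) / 8000
        assert np.abs(freqs - 0.25).max() < 3 * np.sqrt(0.25 * 0.75 / 8000)

    def test_frozen_positions_untouched(self, rng):
        g = np.array([1, 1, 1, 1], dtype=np.uint8)
        allowed = np.array([False, True, False, False])
        for _ in range(100):
            out = mutate(g, rng, pm=1.0, allowed=allowed)
            np.testing.assert_array_equal(out[[0, 2, 3]], 1)


class TestPruning:
    def test_unanimity_keeps_any_supported_region(self):
        pop = [np.array([2, 0, 0], np.uint8), np.array([0, 0, 0], np.uint8)]
        res = prune_initial_regions(pop, theta=1.0)
        assert res.active[0] and res.n_active == 1

    def test_universally_ignored_region_frozen(self):
        pop = [np.array([2, 0, 1], np.uint8), np.array([1, 0, 3], np.uint8)]
        res = prune_initial_regions(pop, theta=1.0)
        assert not res.active[1]

    def test_majority_rule_on_constructed_population(self):
        pop = [
            np.array([2, 0, 1, 0], np.uint8),
            np.array([3, 0, 0, 1], np.uint8),
            np.array([1, 2, 0, 0], np.uint8),
        ]
        # zero fractions: (0, 2/3, 2/3, 2/3); theta=0.5 freezes regions 1,2,3
        res = prune_initial_regions(pop, theta=0.5)
        np.testing.assert_array_equal(res.active, [True, False, False, False])
        for ch in res.population:
            assert (ch[1:] == 0).all()

    def test_pruning_everything_rejected(self):
        with pytest.raises(ValueError, match="every region"):
            prune_initial_regions([np.zeros(3, np.uint8)], theta=0.5)


class TestRunGA:
    def _population(self, rng, R, n):
        return [rng.integers(0, 4, size=R).astype(np.uint8) for _ in range(n)]

    def test_huge_stop_tol_terminates_after_one_generation(self, tiny_atlas, rng):
        pop = self._population(rng, tiny_atlas.R, 6)
        cfg = GAConfig(stop_tol=10.0, max_generations=50, seed=0)
        res = run_ga(pop, _FixedF1(0.5), tiny_atlas, cfg)
        assert res.n_generations == 1
        assert len(res.trajectory) == 2  # initialization + one generation

    def test_elitism_makes_best_fitness_monotone(self, tiny_atlas, rng):
        for seed in range(3):
            pop = self._population(np.random.default_rng(seed), tiny_atlas.R, 8)
            cfg = GAConfig(stop_tol=None, max_generations=15, seed=seed)
            res = run_ga(pop, _FixedF1(0.7), tiny_atlas, cfg)
            best = res.trajectory["best_fitness"].to_numpy()
            assert (np.diff(best) >= -1e-12).all()

    def test_population_size_constant(self, tiny_atlas, rng):
        pop = self._population(rng, tiny_atlas.R, 7)
        cfg = GAConfig(stop_tol=None, max_generations=10, seed=1)
        res = run_ga(pop, _FixedF1(0.5), tiny_atlas, cfg)
        assert res.population_sizes == [7] * 11

    def test_deterministic_for_seed(self, tiny_atlas, rng):
        pop = self._population(rng, tiny_atlas.R, 6)
        cfg = GAConfig(stop_tol=None, max_generations=8, seed=4)
        a = run_ga([p.copy() for p in pop], _FixedF1(0.6), tiny_atlas, cfg)
        b = run_ga([p.copy() for p in pop], _FixedF1(0.6), tiny_atlas, cfg)
        np.testing.assert_array_equal(a.best_genes, b.best_genes)
        assert a.trajectory.equals(b.trajectory)

    def test_population_cap_subsamples_and_pads(self, tiny_atlas, rng):
        pop = self._population(rng, tiny_atlas.R, 10)
        for cap in (4, 14):
            cfg = GAConfig(stop_tol=10.0, population_cap=cap, seed=0)
            res = run_ga([p.copy() for p in pop], _FixedF1(0.5), tiny_atlas, cfg)
            assert res.population_sizes[0] == cap

    def test_recovers_planted_regions(self, tiny_atlas):
        """The GA converges onto exactly the planted region set."""
        planted = np.array([2, 5])
        evaluator = PlantedRegionEvaluator(tiny_atlas, planted)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            pop = self._population(rng, tiny_atlas.R, 10)
            cfg = GAConfig(stop_tol=None, max_generations=40, seed=seed)
            res = run_ga(pop, evaluator, tiny_atlas, cfg)
            selected = res.selected_regions
            assert set(planted.tolist()) <= selected  # recall 1.0
            assert len(selected) <= 4  # precision >= 0.5


class TestIntersectRuns:
    def _result(self, atlas, nonzero):
        genes = np.zeros(atlas.R, dtype=np.uint8)
        genes[np.asarray(nonzero) - 1] = 2
        return GARunResult(
            best_genes=genes,
            best_record=None,
            best_mask=build_mask(genes, atlas),
            trajectory=None,
            atlas=atlas,
            config=GAConfig(),
            initial_active_regions=atlas.R,
            n_generations=0,
        )

    def test_identical_runs(self, tiny_atlas):
        a = self._result(tiny_atlas, [1, 3])
        assert intersect_runs(a, a) == {1, 3}

    def test_disjoint_runs(self, tiny_atlas):
        a = self._result(tiny_atlas, [1, 2])
        b = self._result(tiny_atlas, [3, 4])
        assert intersect_runs(a, b) == set()

    def test_partial_overlap(self):
        atlas = flat_atlas(20)
        a = self._result(atlas, [4, 9, 11])
        b = self._result(atlas, [9, 11, 20])
        assert intersect_runs(a, b) == {9, 11}

    def test_atlas_mismatch_rejected(self, tiny_atlas):
        a = self._result(tiny_atlas, [1])
        b = self._result(flat_atlas(6), [1])
        with pytest.raises(ValueError, match="atlas"):
            intersect_runs(a, b)
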