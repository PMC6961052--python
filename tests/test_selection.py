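"""Metaheuristic band selection: GA, binary PSO, ACO ranking, stopping rule."""

from itertools import product

import numpy as np
import pytest

from hsiband import (
    ACOConfig,
    GAConfig,
    LabeledDataset,
    PSOConfig,
    aco_rank,
    aco_topk_evaluate,
    fisher_scores,
    ga_select,
    penalized,
    pso_select,
    stopping_rule,
)
from hsiband.selection import _CachedFitness

N_TOY = 12


def single_band_oracle(mask):
    """Toy fitness: perfect base metric iff band 7 is selected; optimum is the
    singleton {7} once size is penalized."""
    mask = np.asarray(mask, dtype=bool)
    base = 1.0 if mask[7] else 0.0
    return penalized(base, max(1, int(mask.sum())), mask.size)


def brute_force_optimum(fitness_fn, n_bands):
    best = np.inf
    for bits in product([0, 1], repeat=n_bands):
        mask = np.array(bits, dtype=bool)
        if not mask.any():
            continue
        best = min(best, float(fitness_fn(mask).value))
    return best


class TestStoppingRule:
    def test_strictly_improving_continues(self):
        assert not stopping_rule([5.0, 4.0, 3.0, 2.0, 1.0], patience=3, epsilon=0.1)

    def test_flat_trace_stops(self):
        assert stopping_rule([1.0] * 10, patience=3, epsilon=1e-6)

    def test_improvement_exactly_epsilon_continues(self):
        trace = [2.0, 2.0, 2.0, 1.0]  # improvement == epsilon exactly
        assert not stopping_rule(trace, patience=3, epsilon=1.0)

    def test_short_trace_never_stops(self):
        assert not stopping_rule([1.0, 1.0], patience=5, epsilon=1e-6)


class TestGA:
    @pytest.mark.parametrize("seed", range(10))
    def test_single_band_oracle_recovered(self, seed):
        cfg = GAConfig(population_size=20, generations=50, seed=seed)
        subset, trace = ga_select(single_band_oracle, N_TOY, cfg)
        assert 7 in subset.indices
        assert subset.n_selected <= 3
        assert trace[-1] == 0.0

    def test_trace_non_increasing(self):
        subset, trace = ga_select(single_band_oracle, N_TOY, GAConfig(seed=1, generations=20))
        assert all(a >= b for a, b in zip(trace, trace[1:]))

    def test_identical_population_no_mutation_is_constant(self):
        cfg = GAConfig(
            population_size=8, generations=10, mutation_rate=0.0, init_density=1.0, seed=0
        )
        _, trace = ga_select(single_band_oracle, N_TOY, cfg)
        assert len(set(trace)) == 1

    def test_full_elitism_freezes_population(self):
        cfg = GAConfig(population_size=8, elitism_count=8, generations=15, seed=2)
        _, trace = ga_select(single_band_oracle, N_TOY, cfg)
        assert trace[-1] == trace[0]

    def test_returned_fitness_matches_recomputation(self):
        subset, trace = ga_select(single_band_oracle, N_TOY, GAConfig(seed=3, generations=30))
        assert float(single_band_oracle(subset.to_mask()).value) == trace[-1]


class TestPSO:
    @pytest.mark.parametrize("seed", range(10))
    def test_single_band_oracle_recovered(self, seed):
        cfg = PSOConfig(n_particles=20, iterations=50, seed=seed)
        subset, trace = pso_select(single_band_oracle, N_TOY, cfg)
        assert 7 in subset.indices
        assert trace[-1] == 0.0

    def test_frozen_dynamics_keep_gbest(self):
        """alpha=c1=c2=0 zeroes velocity updates; positions are re-sampled from
        sigmoid(0)=0.5 but gbest can only improve, never regress."""
        cfg = PSOConfig(n_particles=10, iterations=5, alpha=0.0, c1=0.0, c2=0.0, seed=4)
        _, trace = pso_select(single_band_oracle, N_TOY, cfg)
        assert all(a >= b for a, b in zip(trace, trace[1:]))

    def test_trace_non_increasing(self):
        _, trace = pso_select(single_band_oracle, N_TOY, PSOConfig(seed=5, iterations=25))
        assert all(a >= b for a, b in zip(trace, trace[1:]))

    def test_returned_fitness_matches_recomputation(self):
        subset, trace = pso_select(single_band_oracle, N_TOY, PSOConfig(seed=6, iterations=30))
        assert float(single_band_oracle(subset.to_mask()).value) == trace[-1]


class TestBruteForceOptimality:
    """On exhaustively searchable 12-band landscapes both optimizers find the
    global optimum in (at least) 9 of 10 seeds."""

    @staticmethod
    def landscape(seed):
        rng = np.random.default_rng(1000 + seed)
        informative = rng.choice(N_TOY, size=2, replace=False)
        w = rng.uniform(0.3, 0.5, size=2)

        def fitness(mask):
            mask = np.asarray(mask, dtype=bool)
            base = w[0] * mask[informative[0]] + w[1] * mask[informative[1]]
            return penalized(min(1.0, base), max(1, int(mask.sum())), mask.size)

        return fitness

    def test_ga_matches_brute_force(self):
        hits = 0
        for seed in range(10):
            fit = self.landscape(seed)
            optimum = brute_force_optimum(fit, N_TOY)
            _, trace = ga_select(fit, N_TOY, GAConfig(population_size=30, generations=60, seed=seed))
            hits += np.isclose(trace[-1], optimum)
        assert hits >= 9

    def test_pso_matches_brute_force(self):
        hits = 0
        for seed in range(10):
            fit = self.landscape(seed)
            optimum = brute_force_optimum(fit, N_TOY)
            _, trace = pso_select(fit, N_TOY, PSOConfig(n_particles=30, iterations=60, seed=seed))
            hits += np.isclose(trace[-1], optimum)
        assert hits >= 9


class TestSizePreference:
    def test_equal_base_prefers_fewer_bands(self):
        """When many masks tie on the base metric, the search settles on a
        small subset (penalization + tie-break pressure)."""

        def flat_fitness(mask):
            mask = np.asarray(mask, dtype=bool)
            return penalized(1.0, max(1, int(mask.sum())), mask.size)

        subset, _ = ga_select(flat_fitness, N_TOY, GAConfig(population_size=20, generations=40, seed=0))
        assert subset.n_selected <= 2


def _planted_dataset(seed, n=400, n_bands=20, info=(4, 13)):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 4, n)
    spectra = rng.normal(5, 1, (n, n_bands))
    spectra[:, info[0]] += labels * 1.2
    spectra[:, info[1]] += (labels == 1) * 2.5 - (labels == 2) * 1.5
    pids = np.array([f"P{i % 3}" for i in range(n)])
    return LabeledDataset(np.abs(spectra), labels, pids, pids)


class TestACO:
    def test_ranking_is_permutation(self):
        data = _planted_dataset(0)
        rank = aco_rank(data, ACOConfig(n_ants=5, iterations=5, subset_size=4, seed=0))
        assert sorted(rank.tolist()) == list(range(20))

    def test_planted_bands_ranked_on_top(self):
        data = _planted_dataset(1)
        rank = aco_rank(data, ACOConfig(n_ants=8, iterations=10, subset_size=5, seed=1))
        assert {4, 13} <= set(rank[:4].tolist())

    def test_zero_deposits_fall_back_to_heuristic_order(self):
        data = _planted_dataset(2)
        cfg = ACOConfig(n_ants=3, iterations=10, evaporation_rate=0.99, subset_size=4, seed=2)
        rank = aco_rank(data, cfg, quality_fn=lambda idx: 0.0)
        heur = fisher_scores(data)
        expected = np.lexsort((np.arange(20), -heur / (heur.max() + 1e-12)))
        assert rank.tolist() == expected.tolist()

    def test_single_class_rejected(self):
        data = _planted_dataset(3)
        single = data.subset(data.labels == 1)
        with pytest.raises(ValueError):
            aco_rank(single, ACOConfig(seed=0))

    def test_topk_evaluation_shapes(self):
        ranking = np.arange(20)[::-1]
        reports = aco_topk_evaluate(ranking, [5, 10, 20], lambda idx: len(idx))
        assert reports == {5: 5, 10: 10, 20: 20}
        with pytest.raises(ValueError):
            aco_topk_evaluate(ranking, [25], lambda idx: None)


def test_fitness_cache_avoids_reevaluation():
    calls = []

    def fitness(mask):
        calls.append(1)
        return float(mask.sum())

    cached = _CachedFitness(fitness)
    mask = np.zeros(10, dtype=bool)
    mask[3] = True
    assert cached(mask) == cached(mask) == 1.0
    assert len(calls) == 1
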