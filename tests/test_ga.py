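from itertools import combinations

import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone

from smcmn import (
    Chromosome,
    GASettings,
    InfeasibleInstanceError,
    SMCMNPathwayFinder,
    evolve,
    generate_planted_dataset,
    generate_random_instance,
)
from smcmn.clustering import build_cluster_index
from smcmn.ga import fitness, init_chromosome, init_population, recombine, select
from smcmn.scoring import SubsetScorer

from conftest import make_correlation, make_matrix, planted


@pytest.fixture
def chain_instance():
    """Only {ga, gb, gc} is feasible at (mu, nu) = (0.7, 0.5): the three are
    pairwise disjoint and strongly connected, while gd overlaps everything and
    has no network support."""
    A = make_matrix(
        {"ga": {0, 1}, "gb": {2, 3}, "gc": {4, 5}, "gd": {0, 2, 4}}, 6
    )
    W = make_correlation(
        A.gene_ids,
        {("ga", "gb"): 0.9, ("ga", "gc"): 0.9, ("gb", "gc"): 0.9},
    )
    index = build_cluster_index(A, W, 0.7, 0.5)
    return A, W, index


class TestSettings:
    @pytest.mark.parametrize(
        "kwargs", [{"K": 1}, {"rr": 1.5}, {"mu": -0.1}, {"maxt": 0}, {"pop_size": 1}]
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GASettings(**kwargs)

    def test_default_population_is_quarter_of_gene_count(self):
        assert GASettings().effective_pop_size(50) == 13
        assert GASettings().effective_pop_size(4) == 2  # floor of 2
        assert GASettings(pop_size=7).effective_pop_size(50) == 7

    def test_chromosome_requires_distinct_genes(self):
        with pytest.raises(ValueError):
            Chromosome(("ga", "ga"))


class TestInitialization:
    def test_single_feasible_chain_found_on_every_seed(self, chain_instance):
        A, W, index = chain_instance
        settings = GASettings(K=3, pop_size=2, seed=0)
        for seed in range(5):
            pop = init_population(A, W, index, settings, np.random.default_rng(seed))
            assert all(sorted(c.genes) == ["ga", "gb", "gc"] for c in pop)

    def test_empty_pool_is_a_retryable_failure_not_an_exception(self):
        # no gene pair is connected at nu=0.5, so no chromosome can grow
        A = make_matrix({"ga": {0}, "gb": {1}, "gc": {2}}, 3)
        W = make_correlation(A.gene_ids, {})
        index = build_cluster_index(A, W, 0.7, 0.5)
        settings = GASettings(K=3, pop_size=2)
        out = init_chromosome(A, W, index, settings, np.random.default_rng(0))
        assert out is None
        with pytest.raises(InfeasibleInstanceError, match="mu"):
            init_population(A, W, index, settings, np.random.default_rng(0))

    def test_population_has_requested_size_and_valid_chromosomes(self):
        A, W, _ = planted(n_samples=60, n_genes=20, seed=1)
        settings = GASettings(K=3, pop_size=50, seed=1)
        index = build_cluster_index(A, W, settings.mu, settings.nu)
        pop = init_population(A, W, index, settings, np.random.default_rng(1))
        assert len(pop) == 50
        assert all(len(set(c.genes)) == 3 for c in pop)


class TestFitness:
    def test_equals_combined_weight(self, fixture_b, zero_w3):
        settings = GASettings(K=3)
        X = Chromosome(("g1", "g2", "g3"))
        assert fitness(fixture_b, zero_w3, X, settings) == pytest.approx(1 + 16 / 27)

    def test_pure_function_of_the_gene_set(self, fixture_b, zero_w3):
        settings = GASettings(K=3)
        a = fitness(fixture_b, zero_w3, Chromosome(("g1", "g2", "g3")), settings)
        b = fitness(fixture_b, zero_w3, Chromosome(("g3", "g1", "g2")), settings)
        assert a == b

    def test_exhaustive_maximum_dominates(self):
        A, W = generate_random_instance(n_genes=8, seed=2)
        scorer = SubsetScorer(A, W)
        weights = [scorer.weight(list(c)) for c in combinations(range(8), 3)]
        settings = GASettings(K=3)
        for idx_set in combinations(range(8), 3):
            genes = tuple(A.gene_ids[j] for j in idx_set)
            assert fitness(A, W, Chromosome(genes), settings) <= max(weights) + 1e-12


class TestSelection:
    def test_identical_population_is_unchanged(self):
        pop = [Chromosome(("ga", "gb"), fitness=2.0)] * 4
        out = select(pop, pop[0], np.random.default_rng(0))
        assert out == pop

    def test_roulette_frequencies_proportional_to_fitness(self):
        strong = Chromosome(("ga", "gb"), fitness=3.0)
        weak = Chromosome(("gc", "gd"), fitness=1.0)
        rng = np.random.default_rng(42)
        counts = {strong.genes: 0, weak.genes: 0}
        for _ in range(10_000):
            out = select([strong, weak], strong, rng)
            counts[out[1].genes] += 1  # slot 0 is the pinned elite
        chi2 = stats.chisquare(
            [counts[strong.genes], counts[weak.genes]], f_exp=[7500, 2500]
        )
        assert chi2.pvalue > 1e-3

    def test_incumbent_best_always_survives(self):
        best = Chromosome(("ga", "gb"), fitness=5.0)
        weak = Chromosome(("gc", "gd"), fitness=0.1)
        out = select([weak, weak, weak], best, np.random.default_rng(0))
        assert best in out and len(out) == 3


class TestRecombination:
    def test_no_eligible_candidate_leaves_chromosome_unchanged(self, chain_instance):
        A, W, index = chain_instance
        settings = GASettings(K=3, seed=0)
        X = Chromosome(("ga", "gb", "gc"))
        # the only gene outside X is gd, which fails both c1 and the nu constraint
        for seed in range(5):
            assert recombine(X, A, W, index, settings, np.random.default_rng(seed)).genes == X.genes

    def test_min_support_drop_admits_exactly_one_swap(self):
        # ge is the weakest member; once dropped, gc is the only eligible gene
        A = make_matrix(
            {"ga": {0, 1, 2}, "gb": {3, 4, 5}, "gc": {6, 7, 8, 9}, "ge": {10}}, 11
        )
        W = make_correlation(
            A.gene_ids,
            {(a, b): 0.9 for a, b in combinations(A.gene_ids, 2)},
        )
        index = build_cluster_index(A, W, 0.7, 0.5)
        settings = GASettings(K=3, seed=0)
        X = Chromosome(("ga", "gb", "ge"))
        rng = np.random.default_rng(2)
        assert rng.random() < 0.5  # this seed takes the min-drop branch
        out = recombine(X, A, W, index, settings, np.random.default_rng(2))
        assert sorted(out.genes) == ["ga", "gb", "gc"]

    def test_output_always_has_k_distinct_genes(self):
        A, W, _ = planted(n_samples=60, n_genes=20, seed=3)
        settings = GASettings(K=3, seed=3)
        index = build_cluster_index(A, W, settings.mu, settings.nu)
        rng = np.random.default_rng(3)
        X = init_chromosome(A, W, index, settings, rng)
        for _ in range(20):
            X = recombine(X, A, W, index, settings, rng)
            assert len(set(X.genes)) == 3


class TestEvolve:
    def test_identical_seed_gives_identical_result(self):
        A, W, _ = planted(n_samples=80, n_genes=20, seed=4)
        settings = GASettings(K=3, seed=11, maxg=50, maxt=20)
        r1 = evolve(A, W, settings)
        r2 = evolve(A, W, settings)
        assert r1.best.genes == r2.best.genes
        assert r1.history == r2.history
        assert r1.generations_run == r2.generations_run

    def test_history_is_monotone_and_ends_at_best(self):
        A, W, _ = planted(n_samples=80, n_genes=20, seed=5)
        res = evolve(A, W, GASettings(K=3, seed=5, maxg=60, maxt=30))
        assert all(b >= a for a, b in zip(res.history, res.history[1:]))
        assert res.best.fitness == res.history[-1]

    def test_zero_generations_returns_best_of_initial_population(self):
        A, W, _ = planted(n_samples=80, n_genes=20, seed=6)
        res = evolve(A, W, GASettings(K=3, seed=6, maxg=0))
        assert res.generations_run == 0
        assert len(res.history) == 1
        assert res.best.fitness == res.history[0]

    def test_stagnation_stops_before_the_generation_cap(self):
        A, W, _ = planted(n_samples=80, n_genes=20, seed=7)
        res = evolve(A, W, GASettings(K=3, seed=7, maxg=1000, maxt=5))
        assert res.generations_run < 1000

    def test_k_larger_than_gene_count_is_an_error(self, fixture_b, zero_w3):
        with pytest.raises(ValueError, match="exceeds"):
            evolve(fixture_b, zero_w3, GASettings(K=4))


class TestEstimator:
    def test_fit_recovers_planted_module_and_sets_attributes(self):
        inst = generate_planted_dataset(seed=8)
        finder = SMCMNPathwayFinder(K=3, random_state=0).fit(inst.A, inst.W)
        assert sorted(finder.genes_) == sorted(inst.planted_genes)
        assert finder.score_.total == pytest.approx(finder.history_[-1])
        assert finder.n_generations_ == len(finder.history_) - 1

    def test_sklearn_param_protocol(self):
        finder = SMCMNPathwayFinder(K=4, nu=0.2)
        params = finder.get_params()
        assert params["K"] == 4 and params["nu"] == 0.2
        cloned = clone(finder)
        assert cloned.get_params() == params
        finder.set_params(maxg=10)
        assert finder.get_params()["maxg"] == 10

    def test_accepts_plain_arrays_and_transform_extracts_columns(self):
        A, W, _ = planted(n_samples=80, n_genes=16, seed=9)
        finder = SMCMNPathwayFinder(K=3, random_state=1)
        sub = finder.fit_transform(A.values, W.reindex(A.gene_ids).values)
        assert sub.shape == (80, 3)
        assert sub.sum() > 0
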