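"""Genome encoding and the evolutionary operators."""

import numpy as np
import pytest

from omniga.base_models import EFFORT_LEVELS, PARAM_GRIDS
from omniga.ga import (
    GENOME_LENGTH,
    GAConfig,
    FitnessVector,
    Genome,
    NodeGene,
    crossover,
    evaluate_fitness,
    evolve,
    init_population,
    mutate,
    random_genome,
    roulette_select,
    scale_fitness,
)


def _valid_gene(g: NodeGene) -> bool:
    return (
        -1 <= g.model_type <= 3
        and -0.65 <= g.threshold <= 0.65
        and len(g.param_bits) == 4
        and all(b in (0, 1) for b in g.param_bits + g.es_bits)
    )


class TestEncoding:
    def test_population_genomes_valid(self):
        pop = init_population(GAConfig(population_size=20, seed=4))
        assert len(pop) == 20
        for genome in pop:
            assert len(genome.genes) == GENOME_LENGTH
            assert all(_valid_gene(g) for g in genome.genes)

    def test_same_seed_identical_population(self):
        a = init_population(GAConfig(population_size=8, seed=3))
        b = init_population(GAConfig(population_size=8, seed=3))
        assert a == b

    def test_decode_spec_on_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            gene = random_genome(rng).genes[0]
            spec = gene.decode_spec(es_active=True)
            if gene.pruned:
                assert spec is None
                continue
            for name, value in spec.params.items():
                assert value in PARAM_GRIDS[spec.model_kind][name]
            assert spec.effort_fraction in EFFORT_LEVELS

    def test_effort_is_one_when_es_off(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            gene = random_genome(rng).genes[0]
            spec = gene.decode_spec(es_active=False)
            if spec is not None:
                assert spec.effort_fraction == 1.0

    def test_gene_range_validation(self):
        with pytest.raises(ValueError):
            NodeGene(4, 0.0, (0, 0, 0, 0))
        with pytest.raises(ValueError):
            NodeGene(0, 0.9, (0, 0, 0, 0))
        with pytest.raises(ValueError):
            Genome(tuple())

    def test_population_size_minimum(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=3)


class TestScaling:
    def test_stated_example(self):
        fv = FitnessVector(np.array([0.7, 0.5, 0.9]))
        np.testing.assert_allclose(scale_fitness(fv), [0.2, 0.0, 0.4])

    def test_all_equal_gives_zeros(self):
        fv = FitnessVector(np.array([0.6, 0.6, 0.6]))
        np.testing.assert_allclose(scale_fitness(fv), 0.0)

    def test_singleton(self):
        np.testing.assert_allclose(scale_fitness(FitnessVector(np.array([0.4]))), [0.0])

    def test_worst_is_zero(self):
        rng = np.random.default_rng(2)
        old = rng.random(10)
        scaled = scale_fitness(FitnessVector(old))
        assert scaled.min() == 0.0
        assert np.all(scaled >= 0)


class TestRoulette:
    def test_frequencies_match_exact_multinomial(self):
        """10^5 draws against exact probabilities, within 3 sigma."""
        scaled = np.array([0.2, 0.0, 0.4])
        probs = scaled / scaled.sum()
        rng = np.random.default_rng(7)
        n = 100_000
        draws = np.array([roulette_select(scaled, rng) for _ in range(n)])
        counts = np.bincount(draws, minlength=3)
        for i, p in enumerate(probs):
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(counts[i] - n * p) <= 3 * max(sigma, 1)

    def test_worst_never_selected(self):
        scaled = np.array([0.5, 0.0, 0.1])
        rng = np.random.default_rng(1)
        draws = {roulette_select(scaled, rng) for _ in range(2000)}
        assert 1 not in draws

    def test_all_zero_uniform_fallback(self):
        scaled = np.zeros(4)
        rng = np.random.default_rng(3)
        n = 40_000
        counts = np.bincount(
            [roulette_select(scaled, rng) for _ in range(n)], minlength=4)
        p = 0.25
        sigma = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) <= 3 * sigma)


def _marked_genomes():
    """Two parents whose genes are distinguishable by threshold value."""
    ga = Genome(tuple(NodeGene(0, 0.1, (0, 0, 0, 0)) for _ in range(GENOME_LENGTH)))
    gb = Genome(tuple(NodeGene(1, -0.1, (1, 1, 1, 1)) for _ in range(GENOME_LENGTH)))
    return ga, gb


class TestCrossover:
    def test_full_swap_at_boundary_cuts(self):
        ga, gb = _marked_genomes()

        class FixedRng:
            def choice(self, arr, size, replace):
                return np.array([1, GENOME_LENGTH])

        ca, cb = crossover(ga, gb, FixedRng())
        assert ca == gb and cb == ga

    def test_identical_parents_idempotent(self):
        rng = np.random.default_rng(5)
        g = random_genome(rng)
        ca, cb = crossover(g, g, rng)
        assert ca == g and cb == g

    def test_splice_bookkeeping_all_cut_pairs(self):
        """Oracle: explicit splice arithmetic for every C(31,2) cut pair."""
        ga, gb = _marked_genomes()
        for c1 in range(1, GENOME_LENGTH + 1):
            for c2 in range(c1 + 1, GENOME_LENGTH + 1):

                class FixedRng:
                    def __init__(self, a, b):
                        self.vals = np.array([a, b])

                    def choice(self, arr, size, replace):
                        return self.vals

                ca, cb = crossover(ga, gb, FixedRng(c1, c2))
                for pos in range(GENOME_LENGTH):
                    inside = c1 - 1 <= pos <= c2 - 1
                    assert ca.genes[pos] == (gb if inside else ga).genes[pos]
                    assert cb.genes[pos] == (ga if inside else gb).genes[pos]

    def test_offspring_valid_fuzzed(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            ca, cb = crossover(random_genome(rng), random_genome(rng), rng)
            for g in (*ca.genes, *cb.genes):
                assert _valid_gene(g)


class TestMutation:
    def test_zero_rate_identity(self):
        rng = np.random.default_rng(0)
        g = random_genome(rng)
        assert mutate(g, 0.0, rng) == g

    def test_rate_one_flips_all_bits(self):
        rng = np.random.default_rng(1)
        g = random_genome(rng)
        m = mutate(g, 1.0, rng)
        for before, after in zip(g.genes, m.genes):
            assert after.param_bits == tuple(1 - b for b in before.param_bits)
            assert after.es_bits == tuple(1 - b for b in before.es_bits)
            assert -1 <= after.model_type <= 3
            assert -0.65 <= after.threshold <= 0.65

    def test_model_type_redraw_uniform_over_five_values(self):
        """10^4 redraws hit all of {-1..3} uniformly within 3 sigma."""
        rng = np.random.default_rng(2)
        g = Genome(tuple(NodeGene(0, 0.0, (0, 0, 0, 0))
                         for _ in range(GENOME_LENGTH)))
        n = 10_000
        vals = []
        for _ in range(n // GENOME_LENGTH + 1):
            m = mutate(g, 1.0, rng)
            vals.extend(gene.model_type for gene in m.genes)
        vals = np.array(vals[:n])
        p = 1 / 5
        sigma = np.sqrt(n * p * (1 - p))
        for v in (-1, 0, 1, 2, 3):
            assert abs(np.sum(vals == v) - n * p) <= 3 * sigma

    def test_mutants_valid_fuzzed(self):
        rng = np.random.default_rng(3)
        for _ in range(400):
            m = mutate(random_genome(rng), 0.3, rng)
            assert all(_valid_gene(g) for g in m.genes)


@pytest.fixture()
def small_problem(rule_splits):
    return rule_splits["train"], rule_splits["validation"]


class TestEvolution:
    def test_single_leaf_fitness_closed_form(self, small_problem):
        """A genome decoding to one majority leaf predicts all-class1; its F1
        with class1 positive is 2p/(p+1) for class-1 fraction p."""
        train, val = small_problem
        genes = tuple(NodeGene(-1, 0.0, (0, 0, 0, 0)) for _ in range(GENOME_LENGTH))
        pop = [Genome(genes)] * 2 + [Genome(genes)] * 2
        fv, _ = evaluate_fitness(pop, train, val, positive_class=0)
        n1 = np.sum(val.y == 0)
        expect = 2 * n1 / (n1 + len(val.y))
        np.testing.assert_allclose(fv.old, expect)

    def test_parallel_equals_sequential(self, small_problem):
        train, val = small_problem
        pop = init_population(GAConfig(population_size=4, seed=6))
        seq, _ = evaluate_fitness(pop, train, val, seed=6, n_jobs=1)
        par, _ = evaluate_fitness(pop, train, val, seed=6, n_jobs=2)
        np.testing.assert_array_equal(seq.old, par.old)

    def test_accuracy_metric_switch(self, small_problem):
        train, val = small_problem
        genes = tuple(NodeGene(-1, 0.0, (0, 0, 0, 0)) for _ in range(GENOME_LENGTH))
        pop = [Genome(genes)] * 4
        fv, _ = evaluate_fitness(pop, train, val, metric="accuracy",
                                 positive_class=0)
        maj = int(np.argmax(train.class_counts()))
        np.testing.assert_allclose(fv.old, np.mean(val.y == maj))

    def test_elitism_running_best_monotone(self, small_problem):
        train, val = small_problem
        cfg = GAConfig(population_size=6, generations=6, seed=2,
                       halt_on_perfect=False)
        res = evolve(train, val, cfg, positive_class=0)
        best_so_far = [h["best_so_far"] for h in res.history]
        assert all(b >= a for a, b in zip(best_so_far, best_so_far[1:]))
        assert res.best_fitness == best_so_far[-1]

    def test_no_variation_converges_to_elite(self, small_problem):
        train, val = small_problem
        cfg = GAConfig(population_size=4, generations=4, seed=3,
                       crossover_probability=0.0, mutation_probability=0.0,
                       halt_on_perfect=False, early_halt=10)
        res = evolve(train, val, cfg, positive_class=0)
        # selection + elitism with no operators can only copy existing genomes
        pool = set(init_population(GAConfig(population_size=4, seed=3)))
        assert set(res.population) <= pool
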