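"""Genetic algorithm over omnivariate-tree genomes.

A genome is a fixed-length breadth-first list of node genes.  Each gene
carries the node's model type (-1 = pruned, 0 = MLR, 1 = C45, 2 = ANN,
3 = RF), a routing threshold in ``[-0.65, 0.65]``, a fixed-width block of
parameter bits indexing the model kind's parameter grids (out-of-range
indices wrap modulo the grid size so every bitstring decodes), and a 2-bit
early-stopping effort gene used only when the ES add-on is active.

Operators:

* fitness = validation performance (F1 by default), scaled by subtracting
  the population's worst fitness so the worst genome scores 0;
* roulette-wheel parent selection on the scaled fitness (uniform fallback
  when all scaled values are 0);
* two-point crossover whose cut points fall only on node-gene boundaries,
  so offspring always decode to valid trees;
* typed mutation per gene position (model type redrawn in [-1, 3], threshold
  redrawn in [-0.65, 0.65], any binary bit flipped);
* elitism: the worst genome of each new generation is replaced by the
  previous generation's fittest, making the running best non-decreasing.

Fitness evaluations are independent and seeded per (run seed, generation,
genome index), so concurrent evaluation through joblib is bit-identical to
sequential evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .base_models import EFFORT_LEVELS, NodeModelSpec, PARAM_GRIDS
from .data import Dataset
from .metrics import compute_metrics
from .odt import AddOnConfig, ODTree, StoppingConfig, induce_odt, predict_odt

logger = logging.getLogger(__name__)

__all__ = [
    "NodeGene",
    "Genome",
    "GAConfig",
    "FitnessVector",
    "GENOME_LENGTH",
    "PARAM_BITS_WIDTH",
    "MODEL_TYPE_TO_KIND",
    "random_genome",
    "init_population",
    "evaluate_fitness",
    "scale_fitness",
    "roulette_select",
    "crossover",
    "mutate",
    "evolve",
    "EvolveResult",
]

GENOME_LENGTH = 31  # breadth-first slots of a depth-5 binary tree
PARAM_BITS_WIDTH = 4  # sized for the largest per-kind parameter encoding
ES_BITS_WIDTH = 2
MODEL_TYPE_RANGE = (-1, 3)
THRESHOLD_RANGE = (-0.65, 0.65)
MODEL_TYPE_TO_KIND = {0: "MLR", 1: "C45", 2: "ANN", 3: "RF"}

# (name, bit offset, bit width) fields inside the param block, per kind
_PARAM_FIELDS = {
    "MLR": (("ridge", 0, 3),),
    "C45": (("confidence", 0, 2), ("min_instances", 2, 2)),
    "ANN": (("hidden_nodes", 0, 2), ("learning_rate", 2, 2)),
    "RF": (("n_trees", 0, 2), ("max_features", 2, 2)),
}


def _bits_to_int(bits) -> int:
    out = 0
    for b in bits:
        out = (out << 1) | int(b)
    return out


@dataclass(frozen=True)
class NodeGene:
    """One node slot of the genome."""

    model_type: int
    threshold: float
    param_bits: tuple[int, ...]
    es_bits: tuple[int, ...] = (0, 0)

    def __post_init__(self) -> None:
        if not MODEL_TYPE_RANGE[0] <= self.model_type <= MODEL_TYPE_RANGE[1]:
            raise ValueError(f"model_type {self.model_type} out of [-1, 3]")
        if not THRESHOLD_RANGE[0] <= self.threshold <= THRESHOLD_RANGE[1]:
            raise ValueError(f"threshold {self.threshold} out of [-0.65, 0.65]")
        if len(self.param_bits) != PARAM_BITS_WIDTH:
            raise ValueError("param_bits must have width 4")
        if len(self.es_bits) != ES_BITS_WIDTH:
            raise ValueError("es_bits must have width 2")
        if any(b not in (0, 1) for b in self.param_bits + self.es_bits):
            raise ValueError("bits must be 0 or 1")

    @property
    def pruned(self) -> bool:
        return self.model_type == -1

    def decode_spec(self, es_active: bool) -> NodeModelSpec | None:
        if self.pruned:
            return None
        kind = MODEL_TYPE_TO_KIND[self.model_type]
        params = {}
        for name, off, width in _PARAM_FIELDS[kind]:
            grid = PARAM_GRIDS[kind][name]
            idx = _bits_to_int(self.param_bits[off:off + width]) % len(grid)
            params[name] = grid[idx]
        effort = 1.0
        if es_active:
            effort = EFFORT_LEVELS[_bits_to_int(self.es_bits) % len(EFFORT_LEVELS)]
        return NodeModelSpec(kind, params, effort_fraction=effort)


@dataclass(frozen=True)
class Genome:
    """31 node genes in breadth-first order."""

    genes: tuple[NodeGene, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != GENOME_LENGTH:
            raise ValueError(f"genome must have {GENOME_LENGTH} genes")

    def node_spec(self, index: int, es_active: bool = False):
        """Interface consumed by tree induction: (pruned, threshold, spec)."""
        gene = self.genes[index - 1]
        return gene.pruned, gene.threshold, gene.decode_spec(es_active)


def random_gene(rng: np.random.Generator) -> NodeGene:
    return NodeGene(
        model_type=int(rng.integers(MODEL_TYPE_RANGE[0], MODEL_TYPE_RANGE[1] + 1)),
        threshold=float(rng.uniform(*THRESHOLD_RANGE)),
        param_bits=tuple(int(b) for b in rng.integers(0, 2, PARAM_BITS_WIDTH)),
        es_bits=tuple(int(b) for b in rng.integers(0, 2, ES_BITS_WIDTH)),
    )


def random_genome(rng: np.random.Generator) -> Genome:
    return Genome(tuple(random_gene(rng) for _ in range(GENOME_LENGTH)))


@dataclass
class GAConfig:
    population_size: int = 20
    generations: int = 50
    crossover_probability: float = 0.8
    mutation_probability: float = 0.05
    fitness_metric: str = "f1"
    seed: int = 0
    early_halt: int = 10
    halt_on_perfect: bool = True
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        for p in (self.crossover_probability, self.mutation_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.fitness_metric not in ("f1", "accuracy", "precision", "sensitivity"):
            raise ValueError(f"unknown fitness metric {self.fitness_metric!r}")


@dataclass
class FitnessVector:
    """Raw validation fitness per genome plus its worst-scaled form."""

    old: np.ndarray

    @property
    def worst(self) -> float:
        return float(np.min(self.old))

    @property
    def scaled(self) -> np.ndarray:
        return self.old - self.worst


def init_population(config: GAConfig, seed: int | None = None) -> list[Genome]:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return [random_genome(rng) for _ in range(config.population_size)]


def _genome_seed(seed: int, generation: int, index: int) -> int:
    return int(
        np.random.SeedSequence((seed, generation, index)).generate_state(1)[0]
        % (2**31)
    )


def _score(metric: str, y_pred, y_true, positive_class: int) -> float:
    m = compute_metrics(y_pred, y_true, positive_class=positive_class)
    return float(getattr(m, "f1" if metric == "f1" else metric))


def _eval_one(genome, train, validation, addons, stopping, symmetric,
              metric, positive_class, g_seed):
    try:
        tree = induce_odt(genome, train, addons=addons, stopping=stopping,
                          seed=g_seed, symmetric_routing=symmetric)
        labels, _ = predict_odt(tree, validation.X)
        return _score(metric, labels, validation.y, positive_class), tree
    except Exception as exc:  # failed induction scores 0
        logger.warning("genome evaluation failed: %s", exc)
        return 0.0, None


def evaluate_fitness(
    population: list[Genome],
    train: Dataset,
    validation: Dataset,
    addons: AddOnConfig = AddOnConfig(),
    seed: int = 0,
    generation: int = 0,
    stopping: StoppingConfig = StoppingConfig(),
    symmetric_routing: bool = False,
    metric: str = "f1",
    positive_class: int = 1,
    n_jobs: int = 1,
) -> tuple[FitnessVector, list[ODTree | None]]:
    """Validation fitness of every genome, plus the fitted trees.

    Each genome's evaluation is seeded from (seed, generation, index), so
    parallel evaluation (n_jobs > 1) is bit-identical to sequential.
    """
    seeds = [_genome_seed(seed, generation, i) for i in range(len(population))]
    if n_jobs == 1:
        results = [
            _eval_one(g, train, validation, addons, stopping, symmetric_routing,
                      metric, positive_class, s)
            for g, s in zip(population, seeds)
        ]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_eval_one)(g, train, validation, addons, stopping,
                               symmetric_routing, metric, positive_class, s)
            for g, s in zip(population, seeds)
        )
    fitness = np.array([r[0] for r in results])
    trees = [r[1] for r in results]
    return FitnessVector(fitness), trees


def scale_fitness(fitness: FitnessVector) -> np.ndarray:
    """Subtract the worst fitness; the worst genome scores 0."""
    return fitness.scaled


def roulette_select(scaled: np.ndarray, rng: np.random.Generator) -> int:
    """Fitness-proportionate parent index; uniform when all scaled are 0."""
    total = float(np.sum(scaled))
    if total <= 0.0:
        return int(rng.integers(0, len(scaled)))
    return int(rng.choice(len(scaled), p=scaled / total))


def crossover(parent_a: Genome, parent_b: Genome,
              rng: np.random.Generator) -> tuple[Genome, Genome]:
    """Two-point crossover with cuts on node boundaries only.

    Two distinct node indices are drawn from 1..31 and sorted; the middle
    splice (nodes c1..c2 inclusive) is exchanged.  Cuts (1, 31) therefore
    swap the full genomes.
    """
    c1, c2 = sorted(rng.choice(np.arange(1, GENOME_LENGTH + 1), size=2,
                               replace=False))
    a, b = list(parent_a.genes), list(parent_b.genes)
    lo, hi = c1 - 1, c2  # python slice over genes
    child_a = a[:lo] + b[lo:hi] + a[hi:]
    child_b = b[:lo] + a[lo:hi] + b[hi:]
    return Genome(tuple(child_a)), Genome(tuple(child_b))


def mutate(genome: Genome, p_m: float, rng: np.random.Generator) -> Genome:
    """Typed per-position mutation with independent probability ``p_m``."""
    new_genes = []
    for gene in genome.genes:
        model_type = gene.model_type
        threshold = gene.threshold
        pbits = list(gene.param_bits)
        ebits = list(gene.es_bits)
        if rng.random() < p_m:
            model_type = int(rng.integers(MODEL_TYPE_RANGE[0],
                                          MODEL_TYPE_RANGE[1] + 1))
        if rng.random() < p_m:
            threshold = float(rng.uniform(*THRESHOLD_RANGE))
        for i in range(PARAM_BITS_WIDTH):
            if rng.random() < p_m:
                pbits[i] = 1 - pbits[i]
        for i in range(ES_BITS_WIDTH):
            if rng.random() < p_m:
                ebits[i] = 1 - ebits[i]
        new_genes.append(NodeGene(model_type, threshold, tuple(pbits),
                                  tuple(ebits)))
    return Genome(tuple(new_genes))


@dataclass
class EvolveResult:
    best_genome: Genome
    best_fitness: float
    best_tree: ODTree | None
    population: list[Genome]
    population_trees: list[ODTree | None]
    population_fitness: np.ndarray
    history: list[dict] = field(default_factory=list)


def evolve(
    train: Dataset,
    validation: Dataset,
    ga_config: GAConfig,
    addons: AddOnConfig = AddOnConfig(),
    stopping: StoppingConfig = StoppingConfig(),
    symmetric_routing: bool = False,
    positive_class: int = 1,
) -> EvolveResult:
    """Run the generational loop and return the best genome with its tree.

    Each generation: evaluate, scale, roulette-select parents, cross over
    with probability ``p_c`` (else copy), mutate, replace the population,
    then elitism re-inserts the previous generation's fittest over the new
    worst.  Halts after ``generations`` evaluations, after ``early_halt``
    generations without improvement, or when a genome reaches perfect
    validation fitness.
    """
    cfg = ga_config
    rng = np.random.default_rng(cfg.seed)
    population = init_population(cfg, seed=cfg.seed)

    def _evaluate(pop, gen):
        return evaluate_fitness(
            pop, train, validation, addons=addons, seed=cfg.seed,
            generation=gen, stopping=stopping,
            symmetric_routing=symmetric_routing, metric=cfg.fitness_metric,
            positive_class=positive_class, n_jobs=cfg.n_jobs,
        )

    fv, trees = _evaluate(population, 0)
    best_idx = int(np.argmax(fv.old))
    best = (population[best_idx], float(fv.old[best_idx]), trees[best_idx])
    history = [{"generation": 0, "best": float(fv.old.max()),
                "mean": float(fv.old.mean()), "best_so_far": best[1]}]
    stall = 0
    for gen in range(1, cfg.generations):
        if cfg.halt_on_perfect and best[1] >= 1.0:
            break
        if stall >= cfg.early_halt:
            break
        scaled = scale_fitness(fv)
        elite_idx = int(np.argmax(fv.old))
        elite = (population[elite_idx], float(fv.old[elite_idx]),
                 trees[elite_idx])
        offspring: list[Genome] = []
        while len(offspring) < cfg.population_size:
            i, j = roulette_select(scaled, rng), roulette_select(scaled, rng)
            pa, pb = population[i], population[j]
            if rng.random() < cfg.crossover_probability:
                ca, cb = crossover(pa, pb, rng)
            else:
                ca, cb = pa, pb
            offspring.append(mutate(ca, cfg.mutation_probability, rng))
            if len(offspring) < cfg.population_size:
                offspring.append(mutate(cb, cfg.mutation_probability, rng))
        population = offspring
        fv, trees = _evaluate(population, gen)
        # elitism: previous best replaces the new generation's worst
        worst_idx = int(np.argmin(fv.old))
        population[worst_idx] = elite[0]
        trees[worst_idx] = elite[2]
        fv.old[worst_idx] = elite[1]
        gen_best = float(fv.old.max())
        if gen_best > best[1]:
            bi = int(np.argmax(fv.old))
            best = (population[bi], gen_best, trees[bi])
            stall = 0
        else:
            stall += 1
        history.append({"generation": gen, "best": gen_best,
                        "mean": float(fv.old.mean()), "best_so_far": best[1]})
    return EvolveResult(
        best_genome=best[0], best_fitness=best[1], best_tree=best[2],
        population=population, population_trees=trees,
        population_fitness=fv.old, history=history,
    )
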