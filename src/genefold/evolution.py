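"""The Genetic Folding evolutionary loop.

Population of random valid chromosomes -> cross-validated fitness ->
tournament selection -> one-point crossover with repair -> category-
preserving point mutation -> elitism, with per-generation bookkeeping of
best/median/mean/std fitness, population diversity and the complexity
(gene count) of the generation's best kernel.

Fitness of a chromosome is the mean held-out accuracy (as a fraction) of a
precomputed-kernel SVM over stratified k-fold cross-validation of its
decoded kernel on the training table.  Kernels whose Gram matrix had to be
sanitized (non-finite entries) or is degenerate (constant) score 0.
Fitness ties are broken toward lower complexity, then earlier creation,
which nudges the search toward parsimonious kernels.  Elitism makes the
per-generation best fitness non-decreasing; with a fixed seed the whole
run is deterministic.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass

import numpy as np

from .chromosome import (
    Chromosome,
    complexity,
    decode,
    rebuild_from_symbols,
    random_chromosome,
    validate,
)
from .data_io import FeatureTable, kfold_split
from .errors import ConfigError, InputError
from .kernel import gram
from .svm_bridge import cv_evaluate
from .symbols import OPERANDS, OPERATORS, VECTOR_OPERATORS

__all__ = [
    "GFConfig",
    "GenerationStats",
    "EvolutionResult",
    "fitness",
    "evolve",
    "crossover",
    "mutate",
    "diversity",
]


@dataclass
class GFConfig:
    """Hyperparameters of one Genetic Folding run."""

    population_size: int = 50
    generations: int = 20
    head_length: int = 10
    gene_cap: int = 50
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    tournament_size: int = 2
    elite_count: int = 1
    cv_folds: int = 5
    C: float = 1.0
    seed: int = 0
    operator_pool: tuple[str, ...] = OPERATORS
    operand_pool: tuple[str, ...] = OPERANDS
    reduction: str = "sum"

    def validate(self) -> None:
        if self.population_size < 2:
            raise ConfigError(f"population_size must be >= 2, got {self.population_size}")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.elite_count < self.population_size:
            raise ConfigError("elite_count must be < population_size")
        if self.cv_folds < 2:
            raise ConfigError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.gene_cap < 3:
            raise ConfigError(f"gene_cap must be >= 3, got {self.gene_cap}")
        if self.head_length < 1:
            raise ConfigError(f"head_length must be >= 1, got {self.head_length}")
        if self.tournament_size < 1:
            raise ConfigError(f"tournament_size must be >= 1, got {self.tournament_size}")
        if self.C <= 0:
            raise ConfigError(f"C must be positive, got {self.C}")
        if not self.operator_pool or not self.operand_pool:
            raise ConfigError("operator and operand pools must be non-empty")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["operator_pool"] = list(self.operator_pool)
        d["operand_pool"] = list(self.operand_pool)
        return d


@dataclass
class GenerationStats:
    generation: int
    best: float
    median: float
    mean: float
    std: float
    diversity: float
    best_complexity: int
    best_chromosome: Chromosome


@dataclass
class EvolutionResult:
    best_chromosome: Chromosome
    best_fitness: float
    history: list[GenerationStats]
    config: GFConfig
    seed: int

    @property
    def best_expression(self):
        return decode(self.best_chromosome.symbols(), self.best_chromosome.folds())

    def history_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["generation", "best", "median", "mean", "std", "diversity", "complexity"])
        for s in self.history:
            w.writerow(
                [s.generation, s.best, s.median, s.mean, s.std, s.diversity, s.best_complexity]
            )
        return buf.getvalue()

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config.to_dict(),
                "seed": self.seed,
                "best": {
                    "symbols": self.best_chromosome.symbols(),
                    "folds": self.best_chromosome.folds(),
                    "fitness": self.best_fitness,
                    "complexity": complexity(self.best_chromosome),
                },
                "history": [
                    {
                        "generation": s.generation,
                        "best": s.best,
                        "median": s.median,
                        "mean": s.mean,
                        "std": s.std,
                        "diversity": s.diversity,
                        "complexity": s.best_complexity,
                        "best_symbols": s.best_chromosome.symbols(),
                        "best_folds": s.best_chromosome.folds(),
                    }
                    for s in self.history
                ],
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def fitness(
    c: Chromosome,
    data: FeatureTable,
    config: GFConfig,
    cache: dict | None = None,
    folds=None,
) -> float:
    """Cross-validated accuracy (fraction) of the chromosome's kernel.

    Deterministic given (chromosome, data, config.seed): the stratified
    fold assignment is derived from the run seed.  A sanitized or constant
    Gram scores 0.
    """
    if data.y is None:
        raise InputError("feature table labels are not encoded; call encode_labels first")
    if data.single_class:
        raise InputError("fitness needs both classes present in the data")
    key = None
    if cache is not None:
        key = (c.key(), data.fingerprint())
        if key in cache:
            return cache[key]
    expr = decode(c.symbols(), c.folds())
    G = gram(expr, data.X, reduction=config.reduction)
    if G.sanitized or float(G.values.std()) < 1e-12:
        value = 0.0
    else:
        if folds is None:
            folds = kfold_split(data.y, k=config.cv_folds, seed=config.seed)
        value = cv_evaluate(G.values, data.y, C=config.C, folds=folds).accuracy
    if cache is not None:
        cache[key] = value
    return value


# ---------------------------------------------------------------------------
# variation operators
# ---------------------------------------------------------------------------

def crossover(
    a: Chromosome,
    b: Chromosome,
    rng: np.random.Generator,
    rate: float = 1.0,
    operand_pool: tuple[str, ...] = OPERANDS,
) -> tuple[Chromosome, Chromosome]:
    """One-point crossover at a gene boundary, followed by repair.

    Symbol strings are spliced at a common cut point; each child is then
    re-closed into a valid chromosome (dangling child slots filled, fold
    indices rebuilt, unreachable tail genes dropped).  With probability
    ``1 - rate`` the parents are returned unchanged (as copies).
    """
    if rng.random() >= rate:
        return _copy(a), _copy(b)
    sa, sb = a.symbols(), b.symbols()
    lo = min(len(sa), len(sb))
    if lo < 2:
        return _copy(a), _copy(b)
    cut = int(rng.integers(1, lo))
    child1 = rebuild_from_symbols(sa[:cut] + sb[cut:], rng, operand_pool)
    child2 = rebuild_from_symbols(sb[:cut] + sa[cut:], rng, operand_pool)
    return child1, child2


def _copy(c: Chromosome) -> Chromosome:
    return Chromosome(list(c.genes), c.head_length)


def mutate(
    c: Chromosome,
    rng: np.random.Generator,
    rate: float,
    operator_pool: tuple[str, ...] = OPERATORS,
    operand_pool: tuple[str, ...] = OPERANDS,
) -> Chromosome:
    """Category-preserving point mutation: tree shape is untouched.

    Each gene independently, with probability ``rate``, redraws its symbol
    from the compatible pool: internal genes from the operators, leaves
    from the operands plus terminal-acting vector operators.  Scalar
    operators can therefore never land in a leaf, so validity is preserved
    by construction.
    """
    from .chromosome import FoldIndex, Gene
    from .symbols import get_symbol

    leaf_pool = tuple(operand_pool) + tuple(
        s for s in operator_pool if s in VECTOR_OPERATORS
    )
    genes = []
    for g in c.genes:
        if rng.random() < rate:
            pool = leaf_pool if g.is_terminal else tuple(operator_pool)
            name = str(rng.choice(list(pool)))
            genes.append(Gene(g.position, get_symbol(name), g.fold))
        else:
            genes.append(g)
    return Chromosome(genes, c.head_length)


def diversity(pop: list[Chromosome]) -> float:
    """Mean pairwise normalized Hamming distance over aligned symbol strings.

    The shorter chromosome is padded with a sentinel and the raw distance
    divided by the longer length, so the score lies in [0, 1]; identical
    populations score 0.
    """
    if len(pop) < 2:
        raise InputError("diversity needs a population of at least 2")
    strings = [p.symbols() for p in pop]
    total = 0.0
    pairs = 0
    for i in range(len(strings)):
        for j in range(i + 1, len(strings)):
            si, sj = strings[i], strings[j]
            longer = max(len(si), len(sj))
            mismatches = sum(
                1
                for k in range(longer)
                if (si[k] if k < len(si) else None) != (sj[k] if k < len(sj) else None)
            )
            total += mismatches / longer
            pairs += 1
    return total / pairs


# ---------------------------------------------------------------------------
# the main loop
# ---------------------------------------------------------------------------

def evolve(data: FeatureTable, config: GFConfig) -> EvolutionResult:
    """Run the Genetic Folding search and return the best kernel found.

    Order of operations per generation: tournament selection -> one-point
    crossover with repair -> per-gene mutation -> elites carried unchanged.
    Elitism guarantees the per-generation best fitness is non-decreasing.
    With ``generations=0`` only the initial population is evaluated and the
    history is empty.
    """
    config.validate()
    if data.y is None:
        raise InputError("feature table labels are not encoded; call encode_labels first")
    if data.single_class:
        raise InputError("evolution needs both classes present in the data")
    rng = np.random.default_rng(int(config.seed))
    cache: dict = {}
    folds = kfold_split(data.y, k=config.cv_folds, seed=config.seed)

    creation = {}

    def birth(c: Chromosome) -> Chromosome:
        creation[id(c)] = len(creation)
        return c

    def sort_key(item):
        c, fit = item
        return (-fit, complexity(c), creation.get(id(c), 0))

    population = [birth(random_chromosome(config, rng)) for _ in range(config.population_size)]
    fitnesses = [fitness(c, data, config, cache, folds) for c in population]

    def best_of(pop, fits):
        return min(zip(pop, fits), key=sort_key)

    best_c, best_f = best_of(population, fitnesses)
    history: list[GenerationStats] = []

    for gen in range(config.generations):
        ranked = sorted(zip(population, fitnesses), key=sort_key)
        elites = [c for c, _ in ranked[: config.elite_count]]
        next_pop: list[Chromosome] = [_copy(e) for e in elites]
        for e in next_pop:
            birth(e)
        while len(next_pop) < config.population_size:
            p1 = _tournament(population, fitnesses, rng, config.tournament_size, sort_key)
            p2 = _tournament(population, fitnesses, rng, config.tournament_size, sort_key)
            c1, c2 = crossover(p1, p2, rng, config.crossover_rate, config.operand_pool)
            for child in (c1, c2):
                if len(next_pop) >= config.population_size:
                    break
                m = mutate(child, rng, config.mutation_rate, config.operator_pool, config.operand_pool)
                assert validate(m).ok, "closure violated: invalid offspring"
                next_pop.append(birth(m))
        population = next_pop
        fitnesses = [fitness(c, data, config, cache, folds) for c in population]
        gen_best_c, gen_best_f = best_of(population, fitnesses)
        if (gen_best_f, -complexity(gen_best_c)) > (best_f, -complexity(best_c)):
            best_c, best_f = gen_best_c, gen_best_f
        arr = np.asarray(fitnesses, dtype=float)
        history.append(
            GenerationStats(
                generation=gen,
                best=float(arr.max()),
                median=float(np.median(arr)),
                mean=float(arr.mean()),
                std=float(arr.std()),
                diversity=diversity(population),
                best_complexity=complexity(gen_best_c),
                best_chromosome=_copy(gen_best_c),
            )
        )

    return EvolutionResult(
        best_chromosome=_copy(best_c),
        best_fitness=best_f,
        history=history,
        config=config,
        seed=int(config.seed),
    )


def _tournament(pop, fits, rng, size, sort_key) -> Chromosome:
    idx = rng.integers(0, len(pop), size=size)
    best = min(((pop[i], fits[i]) for i in idx), key=sort_key)
    return best[0]
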