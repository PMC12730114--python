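"""Genetic algorithm over binary block-inclusion chromosomes.

The search space is the set of non-empty block subsets (length-72 vectors at
the image level, length-24 at the cell level).  The configuration mirrors a
deliberately small evolutionary budget: 16 individuals, 25 generations,
single-point crossover with an interior cut, a 0.125 mutation rate (two
mutated offspring per generation) and family-local selection keeping the top
two of each {two parents, two offspring} quartet.  Every chromosome is
evaluated at most once: an archive maps chromosomes to fitness, and any
offspring colliding with the archive is mutated again until novel, so each
generation contributes exactly 16 fresh evaluations (400 over a full run).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Chromosome = np.ndarray  # 1-D uint8 vector of 0/1


@dataclass
class GAConfig:
    population_size: int = 16
    generations: int = 25
    mutation_rate: float = 0.125
    crossover: str = "single_point"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size % 2 != 0:
            raise ValueError("population size must be even (mating pairs)")
        if self.crossover != "single_point":
            raise ValueError("only single_point crossover is supported")

    @property
    def mutants_per_generation(self) -> int:
        return int(round(self.mutation_rate * self.population_size))


@dataclass
class Individual:
    chromosome: Chromosome
    fitness: float | None = None

    def key(self) -> bytes:
        return np.asarray(self.chromosome, dtype=np.uint8).tobytes()

    @property
    def bitstring(self) -> str:
        return "".join(str(int(b)) for b in self.chromosome)


@dataclass
class EvaluationArchive:
    """Memo of every chromosome ever scored; guards against re-evaluation."""

    scores: dict[bytes, float] = field(default_factory=dict)
    evaluation_count: int = 0

    def __contains__(self, chromosome) -> bool:
        return np.asarray(chromosome, dtype=np.uint8).tobytes() in self.scores

    def evaluate(self, individual: Individual, fitness_fn) -> float:
        key = individual.key()
        if key not in self.scores:
            value = float(fitness_fn(individual.chromosome))
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"fitness outside [0, 1]: {value}")
            self.scores[key] = value
            self.evaluation_count += 1
        individual.fitness = self.scores[key]
        return individual.fitness


def _repair(chromosome: Chromosome, rng) -> Chromosome:
    """Flip one random bit of an all-zero chromosome (empty subsets invalid)."""
    if not chromosome.any():
        chromosome = chromosome.copy()
        chromosome[rng.integers(chromosome.shape[0])] = 1
    return chromosome


def random_chromosome(length: int, rng) -> Chromosome:
    return _repair(rng.integers(0, 2, size=length, dtype=np.uint8), rng)


def init_population(
    config: GAConfig, length: int, seeds: list[Chromosome] | None = None
) -> list[Individual]:
    """16 unique chromosomes: seed individuals verbatim, remainder random."""
    rng = np.random.default_rng(config.seed)
    seen: set[bytes] = set()
    pop: list[Individual] = []
    for s in seeds or []:
        chrom = _repair(np.asarray(s, dtype=np.uint8).copy(), rng)
        if chrom.shape[0] != length:
            raise ValueError(f"seed individual length {chrom.shape[0]} != {length}")
        key = chrom.tobytes()
        if key in seen:
            raise ValueError("duplicate seed individuals")
        seen.add(key)
        pop.append(Individual(chrom))
    if len(pop) > config.population_size:
        raise ValueError("more seed individuals than population slots")
    while len(pop) < config.population_size:
        chrom = random_chromosome(length, rng)
        if chrom.tobytes() in seen:
            continue
        seen.add(chrom.tobytes())
        pop.append(Individual(chrom))
    return pop


def crossover(parent_a: Chromosome, parent_b: Chromosome, rng):
    """Single-point crossover; the cut avoids both end positions."""
    a = np.asarray(parent_a, dtype=np.uint8)
    b = np.asarray(parent_b, dtype=np.uint8)
    if a.shape != b.shape:
        raise ValueError("parent lengths differ")
    length = a.shape[0]
    if length < 2:
        raise ValueError("chromosome too short for crossover")
    p = int(rng.integers(1, length))  # uniform on {1, ..., L-1}
    child_a = np.concatenate([a[:p], b[p:]])
    child_b = np.concatenate([b[:p], a[p:]])
    return child_a, child_b


def mutate(
    chromosome: Chromosome,
    rng,
    archive: EvaluationArchive | None = None,
    max_attempts_factor: int = 10,
) -> Chromosome:
    """Flip one random bit; re-mutate while the result is already archived.

    The escape loop is bounded (``10 * L`` attempts) so that exhausted tiny
    search spaces terminate; at the production lengths (24/72) the bound is
    never reached.
    """
    out = np.asarray(chromosome, dtype=np.uint8).copy()
    length = out.shape[0]
    out[rng.integers(length)] ^= 1
    if archive is not None:
        attempts = 0
        while out.tobytes() in archive.scores and attempts < max_attempts_factor * length:
            out[rng.integers(length)] ^= 1
            attempts += 1
    return out


def _novel_offspring(
    chrom: Chromosome,
    archive: EvaluationArchive,
    rng,
    claimed: set | None = None,
    max_attempts_factor: int = 10,
) -> Chromosome:
    """Ensure an offspring is not a previously considered solution.

    "Considered" covers both archived chromosomes and offspring already
    produced in the current generation; the escape re-applies single-bit
    mutation (bounded, for exhausted tiny search spaces).
    """
    claimed = claimed if claimed is not None else set()
    chrom = _repair(np.asarray(chrom, dtype=np.uint8), rng)
    attempts = 0
    limit = max_attempts_factor * chrom.shape[0]
    while (chrom.tobytes() in archive.scores or chrom.tobytes() in claimed):
        if attempts >= limit:
            break
        chrom = _repair(mutate(chrom, rng), rng)
        attempts += 1
    return chrom


def family_select(parents: list[Individual], offspring: list[Individual]):
    """Top two of the quartet; ties prefer offspring (exploration bias)."""
    quartet = [(ind, 1) for ind in parents] + [(ind, 0) for ind in offspring]
    for ind, _ in quartet:
        if ind.fitness is None:
            raise ValueError("family_select requires evaluated individuals")
    ranked = sorted(quartet, key=lambda t: (-t[0].fitness, t[1]))
    return [ranked[0][0], ranked[1][0]]


@dataclass
class GenerationRecord:
    generation: int
    best_fitness: float
    mean_fitness: float
    best_chromosome: str
    evaluations: int


def evolve(
    population: list[Individual],
    fitness_fn,
    config: GAConfig,
    archive: EvaluationArchive | None = None,
):
    """Run the GA; returns (best individual ever, per-generation history).

    Per generation: randomly permute the population into 8 mating pairs,
    single-point crossover per pair, mutate 2 randomly chosen offspring,
    replace archive-duplicates by further mutation, evaluate the 16 new
    offspring, then family-local selection.  The initial population is
    evaluated once at generation 0 and not counted among the per-generation
    offspring evaluations.
    """
    rng = np.random.default_rng(config.seed + 1)
    archive = archive if archive is not None else EvaluationArchive()
    pop = list(population)

    for ind in pop:
        archive.evaluate(ind, fitness_fn)
    best = max(pop, key=lambda i: i.fitness)
    best = Individual(best.chromosome.copy(), best.fitness)
    history = [
        GenerationRecord(
            generation=0,
            best_fitness=best.fitness,
            mean_fitness=float(np.mean([i.fitness for i in pop])),
            best_chromosome=best.bitstring,
            evaluations=0,
        )
    ]

    offspring_evaluations = 0
    for gen in range(1, config.generations + 1):
        order = rng.permutation(len(pop))
        all_offspring: list[Individual] = []
        families = []
        for k in range(0, len(pop), 2):
            pa, pb = pop[order[k]], pop[order[k + 1]]
            ca, cb = crossover(pa.chromosome, pb.chromosome, rng)
            family = {"parents": [pa, pb], "children_raw": [ca, cb]}
            families.append(family)
        # mutation hits a fixed number of offspring, chosen uniformly
        flat = [(fi, ci) for fi in range(len(families)) for ci in range(2)]
        m = config.mutants_per_generation
        picked = rng.choice(len(flat), size=min(m, len(flat)), replace=False)
        mutate_set = {flat[int(i)] for i in picked}
        claimed: set = set()
        for fi, family in enumerate(families):
            children = []
            for ci, chrom in enumerate(family["children_raw"]):
                if (fi, ci) in mutate_set:
                    chrom = mutate(chrom, rng)
                chrom = _novel_offspring(chrom, archive, rng, claimed=claimed)
                claimed.add(chrom.tobytes())
                children.append(Individual(chrom))
            family["children"] = children
            all_offspring.extend(children)
        before = archive.evaluation_count
        for child in all_offspring:
            archive.evaluate(child, fitness_fn)
        offspring_evaluations += archive.evaluation_count - before

        new_pop: list[Individual] = []
        for family in families:
            new_pop.extend(family_select(family["parents"], family["children"]))
        pop = new_pop

        gen_best = max(pop, key=lambda i: i.fitness)
        if gen_best.fitness > best.fitness:
            best = Individual(gen_best.chromosome.copy(), gen_best.fitness)
        history.append(
            GenerationRecord(
                generation=gen,
                best_fitness=best.fitness,
                mean_fitness=float(np.mean([i.fitness for i in pop])),
                best_chromosome=best.bitstring,
                evaluations=offspring_evaluations,
            )
        )
    return best, history


def run_ga(
    length: int,
    fitness_fn,
    config: GAConfig | None = None,
    seeds: list[Chromosome] | None = None,
):
    """Convenience wrapper: init + evolve; returns (best, history, archive)."""
    config = config or GAConfig()
    pop = init_population(config, length, seeds=seeds)
    archive = EvaluationArchive()
    best, history = evolve(pop, fitness_fn, config, archive=archive)
    return best, history, archive


def history_to_rows(history):
    return [
        {
            "generation": h.generation,
            "best_fitness": h.best_fitness,
            "mean_fitness": h.mean_fitness,
            "best_chromosome": h.best_chromosome,
            "evaluations": h.evaluations,
        }
        for h in history
    ]
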