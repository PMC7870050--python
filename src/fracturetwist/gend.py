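"""Diversity-preserving genetic algorithm over fixed-length bitstrings.

The published analysis drives both its variable selection and its twin-subset
construction with Semeion's proprietary "genetic doping" algorithm, whose
operators are not public.  This module provides an openly documented
evolutionary core in the same spirit: a generational GA (tournament
selection of size 3, uniform crossover, per-bit mutation, elitism) plus a
"doping" step — each generation a fraction of the worst individuals is
replaced by recombinations of the current best genome with a fresh random
genome, injecting diversity so the search does not collapse on a local
optimum.  All operators are parameterised and seeded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GenDParams", "EvolutionResult", "gend_evolve", "FitnessEvaluationError"]


@dataclass(frozen=True)
class GenDParams:
    population_size: int = 24
    generations: int = 20
    crossover_rate: float = 0.9
    mutation_rate: float = 0.02
    doping_fraction: float = 0.1
    elitism: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 4:
            raise ValueError("population_size must be ≥ 4")
        for name in ("crossover_rate", "mutation_rate", "doping_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.elitism <= self.population_size:
            raise ValueError("elitism must be in [0, population_size]")


@dataclass
class EvolutionResult:
    best_genome: np.ndarray
    best_fitness: float
    fitness_history: np.ndarray  # running best per generation (monotone)
    n_evaluations: int


class FitnessEvaluationError(RuntimeError):
    def __init__(self, generation: int, genome: np.ndarray, cause: Exception):
        super().__init__(
            f"fitness function failed at generation {generation} "
            f"on genome {genome.astype(int).tolist()}: {cause}"
        )
        self.generation = generation
        self.genome = genome


def _tournament(rng, fitnesses: np.ndarray, k: int = 3) -> int:
    idx = rng.integers(0, len(fitnesses), size=k)
    return int(idx[np.argmax(fitnesses[idx])])


def _uniform_crossover(rng, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    mask = rng.random(a.shape[0]) < 0.5
    return np.where(mask, a, b)


def gend_evolve(fitness_fn, genome_length: int,
                params: GenDParams = GenDParams(),
                repair_fn=None) -> EvolutionResult:
    """Maximise ``fitness_fn`` over {0,1}^genome_length.

    ``repair_fn(genome) -> genome``, if given, is applied to every genome
    before evaluation so constraint violations are repaired rather than
    rejected.  Returns the best genome ever evaluated; the total number of
    fitness evaluations is at most population_size × (generations + 1).
    Fixed seed ⇒ identical trajectory.
    """
    if genome_length < 1:
        raise ValueError("genome_length must be ≥ 1")
    rng = np.random.default_rng(params.seed)
    pop_n = params.population_size

    def prep(g: np.ndarray) -> np.ndarray:
        return repair_fn(g) if repair_fn is not None else g

    def evaluate(genomes: list[np.ndarray], generation: int) -> np.ndarray:
        out = np.empty(len(genomes))
        for i, g in enumerate(genomes):
            try:
                out[i] = fitness_fn(g)
            except Exception as e:  # abort with context, per contract
                raise FitnessEvaluationError(generation, g, e) from e
        return out

    population = [prep(rng.integers(0, 2, size=genome_length).astype(bool))
                  for _ in range(pop_n)]
    fitnesses = evaluate(population, 0)
    n_evals = pop_n

    best_i = int(np.argmax(fitnesses))
    best_genome = population[best_i].copy()
    best_fitness = float(fitnesses[best_i])
    history = [best_fitness]

    for gen in range(1, params.generations + 1):
        order = np.argsort(-fitnesses, kind="stable")
        elites = [population[i].copy() for i in order[: params.elitism]]

        children: list[np.ndarray] = []
        while len(children) < pop_n - params.elitism:
            pa = population[_tournament(rng, fitnesses)]
            pb = population[_tournament(rng, fitnesses)]
            if rng.random() < params.crossover_rate:
                child = _uniform_crossover(rng, pa, pb)
            else:
                child = (pa if rng.random() < 0.5 else pb).copy()
            flip = rng.random(genome_length) < params.mutation_rate
            child = child ^ flip
            children.append(child)

        # doping: replace the tail of the offspring with best × random recombinants
        n_dope = int(round(params.doping_fraction * pop_n))
        for d in range(min(n_dope, len(children))):
            fresh = rng.integers(0, 2, size=genome_length).astype(bool)
            children[len(children) - 1 - d] = _uniform_crossover(rng, best_genome, fresh)

        population = elites + [prep(c) for c in children]
        new_fit = np.empty(pop_n)
        new_fit[: params.elitism] = fitnesses[order[: params.elitism]]
        if pop_n > params.elitism:
            new_fit[params.elitism:] = evaluate(population[params.elitism:], gen)
            n_evals += pop_n - params.elitism
        fitnesses = new_fit

        gen_best = int(np.argmax(fitnesses))
        if fitnesses[gen_best] > best_fitness:
            best_fitness = float(fitnesses[gen_best])
            best_genome = population[gen_best].copy()
        history.append(best_fitness)

    return EvolutionResult(best_genome=best_genome, best_fitness=best_fitness,
                           fitness_history=np.asarray(history), n_evaluations=n_evals)
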