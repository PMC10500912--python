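"""Genetic-algorithm hyperparameter search.

A chromosome is a fixed-length gene vector within per-gene bounds.  Two
encodings are used in practice: a classical-CNN layout ([num_layers,
filters per layer..., filter sizes per layer...], whose fitness is the
best training accuracy reached within an epoch budget) and a hybrid
layout ([num_circuits, circuit_depth, learning_rate], whose fitness is
the pair (test accuracy, -trainable parameter count), compared
lexicographically so that among equally accurate models the smaller one
wins).

The evolutionary loop is deliberately plain: tournament selection
(size 3), one-point crossover, per-gene resampling mutation, and
single-individual elitism, which makes best-so-far fitness monotone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml


@dataclass(frozen=True)
class GeneBound:
    """Closed interval for one gene; integer genes are sampled uniformly
    over the lattice, float genes uniformly over the interval."""

    low: float
    high: float
    integer: bool = True

    def sample(self, rng: np.random.Generator) -> float:
        if self.integer:
            return int(rng.integers(int(self.low), int(self.high) + 1))
        return float(rng.uniform(self.low, self.high))

    def contains(self, value: float) -> bool:
        return self.low <= value <= self.high


@dataclass(frozen=True)
class Chromosome:
    kind: str  # "cnn" | "hqcnn" | "stub"
    genes: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))


@dataclass
class FitnessRecord:
    chromosome: Chromosome
    objectives: tuple  # (accuracy,) or (accuracy, -num_params)
    failed: bool = False


@dataclass
class GAConfig:
    population_size: int = 12
    generations: int = 10
    tournament_size: int = 3
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    elitism: int = 1

    @classmethod
    def from_yaml(cls, path) -> "GAConfig":
        with open(path) as handle:
            d = yaml.safe_load(handle) or {}
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


def init_population(
    size: int, bounds: Sequence[GeneBound], rng: np.random.Generator,
    kind: str = "stub",
) -> list[Chromosome]:
    """Uniformly sampled chromosomes within bounds; reproducible by rng."""
    if size < 2:
        raise ValueError("population size must be >= 2")
    if not bounds:
        raise ValueError("bounds are empty")
    return [
        Chromosome(kind, tuple(b.sample(rng) for b in bounds)) for _ in range(size)
    ]


def evaluate_fitness(
    population: Sequence[Chromosome],
    evaluator: Callable[[Chromosome], tuple],
    budget: int | None = None,
) -> list[FitnessRecord]:
    """Run the evaluator on every chromosome.

    The evaluator returns the objective tuple — e.g. train-and-score a
    model within ``budget`` epochs.  A failing evaluation is recorded
    with fitness 0 and flagged rather than aborting the search.
    """
    records = []
    for chrom in population:
        try:
            objectives = evaluator(chrom) if budget is None else evaluator(
                chrom, budget
            )
            if not isinstance(objectives, tuple):
                objectives = (float(objectives),)
            records.append(FitnessRecord(chrom, objectives))
        except Exception:  # noqa: BLE001 - a bad candidate must not kill the run
            records.append(FitnessRecord(chrom, (0.0,), failed=True))
    return records


def _tournament(
    records: list[FitnessRecord], size: int, rng: np.random.Generator
) -> Chromosome:
    picks = rng.integers(0, len(records), size=size)
    best = max(picks, key=lambda i: records[i].objectives)
    return records[best].chromosome


def _clip_gene(value: float, bound: GeneBound) -> float:
    value = min(max(value, bound.low), bound.high)
    return int(round(value)) if bound.integer else float(value)


def evolve(
    population: Sequence[Chromosome],
    records: list[FitnessRecord],
    bounds: Sequence[GeneBound],
    config: GAConfig,
    rng: np.random.Generator,
) -> list[Chromosome]:
    """Produce the next generation (same size).

    Elites pass through unchanged; the rest come from tournament-selected
    parents with one-point crossover at ``crossover_rate`` and per-gene
    resampling mutation at ``mutation_rate``.
    """
    n = len(population)
    ranked = sorted(records, key=lambda r: r.objectives, reverse=True)
    next_pop: list[Chromosome] = [r.chromosome for r in ranked[: config.elitism]]
    while len(next_pop) < n:
        parent_a = _tournament(records, config.tournament_size, rng)
        parent_b = _tournament(records, config.tournament_size, rng)
        genes_a, genes_b = list(parent_a.genes), list(parent_b.genes)
        if len(genes_a) > 1 and rng.random() < config.crossover_rate:
            point = int(rng.integers(1, len(genes_a)))
            genes_a = genes_a[:point] + genes_b[point:]
        for i, bound in enumerate(bounds):
            if rng.random() < config.mutation_rate:
                genes_a[i] = bound.sample(rng)
            else:
                genes_a[i] = _clip_gene(genes_a[i], bound)
        next_pop.append(Chromosome(parent_a.kind, tuple(genes_a)))
    return next_pop


def best_individual(history: Sequence[FitnessRecord]) -> Chromosome:
    """Lexicographic maximum over all evaluated records (accuracy first,
    then any secondary objective); ties keep the earliest discovery."""
    if not history:
        raise ValueError("fitness history is empty")
    best = history[0]
    for rec in history[1:]:
        if rec.objectives > best.objectives:
            best = rec
    return best.chromosome


@dataclass
class GAResult:
    best: Chromosome
    best_objectives: tuple
    per_generation: list[dict] = field(default_factory=list)

    def write_csv(self, path) -> None:
        with open(Path(path), "w", newline="") as handle:
            writer = csv.DictWriter(
                handle, fieldnames=["generation", "best_fitness", "mean_fitness"]
            )
            writer.writeheader()
            writer.writerows(self.per_generation)


def run_ga(
    evaluator: Callable[[Chromosome], tuple],
    bounds: Sequence[GeneBound],
    config: GAConfig | None = None,
    seed: int = 0,
    kind: str = "stub",
) -> GAResult:
    """Full GA loop: init, evaluate, evolve for ``config.generations``."""
    config = config or GAConfig()
    rng = np.random.default_rng(seed)
    population = init_population(config.population_size, bounds, rng, kind)
    all_records: list[FitnessRecord] = []
    per_generation = []
    for generation in range(config.generations):
        records = evaluate_fitness(population, evaluator)
        all_records.extend(records)
        primary = [r.objectives[0] for r in records]
        per_generation.append(
            {
                "generation": generation,
                "best_fitness": max(primary),
                "mean_fitness": float(np.mean(primary)),
            }
        )
        population = evolve(population, records, bounds, config, rng)
    best = best_individual(all_records)
    best_obj = max(r.objectives for r in all_records)
    return GAResult(best=best, best_objectives=best_obj,
                    per_generation=per_generation)
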