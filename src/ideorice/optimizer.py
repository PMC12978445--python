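"""Genetic-algorithm ideotype search over the eight selected coefficients.

Fitness is harvest index plus min-max normalized water-use efficiency
(bounds 2 and 15 kg/ha/mm), so it lives in [0, 2] with equal weight on the
two terms. Operators: roulette-wheel parent selection, whole-mating
arithmetic crossover, and adaptive single-gene Gaussian mutation whose gene
choice can be biased by sensitivity weights. The population is generational
with one elite re-inserted over the worst, which makes the best-so-far
trace non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ideorice.crop_model import (
    DEFAULT_COEFFICIENTS,
    DEFAULT_CONFIG,
    OPTIMIZED_COEFFICIENTS,
    EnvironmentScenario,
    GeneticCoefficients,
    SimulationResult,
    SimulatorConfig,
    simulate,
)
from ideorice.sensitivity import ParameterSpace, default_space

__all__ = [
    "GAConfig",
    "FitnessRecord",
    "GARun",
    "wue_normalize",
    "hi_wue_fitness",
    "roulette_select",
    "arithmetic_crossover",
    "adaptive_mutate",
    "run_ga",
    "optimize_environment",
    "convergence_generation",
]


@dataclass(frozen=True)
class GAConfig:
    """Search settings; defaults follow the study configuration (40/15/0.7)."""

    space: ParameterSpace
    generations: int = 40
    pop_size: int = 15
    mutation_prob: float = 0.7
    wue_min: float = 2.0
    wue_max: float = 15.0
    elitism: bool = True
    seed: int = 0
    sensitivity_weights: np.ndarray | None = None  # per-coefficient, >= 0
    mutation_sd_fraction: float = 0.10             # of each coefficient's range
    #: subtract the generation minimum before the roulette draw; without it
    #: selection pressure vanishes once fitness differences are small
    fitness_windowing: bool = True

    def __post_init__(self) -> None:
        if self.generations < 1 or self.pop_size < 2:
            raise ValueError("generations >= 1 and pop_size >= 2 required")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.wue_min >= self.wue_max:
            raise ValueError("wue_min < wue_max required")
        if self.sensitivity_weights is not None:
            w = np.asarray(self.sensitivity_weights, dtype=float)
            if w.size != self.space.k or np.any(w < 0) or w.sum() == 0:
                raise ValueError("weights must be non-negative with positive sum")
            object.__setattr__(self, "sensitivity_weights", w)


@dataclass(frozen=True)
class FitnessRecord:
    hi: float
    wue: float
    wue_norm: float
    fitness: float


def wue_normalize(wue: float, config: GAConfig) -> float:
    """Min-max normalization of WUE to [0, 1], clamped outside the bounds."""
    x = (wue - config.wue_min) / (config.wue_max - config.wue_min)
    return min(1.0, max(0.0, x))


def hi_wue_fitness(result: SimulationResult, config: GAConfig) -> FitnessRecord:
    """Integrated fitness HI + WUEnorm in [0, 2]; flagged failures score 0."""
    if not result.flowered or result.cum_et <= 0:
        return FitnessRecord(hi=0.0, wue=0.0, wue_norm=0.0, fitness=0.0)
    wn = wue_normalize(result.wue, config)
    return FitnessRecord(
        hi=result.hi, wue=result.wue, wue_norm=wn, fitness=result.hi + wn
    )


def roulette_select(
    population: np.ndarray,
    fitnesses: np.ndarray,
    rng: np.random.Generator,
    n_pairs: int | None = None,
) -> list[tuple[int, int]]:
    """Fitness-proportional parent pairs, sampled with replacement.

    All-zero fitness falls back to uniform probabilities. A self-mating is
    re-drawn once (and kept if it recurs).
    """
    n = len(population)
    if n == 0:
        raise ValueError("empty population")
    f = np.asarray(fitnesses, dtype=float)
    if np.any(f < 0):
        raise ValueError("fitnesses must be non-negative")
    total = f.sum()
    probs = np.full(n, 1.0 / n) if total == 0 else f / total
    if n_pairs is None:
        n_pairs = (n + 1) // 2
    pairs = []
    for _ in range(n_pairs):
        a = int(rng.choice(n, p=probs))
        b = int(rng.choice(n, p=probs))
        if b == a:
            b = int(rng.choice(n, p=probs))
        pairs.append((a, b))
    return pairs


def arithmetic_crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One lambda per mating; convex blends stay within the search bounds."""
    lam = rng.uniform()
    child_a = lam * parent_a + (1.0 - lam) * parent_b
    child_b = (1.0 - lam) * parent_a + lam * parent_b
    return child_a, child_b


def adaptive_mutate(
    individual: np.ndarray,
    config: GAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """With probability ``mutation_prob``, perturb one gene and clip to bounds.

    The gene is drawn proportionally to the sensitivity weights when
    provided (uniform otherwise); the perturbation is Gaussian with sd equal
    to ``mutation_sd_fraction`` of that coefficient's range.
    """
    if rng.uniform() >= config.mutation_prob:
        return individual.copy()
    space = config.space
    if config.sensitivity_weights is not None:
        probs = config.sensitivity_weights / config.sensitivity_weights.sum()
        j = int(rng.choice(space.k, p=probs))
    else:
        j = int(rng.integers(space.k))
    out = individual.copy()
    sd = config.mutation_sd_fraction * (space.upper[j] - space.lower[j])
    out[j] = np.clip(out[j] + rng.normal(0.0, sd), space.lower[j], space.upper[j])
    return out


@dataclass
class GARun:
    """Full optimization record: per-generation traces plus a flat archive."""

    config: GAConfig
    best_individual: np.ndarray
    best_fitness: float
    best_record: FitnessRecord
    best_per_generation: np.ndarray     # best-so-far trace, non-decreasing
    mean_per_generation: np.ndarray
    archive: pd.DataFrame               # generation, coefficients, HI, WUE, fitness
    n_evaluations: int

    def best_coefficients(self, base: GeneticCoefficients = DEFAULT_COEFFICIENTS) -> GeneticCoefficients:
        return base.with_values(self.config.space.names, self.best_individual)


def run_ga(
    evaluate: Callable[[np.ndarray], FitnessRecord],
    config: GAConfig,
) -> GARun:
    """Generational GA; deterministic under a fixed config seed.

    Each generation evaluates the current population, re-inserts the global
    best over the worst member (when elitism is on), then breeds the next
    population by roulette selection, arithmetic crossover and adaptive
    mutation. Evaluation failures must be expressed by the callable as
    fitness-0 records; the loop itself never raises on fitness values.
    """
    space = config.space
    rng = np.random.default_rng(config.seed)
    pop = space.lower + rng.uniform(size=(config.pop_size, space.k)) * (
        space.upper - space.lower
    )

    best_ind: np.ndarray | None = None
    best_rec: FitnessRecord | None = None
    best_trace = np.empty(config.generations)
    mean_trace = np.empty(config.generations)
    rows = []

    for gen in range(config.generations):
        records = [evaluate(ind) for ind in pop]
        fits = np.array([r.fitness for r in records])
        for ind, rec in zip(pop, records):
            row = {"generation": gen + 1}
            row.update({n: v for n, v in zip(space.names, ind)})
            row.update({"HI": rec.hi, "WUE": rec.wue, "fitness": rec.fitness})
            rows.append(row)

        gen_best = int(np.argmax(fits))
        if best_rec is None or fits[gen_best] > best_rec.fitness:
            best_rec = records[gen_best]
            best_ind = pop[gen_best].copy()
        if config.elitism:
            worst = int(np.argmin(fits))
            pop[worst] = best_ind
            fits[worst] = best_rec.fitness
            records[worst] = best_rec
        best_trace[gen] = best_rec.fitness
        mean_trace[gen] = fits.mean()

        if gen == config.generations - 1:
            break

        sel = fits - fits.min() if config.fitness_windowing else fits
        pairs = roulette_select(pop, sel, rng)
        children = []
        for a, b in pairs:
            ca, cb = arithmetic_crossover(pop[a], pop[b], rng)
            children.extend([ca, cb])
        pop = np.array(
            [adaptive_mutate(c, config, rng) for c in children[: config.pop_size]]
        )

    archive = pd.DataFrame(rows)
    return GARun(
        config=config,
        best_individual=best_ind,
        best_fitness=best_rec.fitness,
        best_record=best_rec,
        best_per_generation=best_trace,
        mean_per_generation=mean_trace,
        archive=archive,
        n_evaluations=len(archive),
    )


def optimize_environment(
    env: EnvironmentScenario,
    config: GAConfig | None = None,
    base: GeneticCoefficients = DEFAULT_COEFFICIENTS,
    sim_config: SimulatorConfig = DEFAULT_CONFIG,
    seed: int = 0,
) -> GARun:
    """Run the GA against the growth simulator for one environment."""
    if config is None:
        config = GAConfig(space=default_space(OPTIMIZED_COEFFICIENTS), seed=seed)

    def evaluate(vector: np.ndarray) -> FitnessRecord:
        coeffs = base.with_values(config.space.names, vector)
        result = simulate(coeffs, env, sim_config)
        return hi_wue_fitness(result, config)

    return run_ga(evaluate, config)


def convergence_generation(run: GARun, frac: float = 0.95) -> int:
    """Smallest generation (1-based) whose best fitness reaches
    ``frac`` of the final best fitness."""
    trace = run.best_per_generation
    if trace.size == 0:
        raise ValueError("run has no generations")
    target = frac * trace[-1]
    hits = np.nonzero(trace >= target)[0]
    return int(hits[0]) + 1
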