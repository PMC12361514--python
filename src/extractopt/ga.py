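"""Real-coded genetic algorithm over the three-factor extraction box.

Chromosomes are the three process settings in actual units (temperature,
time, ethanol %).  Parents are drawn by roulette-wheel (fitness-
proportional) selection on shifted fitness, recombined by single-point
crossover on gene boundaries, and mutated by per-gene uniform resampling
within bounds.  One elite individual is carried over unchanged by default,
which makes the best-fitness trace monotone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GAConfig",
    "Individual",
    "GARun",
    "MultiRunResult",
    "roulette_select",
    "single_point_crossover",
    "mutate",
    "run_ga",
    "multi_run",
]

Bounds = tuple[tuple[float, float], tuple[float, float], tuple[float, float]]

#: design-box bounds of the study, actual units
DEFAULT_BOUNDS: Bounds = ((45.0, 65.0), (5.0, 15.0), (0.0, 100.0))


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings (defaults follow the study configuration)."""

    population_size: int = 10
    crossover_rate: float = 0.85
    mutation_rate: float = 0.02
    max_iterations: int = 50
    elitism_count: int = 1
    patience: int = 10  # stop after this many iterations with best unchanged
    seed: int = 0
    bounds: Bounds = DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        if not (0.0 <= self.crossover_rate <= 1.0 and 0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population must be >= 2")
        for lo, hi in self.bounds:
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError("bounds must be finite with lo < hi")


@dataclass(eq=False)
class Individual:
    genes: np.ndarray  # 3 actual-unit values
    fitness: float = -np.inf

    def copy(self) -> "Individual":
        return Individual(self.genes.copy(), self.fitness)


@dataclass
class GARun:
    """Trace and outcome of one generational GA run."""

    best: Individual
    best_per_iteration: list[float] = field(default_factory=list)
    iterations_to_converge: int = -1


def roulette_select(population: Sequence[Individual], rng: np.random.Generator) -> Individual:
    """Sample one parent with probability proportional to shifted fitness.

    Non-negative fitness is used as-is (plain proportional selection);
    when any fitness is negative the whole vector is shifted by -min(f)
    plus eps = 1e-9 * range so the wheel stays well defined.  Equal
    fitness degenerates to uniform selection.
    """
    f = np.array([ind.fitness for ind in population])
    finite = np.isfinite(f)
    if not finite.any():
        return population[int(rng.integers(len(population)))]
    span = float(np.ptp(f[finite]))
    baseline = min(0.0, float(f[finite].min()))
    shifted = np.where(finite, f - baseline, 0.0)
    if shifted[finite].sum() <= 0 or (baseline < 0 and np.any(shifted[finite] == 0)):
        shifted[finite] += 1e-9 * span if span > 0 else 1.0
    probs = shifted / shifted.sum()
    return population[int(rng.choice(len(population), p=probs))]


def single_point_crossover(
    p1: Individual,
    p2: Individual,
    rng: np.random.Generator,
    rate: float,
) -> tuple[Individual, Individual]:
    """With probability ``rate`` cut at a gene boundary (after gene 1 or 2)
    and swap tails; otherwise return copies of the parents."""
    c1, c2 = p1.copy(), p2.copy()
    c1.fitness = c2.fitness = -np.inf
    if rng.random() < rate:
        cut = int(rng.integers(1, 3))  # in {1, 2}
        tail1 = c1.genes[cut:].copy()
        c1.genes[cut:] = c2.genes[cut:]
        c2.genes[cut:] = tail1
    return c1, c2


def mutate(
    ind: Individual,
    rng: np.random.Generator,
    rate: float,
    bounds: Bounds,
) -> Individual:
    """Per-gene uniform resampling within bounds, each with probability ``rate``."""
    out = ind.copy()
    for g, (lo, hi) in enumerate(bounds):
        if rng.random() < rate:
            out.genes[g] = rng.uniform(lo, hi)
            out.fitness = -np.inf
    np.clip(out.genes, [b[0] for b in bounds], [b[1] for b in bounds], out=out.genes)
    return out


def _evaluate(ind: Individual, objective: Callable[[np.ndarray], float]) -> None:
    val = float(objective(ind.genes))
    ind.fitness = val if math.isfinite(val) else -np.inf


def run_ga(objective: Callable[[np.ndarray], float], cfg: GAConfig) -> GARun:
    """One seeded generational GA maximising ``objective`` over the box."""
    rng = np.random.default_rng(cfg.seed)
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    pop = [
        Individual(rng.uniform(lo, hi)) for _ in range(cfg.population_size)
    ]
    for ind in pop:
        _evaluate(ind, objective)

    run = GARun(best=max(pop, key=lambda i: i.fitness).copy())
    stalled = 0
    for it in range(cfg.max_iterations):
        pop.sort(key=lambda i: i.fitness, reverse=True)
        next_pop = [pop[k].copy() for k in range(cfg.elitism_count)]
        while len(next_pop) < cfg.population_size:
            p1 = roulette_select(pop, rng)
            p2 = roulette_select(pop, rng)
            c1, c2 = single_point_crossover(p1, p2, rng, cfg.crossover_rate)
            next_pop.append(mutate(c1, rng, cfg.mutation_rate, cfg.bounds))
            if len(next_pop) < cfg.population_size:
                next_pop.append(mutate(c2, rng, cfg.mutation_rate, cfg.bounds))
        pop = next_pop
        for ind in pop:
            if not math.isfinite(ind.fitness):
                _evaluate(ind, objective)
        gen_best = max(pop, key=lambda i: i.fitness)
        if gen_best.fitness > run.best.fitness + 1e-9:
            run.best = gen_best.copy()
            stalled = 0
        else:
            stalled += 1
        run.best_per_iteration.append(run.best.fitness)
        if run.iterations_to_converge < 0 and stalled >= cfg.patience:
            run.iterations_to_converge = it + 1
            break
    if run.iterations_to_converge < 0:
        run.iterations_to_converge = len(run.best_per_iteration)
    return run


@dataclass
class MultiRunResult:
    """Aggregate of independent GA runs from one master seed."""

    best: Individual
    runs: list[GARun]

    @property
    def per_run_best_genes(self) -> np.ndarray:
        return np.vstack([r.best.genes for r in self.runs])

    @property
    def per_run_best_fitness(self) -> np.ndarray:
        return np.array([r.best.fitness for r in self.runs])

    def dispersion(self) -> np.ndarray:
        """Between-run SD of the best genes (one value per gene)."""
        return self.per_run_best_genes.std(axis=0, ddof=1)


def multi_run(
    objective: Callable[[np.ndarray], float],
    cfg: GAConfig,
    n_runs: int = 60,
) -> MultiRunResult:
    """``n_runs`` independent GA runs; per-run seeds derive from ``cfg.seed``."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    master = np.random.default_rng(cfg.seed)
    runs = []
    for _ in range(n_runs):
        sub = GAConfig(
            population_size=cfg.population_size,
            crossover_rate=cfg.crossover_rate,
            mutation_rate=cfg.mutation_rate,
            max_iterations=cfg.max_iterations,
            elitism_count=cfg.elitism_count,
            patience=cfg.patience,
            seed=int(master.integers(2**31)),
            bounds=cfg.bounds,
        )
        runs.append(run_ga(objective, sub))
    best = max(runs, key=lambda r: r.best.fitness).best.copy()
    return MultiRunResult(best=best, runs=runs)
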