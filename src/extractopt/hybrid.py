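"""End-to-end surrogate-assisted optimization and the RSM head-to-head.

``ann_ga_optimize`` chains the pieces the way the study does: select and
train the neural surrogate on the factorial dataset, then maximise its
prediction over the design box with the genetic algorithm (60 independent
runs by default, best-of-runs reported).  ``compare_strategies`` runs the
polynomial and surrogate routes on identical data and returns both optima
side by side.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from . import ann, ga
from .design import Condition, FFDDataset, from_coded, to_coded
from .rsm import FitDiagnostics, QuadraticModel, fit_quadratic, maximize_surface, predict

__all__ = ["OptimumReport", "ComparisonReport", "ann_ga_optimize", "compare_strategies"]


@dataclass
class OptimumReport:
    """Outcome of one surrogate + GA optimization."""

    condition: Condition
    predicted_tas: float
    hidden_size: int
    surrogate_metrics: dict[str, dict[str, float]]
    ga_best_fitness: float
    per_run_best: np.ndarray  # (n_runs, 3) actual units
    per_run_fitness: np.ndarray
    convergence_traces: list[list[float]]
    master_seed: int
    surrogate: object = None  # the optimised predictor (not serialised)

    def to_dict(self) -> dict:
        return {
            "condition": {
                "temperature": self.condition.temperature,
                "time": self.condition.time,
                "ethanol_pct": self.condition.ethanol_pct,
            },
            "predicted_tas": self.predicted_tas,
            "hidden_size": self.hidden_size,
            "surrogate_metrics": self.surrogate_metrics,
            "ga_best_fitness": self.ga_best_fitness,
            "per_run_best": self.per_run_best.tolist(),
            "per_run_fitness": self.per_run_fitness.tolist(),
            "master_seed": self.master_seed,
        }


def ann_ga_optimize(
    dataset: FFDDataset,
    train_cfg: ann.TrainConfig | None = None,
    ga_cfg: ga.GAConfig | None = None,
    hidden_range: Sequence[int] = range(1, 11),
    n_runs: int = 60,
    surrogate: ann.MLPSurrogate | None = None,
) -> OptimumReport:
    """Architecture search + Levenberg-Marquardt training, then multi-run GA.

    The GA works in actual units over the design box (no extrapolation:
    the surrogate is only trusted where it saw data).  Passing
    ``surrogate`` skips the search and optimises that network instead.
    """
    train_cfg = train_cfg or ann.TrainConfig()
    bounds = tuple(
        (f.levels[0], f.levels[2]) for f in dataset.factors
    )
    ga_cfg = ga_cfg or ga.GAConfig(seed=train_cfg.seed, bounds=bounds)

    if surrogate is None:
        search = ann.architecture_search(dataset, hidden_range, train_cfg)
        net = search.best.net
        hidden = search.best_hidden
        metrics = search.best.metrics
    else:
        net = surrogate
        hidden = net.hidden_size
        metrics = {}

    agg = ga.multi_run(net.predict_one, ga_cfg, n_runs=n_runs)
    cond = Condition(*agg.best.genes)
    return OptimumReport(
        condition=cond,
        predicted_tas=float(agg.best.fitness),
        hidden_size=hidden,
        surrogate_metrics=metrics,
        ga_best_fitness=float(agg.best.fitness),
        per_run_best=agg.per_run_best_genes,
        per_run_fitness=agg.per_run_best_fitness,
        convergence_traces=[r.best_per_iteration for r in agg.runs],
        master_seed=ga_cfg.seed,
        surrogate=net,
    )


@dataclass
class ComparisonReport:
    """RSM and surrogate-GA optima computed from identical data."""

    rsm_model: QuadraticModel
    rsm_diagnostics: FitDiagnostics
    rsm_optimum: Condition
    rsm_predicted_tas: float
    ann_ga: OptimumReport
    master_seed: int

    def to_dict(self) -> dict:
        return {
            "rsm": {
                "coefficients": self.rsm_model.by_name(),
                "r2": self.rsm_diagnostics.r2,
                "r2_adjusted": self.rsm_diagnostics.r2_adjusted,
                "r2_predicted": self.rsm_diagnostics.r2_predicted,
                "optimum": {
                    "temperature": self.rsm_optimum.temperature,
                    "time": self.rsm_optimum.time,
                    "ethanol_pct": self.rsm_optimum.ethanol_pct,
                },
                "predicted_tas": self.rsm_predicted_tas,
            },
            "ann_ga": self.ann_ga.to_dict(),
            "master_seed": self.master_seed,
        }


def compare_strategies(
    dataset: FFDDataset,
    train_cfg: ann.TrainConfig | None = None,
    ga_cfg: ga.GAConfig | None = None,
    hidden_range: Sequence[int] = range(1, 11),
    n_runs: int = 60,
) -> ComparisonReport:
    """Run both optimization strategies on the same dataset."""
    train_cfg = train_cfg or ann.TrainConfig()
    model, diag = fit_quadratic(dataset)
    x_opt, val = maximize_surface(model, dataset.factors)
    report = ann_ga_optimize(
        dataset, train_cfg=train_cfg, ga_cfg=ga_cfg,
        hidden_range=hidden_range, n_runs=n_runs,
    )
    return ComparisonReport(
        rsm_model=model,
        rsm_diagnostics=diag,
        rsm_optimum=from_coded(x_opt, dataset.factors),
        rsm_predicted_tas=float(val),
        ann_ga=report,
        master_seed=train_cfg.seed,
    )
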