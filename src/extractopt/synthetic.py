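"""Synthetic factorial datasets with the structure the analysis assumes.

Ground truth is a known quadratic surface on coded factors (optionally
perturbed by a cubic term, for lack-of-fit power studies); replicate noise
is homoscedastic Gaussian, matching the near-constant replicate SDs
(~0.01-0.07 mmol/L) seen in real TAS assay triplicates.  All randomness
flows through one explicit seeded generator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .design import (
    DEFAULT_FACTORS,
    Condition,
    FFDDataset,
    FactorSpec,
    ReplicateSet,
    load_dataset,
    to_coded,
)
from .rsm import QuadraticModel, fit_quadratic, predict

__all__ = ["TrueSurface", "NoiseSpec", "generate_ffd", "table1_like"]


@dataclass(frozen=True)
class TrueSurface:
    """Ground-truth response surface: a quadratic plus optional cubic bump."""

    model: QuadraticModel
    #: coefficient on the third-order term x1^2 x2 (model misspecification).
    #: Note a pure x^3 term would be aliased with the linear term on a
    #: 3-level design, so this mixed cubic is the detectable choice.
    cubic_amplitude: float = 0.0

    def evaluate(self, coded: np.ndarray) -> np.ndarray:
        coded = np.atleast_2d(coded)
        y = predict(self.model, coded)
        if self.cubic_amplitude:
            y = y + self.cubic_amplitude * coded[:, 0] ** 2 * coded[:, 1]
        return np.atleast_1d(y)


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate noise: iid Gaussian, SD sigma, n replicates per condition."""

    sigma: float = 0.03
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.n_replicates < 2:
            raise ValueError("need sigma >= 0 and >= 2 replicates")


def generate_ffd(
    truth: TrueSurface,
    noise: NoiseSpec,
    factors: tuple[FactorSpec, FactorSpec, FactorSpec] = DEFAULT_FACTORS,
    rng: np.random.Generator | None = None,
) -> FFDDataset:
    """Evaluate the truth at all 27 design points and add replicate noise.

    The result is schema-identical to the packaged measured dataset.  A
    floor at 1e-6 keeps responses positive (the container requires it);
    irrelevant at the response scales this generator is meant for.
    """
    rng = rng if rng is not None else np.random.default_rng(noise.seed)
    records = []
    for combo in itertools.product(*(f.levels for f in factors)):
        c = Condition(*combo)
        mu = float(truth.evaluate(to_coded(c, factors))[0])
        ys = mu + noise.sigma * rng.standard_normal(noise.n_replicates)
        records.append(ReplicateSet(c, tuple(np.maximum(ys, 1e-6))))
    return FFDDataset(factors=factors, records=tuple(records))


def table1_like(seed: int = 0, sigma: float = 0.03) -> FFDDataset:
    """A dataset statistically resembling the packaged measured table.

    Truth is the quadratic fitted to the packaged fixture; replicate noise
    sigma defaults to 0.03 mmol/L, the typical fixture replicate SD.
    """
    model, _ = fit_quadratic(load_dataset("table1"))
    return generate_ffd(
        TrueSurface(model), NoiseSpec(sigma=sigma, n_replicates=3, seed=seed)
    )
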