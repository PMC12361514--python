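"""Second-order response-surface modelling on coded factors.

The model is the standard full quadratic in three coded variables,

    y = b0 + sum_i bi xi + sum_{i<j} bij xi xj + sum_i bii xi^2,

fitted by ordinary least squares to replicate-level observations.  The
design matrix and normal equations are formed explicitly and solved by QR
(``numpy.linalg.lstsq``); nothing is delegated to a formula engine, so the
coefficient bookkeeping (keyed by factor *name*, never by symbol index) is
fully under this module's control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .design import DEFAULT_FACTORS, FFDDataset, FactorSpec, from_coded

__all__ = [
    "QuadraticModel",
    "FitDiagnostics",
    "design_matrix",
    "fit_quadratic",
    "predict",
    "maximize_surface",
    "lack_of_fit",
]

#: pairwise interaction order (factor-index pairs) used throughout
INTERACTION_PAIRS = ((0, 1), (0, 2), (1, 2))


@dataclass(frozen=True)
class QuadraticModel:
    """Ten coded-scale coefficients of a full quadratic surface."""

    b0: float
    b_lin: tuple[float, float, float]
    b_int: tuple[float, float, float]  # ordered (12, 13, 23)
    b_quad: tuple[float, float, float]
    factor_names: tuple[str, str, str] = tuple(f.name for f in DEFAULT_FACTORS)

    def __post_init__(self) -> None:
        coefs = np.array([self.b0, *self.b_lin, *self.b_int, *self.b_quad])
        if not np.all(np.isfinite(coefs)):
            raise ValueError("coefficients must be finite")

    @property
    def coefficients(self) -> np.ndarray:
        """Length-10 vector ordered [1, x1, x2, x3, x1x2, x1x3, x2x3, x1^2, x2^2, x3^2]."""
        return np.array([self.b0, *self.b_lin, *self.b_int, *self.b_quad])

    def by_name(self) -> dict[str, float]:
        """Coefficients keyed by factor name (the only supported labelling)."""
        out = {"intercept": self.b0}
        for name, b in zip(self.factor_names, self.b_lin):
            out[f"{name}:linear"] = b
        for (i, j), b in zip(INTERACTION_PAIRS, self.b_int):
            out[f"{self.factor_names[i]}x{self.factor_names[j]}"] = b
        for name, b in zip(self.factor_names, self.b_quad):
            out[f"{name}:quadratic"] = b
        return out

    def hessian(self) -> np.ndarray:
        """3x3 Hessian of the surface in coded units."""
        (b12, b13, b23) = self.b_int
        q1, q2, q3 = self.b_quad
        return np.array(
            [[2 * q1, b12, b13], [b12, 2 * q2, b23], [b13, b23, 2 * q3]]
        )


@dataclass(frozen=True)
class FitDiagnostics:
    """Goodness-of-fit summary of a quadratic response-surface fit.

    ``r2``/``r2_adjusted`` are computed on the replicate-level rows the model
    was fitted to.  ``r2_predicted`` is the leave-one-out (PRESS) statistic
    computed on the condition means — the "predicted R2" convention of
    response-surface software.
    """

    r2: float
    r2_adjusted: float
    r2_predicted: float
    ss_model: float
    ss_residual: float
    ss_total: float
    lof_f: float
    lof_p: float
    n_obs: int
    n_params: int


def design_matrix(x: np.ndarray) -> np.ndarray:
    """Build the 10-column quadratic design matrix from (n, 3) coded points."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x1, x2, x3 = x[:, 0], x[:, 1], x[:, 2]
    return np.column_stack(
        [
            np.ones(len(x)),
            x1,
            x2,
            x3,
            x1 * x2,
            x1 * x3,
            x2 * x3,
            x1**2,
            x2**2,
            x3**2,
        ]
    )


def _press_r2(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out predicted R2 via the hat-matrix shortcut."""
    H = X @ np.linalg.solve(X.T @ X, X.T)
    resid = y - H @ y
    press = float(np.sum((resid / (1.0 - np.diag(H))) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / sst


def fit_quadratic(d: FFDDataset) -> tuple[QuadraticModel, FitDiagnostics]:
    """OLS fit of the full quadratic to all replicate-level observations."""
    X = design_matrix(d.coded_matrix())
    y = d.responses()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient quadratic design")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    model = QuadraticModel(
        b0=float(beta[0]),
        b_lin=tuple(beta[1:4]),
        b_int=tuple(beta[4:7]),
        b_quad=tuple(beta[7:10]),
        factor_names=tuple(f.name for f in d.factors),
    )
    yhat = X @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - yhat) ** 2))
    ssm = sst - sse
    n, p = X.shape
    r2 = 1.0 - sse / sst
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    # predicted R2 on condition means (the summary the surface is judged on)
    smry = d.summary()
    Xm = design_matrix(
        np.column_stack(
            [
                d.factors[0].code(smry["temperature_C"].to_numpy()),
                d.factors[1].code(smry["time_h"].to_numpy()),
                d.factors[2].code(smry["ethanol_pct"].to_numpy()),
            ]
        )
    )
    r2_pred = _press_r2(Xm, smry["mean"].to_numpy())
    if d.n_replicates >= 2:
        try:
            lof_f, lof_p = lack_of_fit(d, model)
        except ZeroDivisionError:  # replicates are (numerically) identical
            lof_f, lof_p = float("nan"), float("nan")
    else:
        lof_f, lof_p = float("nan"), float("nan")
    diag = FitDiagnostics(
        r2=r2,
        r2_adjusted=r2_adj,
        r2_predicted=r2_pred,
        ss_model=ssm,
        ss_residual=sse,
        ss_total=sst,
        lof_f=lof_f,
        lof_p=lof_p,
        n_obs=n,
        n_params=p,
    )
    return model, diag


def predict(m: QuadraticModel, x: Sequence[float]) -> float | np.ndarray:
    """Evaluate the surface at coded point(s) x ((3,) or (n, 3))."""
    arr = np.asarray(x, dtype=float)
    out = design_matrix(arr) @ m.coefficients
    return float(out[0]) if arr.ndim == 1 else out


def maximize_surface(
    m: QuadraticModel,
    factors: Sequence[FactorSpec] = DEFAULT_FACTORS,
    grid_step: float = 0.01,
) -> tuple[np.ndarray, float]:
    """Global maximum of the surface over the coded cube [-1, 1]^3.

    Dense grid scan (default step 0.01) sliced along x1 to bound memory,
    followed by a bounded local polish; the interior stationary point (from
    the 3x3 linear gradient system) is checked as an extra candidate when
    it falls inside the cube.  Deterministic.
    """
    axis = np.arange(-1.0, 1.0 + grid_step / 2, grid_step)
    g2, g3 = np.meshgrid(axis, axis, indexing="ij")
    b = m.coefficients
    best_val, best_x = -np.inf, None
    for x1 in axis:
        vals = (
            b[0]
            + b[1] * x1
            + b[2] * g2
            + b[3] * g3
            + b[4] * x1 * g2
            + b[5] * x1 * g3
            + b[6] * g2 * g3
            + b[7] * x1**2
            + b[8] * g2**2
            + b[9] * g3**2
        )
        k = np.unravel_index(np.argmax(vals), vals.shape)
        if vals[k] > best_val:
            best_val = float(vals[k])
            best_x = np.array([x1, g2[k], g3[k]])

    candidates = [best_x]
    H = m.hessian()
    if abs(np.linalg.det(H)) > 1e-12:
        xs = np.linalg.solve(H, -np.asarray(m.b_lin))
        if np.all(np.abs(xs) <= 1.0):
            candidates.append(xs)
    best_x, best_val = None, -np.inf
    for x0 in candidates:
        res = optimize.minimize(
            lambda x: -predict(m, x),
            x0,
            bounds=[(-1.0, 1.0)] * 3,
            method="L-BFGS-B",
        )
        if -res.fun > best_val:
            best_val, best_x = -float(res.fun), np.asarray(res.x)
    return best_x, best_val


def lack_of_fit(d: FFDDataset, m: QuadraticModel) -> tuple[float, float]:
    """Lack-of-fit F test of the quadratic against replicate pure error.

    Residual SS is split into pure error (sum over conditions of
    (n_i - 1) s_i^2, df = sum (n_i - 1)) and lack of fit (remainder,
    df = n_conditions - n_params).  Requires >=2 replicates per condition
    and nonzero pure error.
    """
    if d.n_replicates < 2:
        raise ValueError("lack-of-fit needs >=2 replicates per condition")
    y = d.responses()
    yhat = design_matrix(d.coded_matrix()) @ m.coefficients
    sse = float(np.sum((y - yhat) ** 2))
    smry = d.summary()
    ss_pe = float(np.sum((smry["n"] - 1) * smry["sd"] ** 2))
    df_pe = int(np.sum(smry["n"] - 1))
    df_lof = len(smry) - 10
    ss_lof = max(sse - ss_pe, 0.0)
    # 'zero' pure error up to rounding dust relative to the response scale
    if ss_pe <= 1e-20 * max(float(np.sum(y**2)), 1.0):
        raise ZeroDivisionError("zero pure error: lack-of-fit F undefined")
    f = (ss_lof / df_lof) / (ss_pe / df_pe)
    p = float(stats.f.sf(f, df_lof, df_pe))
    return f, p
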