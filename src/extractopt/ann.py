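"""A 3-H-1 multilayer perceptron surrogate trained by Levenberg-Marquardt.

The network maps (temperature, time, ethanol %) to predicted total
antioxidant status.  Hidden units use the hyperbolic-tangent sigmoid
("tansig"), the output unit is linear ("purelin").  Inputs and the output
are min-max scaled to [-1, 1] before training, the standard practice for
tansig networks; predictions are returned in original units.

Training minimises the sum of squared errors with the damped Gauss-Newton
(Levenberg-Marquardt) scheme: the Jacobian of the residual vector with
respect to all weights is assembled by backpropagation each epoch, the
damped normal equations ``(J'J + lambda I) step = -J'r`` are solved, the
damping ``lambda`` shrinks after accepted steps and grows after rejected
ones.  Early stopping monitors a held-out validation set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .design import DEFAULT_FACTORS, FFDDataset, FactorSpec

__all__ = [
    "AffineScaler",
    "MLPSurrogate",
    "TrainConfig",
    "SplitSpec",
    "mse",
    "mape",
    "pearson_r",
    "split_conditions",
    "lm_train",
    "architecture_search",
]

#: evaluation beyond this many coded half-ranges from the box centre is clamped
EXTRAPOLATION_GUARD = 1.5


@dataclass(frozen=True)
class AffineScaler:
    """Per-dimension affine map x -> (x - center) / half onto [-1, 1]."""

    center: np.ndarray
    half: np.ndarray

    @classmethod
    def from_bounds(cls, lo: Sequence[float], hi: Sequence[float]) -> "AffineScaler":
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        return cls(center=(lo + hi) / 2.0, half=(hi - lo) / 2.0)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.center) / self.half

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.half + self.center


@dataclass
class MLPSurrogate:
    """Weights and scalers of a trained (or freshly initialised) 3-H-1 net."""

    input_weights: np.ndarray  # (H, 3)
    input_bias: np.ndarray  # (H,)
    output_weights: np.ndarray  # (H,)
    output_bias: float
    input_scaling: AffineScaler
    output_scaling: AffineScaler

    def __post_init__(self) -> None:
        H = self.hidden_size
        if not (1 <= H <= 20):
            raise ValueError(f"hidden size must be 1..20, got {H}")
        if self.input_weights.shape != (H, 3) or self.input_bias.shape != (H,):
            raise ValueError("inconsistent weight shapes")

    @property
    def hidden_size(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_weights(self) -> int:
        return 5 * self.hidden_size + 1

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [
                self.input_weights.ravel(),
                self.input_bias,
                self.output_weights,
                [self.output_bias],
            ]
        )

    def unpack(self, theta: np.ndarray) -> None:
        H = self.hidden_size
        self.input_weights = theta[: 3 * H].reshape(H, 3)
        self.input_bias = theta[3 * H : 4 * H]
        self.output_weights = theta[4 * H : 5 * H]
        self.output_bias = float(theta[5 * H])

    def _forward_scaled(self, z: np.ndarray) -> np.ndarray:
        a = np.tanh(z @ self.input_weights.T + self.input_bias)
        return a @ self.output_weights + self.output_bias

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predict TAS (original units) at (n, 3) actual-unit inputs.

        Points farther than :data:`EXTRAPOLATION_GUARD` scaled units from
        the training box centre are clamped to the guard with a warning.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z = self.input_scaling.transform(x)
        if np.any(np.abs(z) > EXTRAPOLATION_GUARD):
            warnings.warn(
                "input beyond the surrogate's extrapolation guard; clamping",
                stacklevel=2,
            )
            z = np.clip(z, -EXTRAPOLATION_GUARD, EXTRAPOLATION_GUARD)
        return self.output_scaling.inverse(self._forward_scaled(z))

    def predict_one(self, condition) -> float:
        """Point prediction for a single Condition or length-3 sequence."""
        vals = (
            condition.as_tuple() if hasattr(condition, "as_tuple") else condition
        )
        return float(self.predict(np.asarray(vals, dtype=float))[0])


@dataclass(frozen=True)
class TrainConfig:
    """Levenberg-Marquardt training hyperparameters."""

    max_epochs: int = 500
    validation_checks: int = 50
    error_tolerance: float = 1e-5  # on scaled-space training MSE
    lm_lambda_init: float = 1e-3
    lm_lambda_up: float = 10.0
    lm_lambda_down: float = 0.1
    lm_lambda_max: float = 1e10
    restarts: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.max_epochs,
            self.validation_checks,
            self.error_tolerance,
            self.lm_lambda_init,
            self.lm_lambda_up,
            self.lm_lambda_down,
        ) <= 0:
            raise ValueError("all training parameters must be positive")
        if self.validation_checks > self.max_epochs:
            raise ValueError("validation_checks must be <= max_epochs")


@dataclass(frozen=True)
class SplitSpec:
    """Assignment of whole conditions (replicates stay together) to subsets."""

    train_idx: tuple[int, ...]
    val_idx: tuple[int, ...]
    test_idx: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        all_idx = sorted(self.train_idx + self.val_idx + self.test_idx)
        if all_idx != list(range(len(all_idx))):
            raise ValueError("every condition must be assigned exactly once")


def split_conditions(
    n_conditions: int,
    seed: int,
    fractions: tuple[float, float, float] = (0.80, 0.10, 0.10),
) -> SplitSpec:
    """Seeded 80/10/10 split of conditions (21/3/3 for the 27-point design).

    Fractions are rounded to whole conditions with at least one condition in
    each of validation and test; replicates of a condition never straddle
    subsets.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_conditions)
    n_val = max(1, round(fractions[1] * n_conditions))
    n_test = max(1, round(fractions[2] * n_conditions))
    n_train = n_conditions - n_val - n_test
    return SplitSpec(
        train_idx=tuple(int(i) for i in order[:n_train]),
        val_idx=tuple(int(i) for i in order[n_train : n_train + n_val]),
        test_idx=tuple(int(i) for i in order[n_train + n_val :]),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# error metrics


def _pairs(e, p) -> tuple[np.ndarray, np.ndarray]:
    e = np.asarray(e, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    if e.shape != p.shape or e.size < 1:
        raise ValueError("experimental and predicted vectors must match, n >= 1")
    return e, p


def mse(e, p) -> float:
    """Mean squared error (1/n) sum (e_i - p_i)^2."""
    e, p = _pairs(e, p)
    return float(np.mean((e - p) ** 2))


def mape(e, p) -> float:
    """Mean absolute percentage error (1/n) sum |(e_i - p_i)/e_i| * 100."""
    e, p = _pairs(e, p)
    if np.any(e == 0):
        raise ValueError("MAPE undefined when an experimental value is zero")
    return float(np.mean(np.abs((e - p) / e)) * 100.0)


def pearson_r(e, p) -> float:
    """Sample Pearson correlation between experimental and predicted values."""
    e, p = _pairs(e, p)
    if np.ptp(e) == 0 or np.ptp(p) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(e, p)[0, 1])


# ---------------------------------------------------------------------------
# Levenberg-Marquardt training


def _init_net(
    hidden: int,
    in_scaler: AffineScaler,
    out_scaler: AffineScaler,
    rng: np.random.Generator,
) -> MLPSurrogate:
    # uniform(-0.5, 0.5) init; small enough to start tansig units in their
    # near-linear range for 3 scaled inputs
    return MLPSurrogate(
        input_weights=rng.uniform(-0.5, 0.5, size=(hidden, 3)),
        input_bias=rng.uniform(-0.5, 0.5, size=hidden),
        output_weights=rng.uniform(-0.5, 0.5, size=hidden),
        output_bias=float(rng.uniform(-0.5, 0.5)),
        input_scaling=in_scaler,
        output_scaling=out_scaler,
    )


def _jacobian(net: MLPSurrogate, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predictions and d(prediction)/d(theta) in scaled space, by backprop."""
    a = np.tanh(z @ net.input_weights.T + net.input_bias)  # (n, H)
    yhat = a @ net.output_weights + net.output_bias
    d = (1.0 - a**2) * net.output_weights  # (n, H): dyhat/d(pre-activation)
    J_w1 = d[:, :, None] * z[:, None, :]  # (n, H, 3)
    J = np.concatenate(
        [J_w1.reshape(len(z), -1), d, a, np.ones((len(z), 1))], axis=1
    )
    return yhat, J


@dataclass
class TrainTrace:
    """Per-epoch record of a Levenberg-Marquardt run (scaled-space MSE)."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = -1


def lm_train(
    net: MLPSurrogate,
    z_train: np.ndarray,
    y_train: np.ndarray,
    z_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig,
) -> TrainTrace:
    """Train ``net`` in place; returns the per-epoch trace.

    Inputs/targets are already in scaled space.  The weights left on the
    network are those of the best validation epoch (early-stopping
    semantics); with an empty validation set the final weights are kept.
    """
    theta = net.pack()
    lam = cfg.lm_lambda_init
    n = len(z_train)
    have_val = len(z_val) > 0

    yhat, J = _jacobian(net, z_train)
    r = yhat - y_train
    sse = float(r @ r)
    trace = TrainTrace()
    best_val = np.inf
    best_theta = theta.copy()
    checks = 0

    for epoch in range(cfg.max_epochs):
        if not np.isfinite(sse):
            trace.stop_reason = "non-finite loss"
            raise FloatingPointError("non-finite training loss")
        JtJ = J.T @ J
        Jtr = J.T @ r
        if float(Jtr @ Jtr) == 0.0:
            trace.stop_reason = "zero gradient"
            break
        accepted = False
        while lam <= cfg.lm_lambda_max:
            try:
                step = np.linalg.solve(
                    JtJ + lam * np.eye(len(theta)), -Jtr
                )
            except np.linalg.LinAlgError:
                lam *= cfg.lm_lambda_up
                continue
            net.unpack(theta + step)
            yhat_new, J_new = _jacobian(net, z_train)
            r_new = yhat_new - y_train
            sse_new = float(r_new @ r_new)
            if np.isfinite(sse_new) and sse_new < sse:
                theta = theta + step
                r, J, sse = r_new, J_new, sse_new
                lam = max(lam * cfg.lm_lambda_down, 1e-20)
                accepted = True
                break
            lam *= cfg.lm_lambda_up
        if not accepted:
            net.unpack(theta)
            trace.stop_reason = "damping exhausted"
            break

        trace.train_mse.append(sse / n)
        if have_val:
            val = float(np.mean((net._forward_scaled(z_val) - y_val) ** 2))
            trace.val_mse.append(val)
            if val < best_val - 1e-15:
                best_val = val
                best_theta = theta.copy()
                trace.best_epoch = epoch
                checks = 0
            else:
                checks += 1
                if checks >= cfg.validation_checks:
                    trace.stop_reason = "validation checks"
                    break
        if sse / n < cfg.error_tolerance:
            trace.stop_reason = "error tolerance"
            break
    if not trace.stop_reason:
        trace.stop_reason = "max epochs"
    if have_val:
        net.unpack(best_theta)
    else:
        net.unpack(theta)
    return trace


# ---------------------------------------------------------------------------
# dataset-level training and architecture search


@dataclass
class FitResult:
    """A trained surrogate plus its per-subset error metrics."""

    net: MLPSurrogate
    split: SplitSpec
    trace: TrainTrace
    metrics: dict[str, dict[str, float]]  # subset -> {mse, mape, r}
    seed: int

    @property
    def val_mse(self) -> float:
        return self.metrics["val"]["mse"]


def _dataset_arrays(d: FFDDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(27,3) actual-unit conditions, (27, n_rep) responses, condition index."""
    X = np.array([rec.condition.as_tuple() for rec in d.records])
    Y = np.array([rec.responses for rec in d.records])
    return X, Y, np.arange(len(d.records))


def _subset_metrics(net: MLPSurrogate, X: np.ndarray, Y: np.ndarray) -> dict:
    preds = net.predict(X)  # (n_cond,)
    e = Y.ravel()
    p = np.repeat(preds, Y.shape[1])
    try:
        r = pearson_r(e, p)
    except ValueError:  # collapsed net: constant predictions
        r = float("nan")
    return {"mse": mse(e, p), "mape": mape(e, p), "r": r}


def train_surrogate(
    d: FFDDataset,
    hidden: int,
    cfg: TrainConfig | None = None,
    split: SplitSpec | None = None,
) -> FitResult:
    """Best-of-``cfg.restarts`` Levenberg-Marquardt training on a dataset.

    The 27 conditions are split 21/3/3 (replicates kept together), each
    restart draws fresh uniform(-0.5, 0.5) weights from a seeded stream, and
    the restart with the lowest validation MSE wins.
    """
    cfg = cfg or TrainConfig()
    X, Y, _ = _dataset_arrays(d)
    split = split or split_conditions(len(X), seed=cfg.seed)
    in_scaler = AffineScaler.from_bounds(X.min(axis=0), X.max(axis=0))
    tr = list(split.train_idx)
    va = list(split.val_idx)
    out_scaler = AffineScaler.from_bounds(Y[tr].min(), Y[tr].max())

    def scaled(idx):
        z = in_scaler.transform(X[idx])
        z = np.repeat(z, Y.shape[1], axis=0)
        y = out_scaler.transform(Y[idx].ravel())
        return z, y

    z_tr, y_tr = scaled(tr)
    z_va, y_va = scaled(va)

    master = np.random.default_rng(cfg.seed)
    best: FitResult | None = None
    for k in range(cfg.restarts):
        restart_seed = int(master.integers(2**31))
        rng = np.random.default_rng(restart_seed)
        net = _init_net(hidden, in_scaler, out_scaler, rng)
        trace = lm_train(net, z_tr, y_tr, z_va, y_va, cfg)
        metrics = {
            "train": _subset_metrics(net, X[tr], Y[tr]),
            "val": _subset_metrics(net, X[va], Y[va]),
            "test": _subset_metrics(net, X[list(split.test_idx)], Y[list(split.test_idx)]),
            "all": _subset_metrics(net, X, Y),
        }
        cand = FitResult(net=net, split=split, trace=trace, metrics=metrics, seed=restart_seed)
        if best is None or cand.val_mse < best.val_mse:
            best = cand
    assert best is not None
    return best


@dataclass
class SearchResult:
    """Outcome of a hidden-layer-size sweep."""

    best: FitResult
    best_hidden: int
    per_hidden: dict[int, FitResult]


def architecture_search(
    d: FFDDataset,
    hidden_range: Sequence[int] = range(1, 11),
    cfg: TrainConfig | None = None,
) -> SearchResult:
    """Sweep hidden sizes, ``cfg.restarts`` trainings each; lowest validation
    MSE wins, ties broken by the smaller network."""
    cfg = cfg or TrainConfig()
    split = split_conditions(len(d.records), seed=cfg.seed)
    per: dict[int, FitResult] = {}
    for h in hidden_range:
        # independent substream per width so results don't shift if the
        # range changes
        per[h] = train_surrogate(
            d, h, replace(cfg, seed=cfg.seed + 1000 * h), split=split
        )
    lowest = min(fr.val_mse for fr in per.values())
    # near-ties (within numerical noise of the winner) go to the smaller net
    tol = lowest * 1e-6 + 1e-12
    best_h = min(h for h, fr in per.items() if fr.val_mse <= lowest + tol)
    return SearchResult(best=per[best_h], best_hidden=best_h, per_hidden=per)


# ---------------------------------------------------------------------------
# portable weights file (plain text: shapes header, then row-major values)


def save_weights(net: MLPSurrogate, path: str | Path) -> None:
    lines = [f"hidden {net.hidden_size}"]
    for name in ("center", "half"):
        for tag, scaler in (("in", net.input_scaling), ("out", net.output_scaling)):
            vals = np.atleast_1d(getattr(scaler, name))
            lines.append(f"{tag}_{name} " + " ".join(repr(float(v)) for v in vals))
    lines.append("theta " + " ".join(repr(float(v)) for v in net.pack()))
    Path(path).write_text("\n".join(lines) + "\n")


def load_weights(path: str | Path) -> MLPSurrogate:
    fields = {}
    for line in Path(path).read_text().splitlines():
        key, *vals = line.split()
        fields[key] = np.array([float(v) for v in vals])
    H = int(fields["hidden"][0])
    net = MLPSurrogate(
        input_weights=np.zeros((H, 3)),
        input_bias=np.zeros(H),
        output_weights=np.zeros(H),
        output_bias=0.0,
        input_scaling=AffineScaler(fields["in_center"], fields["in_half"]),
        output_scaling=AffineScaler(fields["out_center"], fields["out_half"]),
    )
    net.unpack(fields["theta"])
    return net
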