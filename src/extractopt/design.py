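"""Three-level full-factorial extraction designs and their replicate data.

The central container is :class:`FFDDataset`: a complete 3x3x3 crossed design
over extraction temperature (degC), extraction time (h) and ethanol/water ratio
(%), with >=2 replicate responses (total antioxidant status, TAS, mmol/L) per
condition.  Factors are mapped to the coded scale -1/0/+1 so that regression
coefficients are comparable across units.
"""

from __future__ import annotations

import importlib.resources
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "Condition",
    "ReplicateSet",
    "FFDDataset",
    "DEFAULT_FACTORS",
    "to_coded",
    "from_coded",
    "load_dataset",
    "best_condition",
]

#: numeric tolerance when matching a condition value to a factor level
LEVEL_ATOL = 1e-9


class SchemaError(ValueError):
    """Raised when an input table is not a valid complete factorial dataset."""


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with exactly three increasing levels."""

    name: str
    levels: tuple[float, float, float]
    unit: str = ""

    def __post_init__(self) -> None:
        if len(self.levels) != 3:
            raise ValueError(f"factor {self.name!r} needs exactly 3 levels")
        lo, mid, hi = self.levels
        if not (lo < mid < hi):
            raise ValueError(f"levels of {self.name!r} must be strictly increasing")

    @property
    def center(self) -> float:
        return self.levels[1]

    @property
    def half_range(self) -> float:
        return (self.levels[2] - self.levels[0]) / 2.0

    def code(self, value: float) -> float:
        """Affine map level0 -> -1, level1 -> 0, level2 -> +1.

        The three levels are assumed (and validated for the default design)
        to be equally spaced; intermediate values map linearly.
        """
        return (value - self.center) / self.half_range

    def decode(self, coded: float) -> float:
        return self.center + self.half_range * coded


#: the study's design: 45/55/65 degC, 5/10/15 h, 0/50/100 % ethanol
DEFAULT_FACTORS: tuple[FactorSpec, FactorSpec, FactorSpec] = (
    FactorSpec("temperature", (45.0, 55.0, 65.0), "degC"),
    FactorSpec("time", (5.0, 10.0, 15.0), "h"),
    FactorSpec("ethanol_pct", (0.0, 50.0, 100.0), "%"),
)


@dataclass(frozen=True)
class Condition:
    """A point in the factor space, in actual units."""

    temperature: float
    time: float
    ethanol_pct: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.temperature, self.time, self.ethanol_pct)


def to_coded(
    c: Condition | Sequence[float],
    factors: Sequence[FactorSpec] = DEFAULT_FACTORS,
) -> np.ndarray:
    """Map a condition in actual units to the coded cube.

    Raises ``ValueError`` if any coordinate lies outside its factor's
    [low, high] range.
    """
    vals = c.as_tuple() if isinstance(c, Condition) else tuple(c)
    coded = np.empty(3)
    for i, (v, f) in enumerate(zip(vals, factors)):
        if v < f.levels[0] - LEVEL_ATOL or v > f.levels[2] + LEVEL_ATOL:
            raise ValueError(
                f"{f.name}={v} outside design range [{f.levels[0]}, {f.levels[2]}]"
            )
        coded[i] = f.code(v)
    return coded


def from_coded(
    x: Sequence[float], factors: Sequence[FactorSpec] = DEFAULT_FACTORS
) -> Condition:
    """Inverse of :func:`to_coded` (exact round trip)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (3,) or not np.all(np.isfinite(x)):
        raise ValueError("coded point must be 3 finite numbers")
    return Condition(*(f.decode(v) for v, f in zip(x, factors)))


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate responses observed at one design condition."""

    condition: Condition
    responses: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.responses) < 2:
            raise ValueError("need >=2 replicates per condition")
        arr = np.asarray(self.responses)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("responses must be finite and positive")

    @property
    def mean(self) -> float:
        return float(np.mean(self.responses))

    @property
    def sd(self) -> float:
        return float(np.std(self.responses, ddof=1))

    @property
    def n(self) -> int:
        return len(self.responses)


def _reconstruct_replicates(mean: float, sd: float, n: int) -> tuple[float, ...]:
    """Synthetic replicate triple {m-s, m, m+s} with exact mean m and SD s.

    Used when only (mean, SD, n) summaries are available; it is a
    reconstruction, not original data, but is exact for every statistic
    that depends on the data only through per-condition mean and SD
    (the ANOVA, the OLS fit, R-squared, lack-of-fit).  Only n=3 is
    supported because a symmetric exact triple requires it.
    """
    if n != 3:
        raise SchemaError(
            f"replicate reconstruction from summaries is defined for n=3, got n={n}"
        )
    return (mean - sd, mean, mean + sd)


@dataclass(frozen=True)
class FFDDataset:
    """A complete 3-level crossed design with uniform replicate count."""

    factors: tuple[FactorSpec, FactorSpec, FactorSpec] = DEFAULT_FACTORS
    records: tuple[ReplicateSet, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        expected = {
            combo
            for combo in itertools.product(*(f.levels for f in self.factors))
        }
        seen: set[tuple[float, float, float]] = set()
        for rec in self.records:
            key = self._level_key(rec.condition)
            if key is None:
                raise SchemaError(
                    f"condition {rec.condition} is not on the factor grid"
                )
            if key in seen:
                raise SchemaError(f"duplicate condition {rec.condition}")
            seen.add(key)
        missing = expected - seen
        if missing:
            raise SchemaError(f"missing design point(s): {sorted(missing)[:3]} ...")
        ns = {rec.n for rec in self.records}
        if len(ns) > 1:
            raise SchemaError(f"replicate count not uniform across conditions: {ns}")

    def _level_key(self, c: Condition) -> tuple[float, float, float] | None:
        key = []
        for v, f in zip(c.as_tuple(), self.factors):
            hits = [lv for lv in f.levels if abs(lv - v) <= LEVEL_ATOL]
            if not hits:
                return None
            key.append(hits[0])
        return tuple(key)

    @property
    def n_replicates(self) -> int:
        return self.records[0].n

    def to_long_frame(self) -> pd.DataFrame:
        """Replicate-level long table (one row per measurement)."""
        rows = [
            {
                "temperature_C": rec.condition.temperature,
                "time_h": rec.condition.time,
                "ethanol_pct": rec.condition.ethanol_pct,
                "replicate": i + 1,
                "TAS_mmol_L": y,
            }
            for rec in self.records
            for i, y in enumerate(rec.responses)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Per-condition mean, SD (n-1 denominator) and replicate count."""
        rows = [
            {
                "temperature_C": rec.condition.temperature,
                "time_h": rec.condition.time,
                "ethanol_pct": rec.condition.ethanol_pct,
                "mean": rec.mean,
                "sd": rec.sd,
                "n": rec.n,
            }
            for rec in self.records
        ]
        return pd.DataFrame(rows)

    def coded_matrix(self) -> np.ndarray:
        """(n_obs, 3) coded coordinates, one row per replicate observation."""
        return np.vstack(
            [
                np.tile(to_coded(rec.condition, self.factors), (rec.n, 1))
                for rec in self.records
            ]
        )

    def responses(self) -> np.ndarray:
        """(n_obs,) replicate responses aligned with :meth:`coded_matrix`."""
        return np.concatenate([np.asarray(rec.responses) for rec in self.records])

    def save_csv(self, path: str | Path, kind: str = "long") -> None:
        if kind == "long":
            self.to_long_frame().to_csv(path, index=False)
        elif kind == "summary":
            self.summary().to_csv(path, index=False)
        else:
            raise ValueError("kind must be 'long' or 'summary'")


_LONG_COLS = {"temperature_C", "time_h", "ethanol_pct", "replicate", "TAS_mmol_L"}
_SUMMARY_COLS = {"temperature_C", "time_h", "ethanol_pct", "mean", "sd", "n"}


def _fixture_path(name: str) -> Path:
    res = importlib.resources.files("extractopt.data") / f"{name}.csv"
    return Path(str(res))


def load_dataset(
    source: str | Path,
    factors: tuple[FactorSpec, FactorSpec, FactorSpec] = DEFAULT_FACTORS,
) -> FFDDataset:
    """Load a factorial dataset from CSV, or a packaged fixture by name.

    Two CSV dialects are accepted and auto-detected by column names:

    * long: ``temperature_C,time_h,ethanol_pct,replicate,TAS_mmol_L``
    * summary: ``temperature_C,time_h,ethanol_pct,mean,sd,n`` (replicates are
      reconstructed as the exact-moment triple {m-s, m, m+s})

    ``load_dataset("table1")`` returns the packaged 27-condition TAS dataset.
    """
    path = Path(source)
    if not path.suffix and not path.exists():
        path = _fixture_path(str(source))
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - reported as schema error
        raise SchemaError(f"cannot read {path}: {exc}") from exc

    cols = set(df.columns)
    if _LONG_COLS.issubset(cols):
        records = []
        grouped = df.groupby(["temperature_C", "time_h", "ethanol_pct"], sort=True)
        for (t, h, e), grp in grouped:
            ys = grp["TAS_mmol_L"].to_numpy(dtype=float)
            if not np.all(np.isfinite(ys)):
                raise SchemaError(f"non-numeric response at condition ({t},{h},{e})")
            records.append(ReplicateSet(Condition(t, h, e), tuple(ys)))
    elif _SUMMARY_COLS.issubset(cols):
        records = []
        for idx, row in df.iterrows():
            try:
                reps = _reconstruct_replicates(
                    float(row["mean"]), float(row["sd"]), int(row["n"])
                )
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"bad summary row {idx}: {exc}") from exc
            records.append(
                ReplicateSet(
                    Condition(
                        float(row["temperature_C"]),
                        float(row["time_h"]),
                        float(row["ethanol_pct"]),
                    ),
                    reps,
                )
            )
    else:
        raise SchemaError(
            f"unrecognized columns {sorted(cols)}; expected long "
            f"{sorted(_LONG_COLS)} or summary {sorted(_SUMMARY_COLS)}"
        )
    return FFDDataset(factors=factors, records=tuple(records))


def best_condition(d: FFDDataset) -> tuple[Condition, float]:
    """Condition with the highest replicate mean.

    Ties are broken lexicographically on (temperature, time, ethanol_pct).
    """
    if not d.records:
        raise ValueError("empty dataset")
    best = min(
        d.records, key=lambda r: (-r.mean, r.condition.as_tuple())
    )
    return best.condition, best.mean
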