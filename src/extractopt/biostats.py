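"""Replicate-assay statistics for comparing extraction protocols.

Everything here works from sufficient statistics — per-group (mean, SD, n)
records, :class:`AssaySummary` — so printed summary tables can be analysed
directly; raw replicate vectors are accepted wherever summaries are, and
the two routes agree exactly.

Implemented: one-way ANOVA with eta-squared, Duncan's multiple range test
with a compact letter display, the pooled-variance independent-samples
t-test, Cohen's d, z-based (and optionally t-based) confidence intervals,
and the oxidative stress index OSI = TOS / (TAS * 10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AssaySummary",
    "AnovaResult",
    "LetterDisplay",
    "one_way_anova",
    "duncan_mrt",
    "independent_t_test",
    "cohens_d",
    "ci_bounds",
    "osi",
    "load_assay_table",
]


@dataclass(frozen=True)
class AssaySummary:
    """A labelled mean/SD/n record, e.g. one cell of a results table."""

    label: str
    mean: float
    sd: float
    n: int
    group: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n < 2:
            raise ValueError("need n >= 2 replicates")

    @classmethod
    def from_raw(cls, label: str, values: Sequence[float], group: str = "") -> "AssaySummary":
        arr = np.asarray(values, dtype=float)
        return cls(
            label=label,
            mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)),
            n=len(arr),
            group=group,
        )


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta_squared: float
    ms_within: float


def _as_summaries(groups: Iterable) -> list[AssaySummary]:
    out = []
    for i, g in enumerate(groups):
        if isinstance(g, AssaySummary):
            out.append(g)
        else:
            out.append(AssaySummary.from_raw(label=f"group{i}", values=g))
    return out


def one_way_anova(groups: Iterable) -> AnovaResult:
    """One-way fixed-effects ANOVA from summaries or raw replicate vectors.

    Uses the sufficient-statistic decomposition SSW = sum (n_i - 1) s_i^2,
    SSB = sum n_i (ybar_i - ybar)^2, which is exact and identical to the
    raw-data computation.
    """
    gs = _as_summaries(groups)
    if len(gs) < 2:
        raise ValueError("need >= 2 groups")
    ns = np.array([g.n for g in gs], dtype=float)
    means = np.array([g.mean for g in gs])
    sds = np.array([g.sd for g in gs])
    grand = float(np.sum(ns * means) / ns.sum())
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(np.sum((ns - 1) * sds**2))
    df_b = len(gs) - 1
    df_w = int(ns.sum()) - len(gs)
    if ssw == 0.0:
        if ssb > 0:
            warnings.warn("zero within-group variance; F reported as +inf")
            return AnovaResult(np.inf, df_b, df_w, 0.0, 1.0, 0.0)
        return AnovaResult(0.0, df_b, df_w, 1.0, 0.0, 0.0)
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(F, df_b, df_w, p, ssb / (ssb + ssw), ssw / df_w)


# ---------------------------------------------------------------------------
# Duncan's multiple range test


def duncan_critical(alpha: float, span: int, df: int) -> float:
    """Duncan's least-significant-range multiplier.

    The studentized-range quantile at Duncan's protection level
    1 - (1 - alpha)^(span - 1) for a span of ``span`` ordered means.
    """
    level = 1.0 - (1.0 - alpha) ** (span - 1)
    return float(stats.studentized_range.ppf(1.0 - level, span, df))


@dataclass(frozen=True)
class LetterDisplay:
    """Compact letter display: groups sharing a letter are homogeneous."""

    labels: tuple[str, ...]  # in descending-mean order
    means: tuple[float, ...]
    letters: tuple[str, ...]  # letter string per label, aligned with labels

    def letters_by_label(self) -> dict[str, str]:
        return dict(zip(self.labels, self.letters))

    def share_letter(self, a: str, b: str) -> bool:
        la = set(self.letters_by_label()[a])
        lb = set(self.letters_by_label()[b])
        return bool(la & lb)


def duncan_mrt(groups: Iterable, alpha: float = 0.05) -> LetterDisplay:
    """Duncan's multiple range test with compact letters.

    Means are ranked; a pair spanning ``p`` ranks differs significantly when
    its difference exceeds LSR(p) = q_duncan(alpha, p, df_w) * sqrt(MSW/n).
    Duncan's step-down protection applies: no pair inside a non-significant
    range is declared significant.  Unbalanced groups use the harmonic mean
    n with a warning.
    """
    gs = _as_summaries(groups)
    an = one_way_anova(gs)
    ns = np.array([g.n for g in gs], dtype=float)
    if np.ptp(ns) > 0:
        warnings.warn("unbalanced groups: using harmonic mean n for Duncan ranges")
        n_eff = len(ns) / np.sum(1.0 / ns)
    else:
        n_eff = float(ns[0])
    order = np.argsort([-g.mean for g in gs], kind="stable")
    means = np.array([gs[i].mean for i in order])
    labels = tuple(gs[i].label for i in order)
    k = len(means)
    se = np.sqrt(an.ms_within / n_eff)
    lsr = {span: duncan_critical(alpha, span, an.df_within) * se for span in range(2, k + 1)}

    # ns[i][j]: ordered pair (i < j) not significantly different
    nonsig = np.eye(k, dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            nonsig[i, j] = nonsig[j, i] = (means[i] - means[j]) <= lsr[j - i + 1]
    # step-down protection: a non-significant outer range protects everything inside
    for span in range(k, 2, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if nonsig[i, j]:
                nonsig[i : j + 1, i : j + 1] = True

    # maximal homogeneous intervals -> letters (insert-and-absorb)
    intervals: list[tuple[int, int]] = []
    max_reach = -1
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        if j > max_reach or not intervals:
            intervals.append((i, j))
            max_reach = j
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letter_sets: list[list[str]] = [[] for _ in range(k)]
    # letters assigned from the smallest mean upward to mirror the 'a = lowest'
    # convention of the source tables
    for li, (i, j) in enumerate(reversed(intervals)):
        ch = alphabet[li % len(alphabet)]
        for idx in range(i, j + 1):
            letter_sets[idx].append(ch)
    letters = tuple("".join(sorted(ls)) for ls in letter_sets)
    return LetterDisplay(labels=labels, means=tuple(means), letters=letters)


# ---------------------------------------------------------------------------
# pairwise comparisons and effect sizes


def _pooled_sd(a: AssaySummary, b: AssaySummary) -> float:
    return np.sqrt(
        ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    )


def independent_t_test(a, b) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from summaries (or raw vectors).

    Returns (t, df, two-sided p).
    """
    a, b = _as_summaries([a, b])
    df = a.n + b.n - 2
    sp = _pooled_sd(a, b)
    if sp == 0.0:
        if a.mean == b.mean:
            return 0.0, df, 1.0
        warnings.warn("zero pooled variance with unequal means; p = 0")
        return np.inf if a.mean > b.mean else -np.inf, df, 0.0
    t = (a.mean - b.mean) / (sp * np.sqrt(1.0 / a.n + 1.0 / b.n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), df, p


def cohens_d(a, b) -> float:
    """Cohen's d: absolute mean difference over the pooled SD."""
    a, b = _as_summaries([a, b])
    sp = _pooled_sd(a, b)
    if sp == 0.0:
        if a.mean == b.mean:
            return 0.0
        warnings.warn("zero pooled SD; Cohen's d reported as +inf")
        return np.inf
    return float(abs(a.mean - b.mean) / sp)


def ci_bounds(
    s: AssaySummary, level: float = 0.95, use_t: bool = False
) -> tuple[float, float]:
    """Confidence interval for the mean: mean +/- q * SD / sqrt(n).

    By default q is the normal quantile (1.959964 at 95%), the convention
    of the source tables; ``use_t=True`` switches to the Student-t quantile
    with n-1 degrees of freedom.
    """
    if use_t:
        q = float(stats.t.ppf(0.5 + level / 2.0, s.n - 1))
    else:
        q = float(stats.norm.ppf(0.5 + level / 2.0))
    half = q * s.sd / np.sqrt(s.n)
    return (s.mean - half, s.mean + half)


def osi(tas: float, tos: float) -> float:
    """Oxidative stress index: TOS (umol/L) / (TAS (mmol/L) * 10)."""
    if tas <= 0:
        raise ValueError("TAS must be positive")
    return tos / (tas * 10.0)


# ---------------------------------------------------------------------------
# packaged assay tables


def load_assay_table(name: str) -> list[AssaySummary]:
    """Load a packaged assay summary table as AssaySummary records.

    Known names: ``table2_antioxidant``, ``table3_anticholinesterase``,
    ``table4_phenolics``.  Any CSV path with columns
    ``parameter,group,mean,sd,n`` also works.
    """
    import pandas as pd

    from .design import _fixture_path

    path = _fixture_path(name) if not str(name).endswith(".csv") else name
    df = pd.read_csv(path)
    return [
        AssaySummary(
            label=str(r["parameter"]),
            mean=float(r["mean"]),
            sd=float(r["sd"]),
            n=int(r["n"]),
            group=str(r["group"]),
        )
        for _, r in df.iterrows()
    ]
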