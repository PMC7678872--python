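"""Statistical toolkit for per-cell secretion rates.

Implements, from their textbook sums-of-squares formulas, the tests used to
compare event rates between conditions: pooled-variance Student's t (with a
Welch variant), one-way fixed-effects ANOVA, one-way repeated-measures ANOVA
(cell as block, for sequential protocols where every cell sees every
condition), balanced two-way fixed-effects ANOVA with interaction, and the
Scheffé post-hoc means comparison.  The statistical unit throughout is the
cell, matching how such imaging experiments report n.

Scheffé's procedure declares a pairwise difference significant iff

    (m_i - m_j)^2 / (MS_within (1/n_i + 1/n_j)) > (k - 1) F_crit(alpha; k-1, df_within)

which is coherent with the omnibus F test: no pair can be significant when
the omnibus F is below its critical value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "GroupSample",
    "TestResult",
    "AnovaResult",
    "TwoWayAnovaResult",
    "students_t",
    "one_way_anova",
    "repeated_measures_anova",
    "two_way_anova",
    "scheffe_posthoc",
]


@dataclass(frozen=True)
class GroupSample:
    """A labelled sample of per-cell values (one group / condition)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64).ravel()
        if values.size < 1:
            raise ValueError("group sample must not be empty")
        if not np.all(np.isfinite(values)):
            raise ValueError("group sample contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple[float, ...]
    p_value: float
    labels: tuple[str, ...] = ()
    method: str = ""
    degenerate: bool = False
    significant: bool | None = None


@dataclass(frozen=True)
class AnovaResult:
    """Omnibus ANOVA result carrying the error term for post-hoc tests."""

    statistic: float
    df: tuple[float, float]
    p_value: float
    ms_error: float
    df_error: float
    method: str = ""
    degenerate: bool = False


@dataclass(frozen=True)
class TwoWayAnovaResult:
    factor_a: TestResult
    factor_b: TestResult
    interaction: TestResult
    ms_error: float
    df_error: float


def _f_sf(f: float, df1: float, df2: float) -> float:
    return float(_sps.f.sf(f, df1, df2))


def students_t(a: GroupSample, b: GroupSample, variant: str = "pooled") -> TestResult:
    """Two-sample two-tailed t test.

    ``pooled`` (default) is the classical Student's test with
    df = n_a + n_b - 2; ``welch`` does not assume equal variances.  With zero
    within-group variance the result is degenerate: p = 1 for equal means,
    p = 0 otherwise.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both samples need n >= 2")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    va = float(a.values.var(ddof=1))
    vb = float(b.values.var(ddof=1))
    diff = a.mean - b.mean

    if variant == "pooled":
        df = float(a.n + b.n - 2)
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / df
        if sp2 == 0.0:
            if diff == 0.0:
                return TestResult(0.0, (df,), 1.0, (a.label, b.label),
                                  "student_t_pooled", degenerate=True)
            return TestResult(math.copysign(math.inf, diff), (df,), 0.0,
                              (a.label, b.label), "student_t_pooled",
                              degenerate=True)
        t = diff / math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        method = "student_t_pooled"
    else:
        se2 = va / a.n + vb / b.n
        if se2 == 0.0:
            if diff == 0.0:
                return TestResult(0.0, (float(a.n + b.n - 2),), 1.0,
                                  (a.label, b.label), "welch_t", degenerate=True)
            return TestResult(math.copysign(math.inf, diff),
                              (float(a.n + b.n - 2),), 0.0,
                              (a.label, b.label), "welch_t", degenerate=True)
        df = se2 ** 2 / (
            (va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1)
        )
        t = diff / math.sqrt(se2)
        method = "welch_t"

    p = 2.0 * float(_sps.t.sf(abs(t), df))
    return TestResult(float(t), (float(df),), min(p, 1.0),
                      (a.label, b.label), method)


def one_way_anova(groups: Sequence[GroupSample]) -> AnovaResult:
    """Fixed-effects one-way ANOVA: F = MS_between / MS_within."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.label!r} needs n >= 2")
    all_values = np.concatenate([g.values for g in groups])
    grand = all_values.mean()
    n_total = all_values.size
    k = len(groups)

    ss_between = sum(g.n * (g.mean - grand) ** 2 for g in groups)
    ss_within = sum(float(((g.values - g.mean) ** 2).sum()) for g in groups)
    df1, df2 = float(k - 1), float(n_total - k)
    ms_within = ss_within / df2

    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, (df1, df2), 1.0, 0.0, df2,
                               "one_way_anova", degenerate=True)
        return AnovaResult(math.inf, (df1, df2), 0.0, 0.0, df2,
                           "one_way_anova", degenerate=True)
    f = (ss_between / df1) / ms_within
    return AnovaResult(float(f), (df1, df2), _f_sf(f, df1, df2),
                       float(ms_within), df2, "one_way_anova")


def repeated_measures_anova(
    data: np.ndarray, labels: Sequence[str] | None = None
) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions table.

    The subject (cell) effect is removed from the error term:
    SS_error = SS_total - SS_subjects - SS_conditions, with
    df_error = (k - 1)(n - 1).
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("data must be subjects x conditions")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite values")

    grand = data.mean()
    ss_total = float(((data - grand) ** 2).sum())
    ss_subjects = float(k * ((data.mean(axis=1) - grand) ** 2).sum())
    ss_cond = float(n * ((data.mean(axis=0) - grand) ** 2).sum())
    ss_error = ss_total - ss_subjects - ss_cond
    # numerical floor: the decomposition can leave a tiny negative residual
    ss_error = max(ss_error, 0.0)

    df1 = float(k - 1)
    df2 = float((k - 1) * (n - 1))
    ms_error = ss_error / df2
    if ms_error == 0.0:
        if ss_cond == 0.0:
            return AnovaResult(0.0, (df1, df2), 1.0, 0.0, df2,
                               "repeated_measures_anova", degenerate=True)
        return AnovaResult(math.inf, (df1, df2), 0.0, 0.0, df2,
                           "repeated_measures_anova", degenerate=True)
    f = (ss_cond / df1) / ms_error
    return AnovaResult(float(f), (df1, df2), _f_sf(f, df1, df2),
                       float(ms_error), df2, "repeated_measures_anova")


def two_way_anova(table: np.ndarray,
                  labels: tuple[str, str] = ("A", "B")) -> TwoWayAnovaResult:
    """Balanced fixed-effects two-way ANOVA with interaction.

    ``table`` has shape (levels_a, levels_b, replicates); requiring a full
    array enforces the balanced design (unbalanced data must be rejected
    upstream).
    """
    table = np.asarray(table, dtype=np.float64)
    if table.ndim != 3:
        raise ValueError(
            "table must be (levels_a, levels_b, replicates); unbalanced "
            "designs are not supported"
        )
    a, b, r = table.shape
    if a < 2 or b < 2:
        raise ValueError("both factors need at least 2 levels")
    if r < 2:
        raise ValueError("need at least 2 replicates per cell")
    if not np.all(np.isfinite(table)):
        raise ValueError("table contains non-finite values")

    grand = table.mean()
    mean_a = table.mean(axis=(1, 2))
    mean_b = table.mean(axis=(0, 2))
    mean_cell = table.mean(axis=2)

    ss_a = float(b * r * ((mean_a - grand) ** 2).sum())
    ss_b = float(a * r * ((mean_b - grand) ** 2).sum())
    ss_ab = float(
        r * ((mean_cell - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    )
    ss_e = float(((table - mean_cell[:, :, None]) ** 2).sum())

    df_a, df_b = float(a - 1), float(b - 1)
    df_ab = float((a - 1) * (b - 1))
    df_e = float(a * b * (r - 1))
    ms_e = ss_e / df_e

    def effect(ss: float, df: float, name: str) -> TestResult:
        if ms_e == 0.0:
            if ss == 0.0:
                return TestResult(0.0, (df, df_e), 1.0, (name,),
                                  "two_way_anova", degenerate=True)
            return TestResult(math.inf, (df, df_e), 0.0, (name,),
                              "two_way_anova", degenerate=True)
        f = (ss / df) / ms_e
        return TestResult(float(f), (df, df_e), _f_sf(f, df, df_e),
                          (name,), "two_way_anova")

    return TwoWayAnovaResult(
        factor_a=effect(ss_a, df_a, labels[0]),
        factor_b=effect(ss_b, df_b, labels[1]),
        interaction=effect(ss_ab, df_ab, f"{labels[0]}x{labels[1]}"),
        ms_error=float(ms_e),
        df_error=df_e,
    )


def scheffe_posthoc(
    groups: Sequence[GroupSample],
    ms_within: float,
    df_within: float,
    alpha: float = 0.05,
) -> list[TestResult]:
    """All pairwise Scheffé comparisons given an ANOVA error term.

    For each pair the statistic is
    ``(m_i - m_j)^2 / (MS_within (1/n_i + 1/n_j))``, significant iff it
    exceeds ``(k - 1) F_crit(alpha; k-1, df_within)``; the p-value is the
    upper F tail at ``statistic / (k - 1)``.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    if df_within <= 0:
        raise ValueError("df_within must be > 0")
    if ms_within < 0:
        raise ValueError("ms_within must be >= 0")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")

    df1 = float(k - 1)
    f_crit = float(_sps.f.ppf(1.0 - alpha, df1, df_within))
    results: list[TestResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            diff = gi.mean - gj.mean
            denom = ms_within * (1.0 / gi.n + 1.0 / gj.n)
            if denom == 0.0:
                stat = 0.0 if diff == 0.0 else math.inf
                p = 1.0 if diff == 0.0 else 0.0
                results.append(
                    TestResult(stat, (df1, float(df_within)), p,
                               (gi.label, gj.label), "scheffe",
                               degenerate=True, significant=diff != 0.0)
                )
                continue
            stat = diff ** 2 / denom
            p = _f_sf(stat / df1, df1, df_within)
            results.append(
                TestResult(float(stat), (df1, float(df_within)), p,
                           (gi.label, gj.label), "scheffe",
                           significant=bool(stat > df1 * f_crit))
            )
    return results
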