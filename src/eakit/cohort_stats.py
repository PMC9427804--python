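"""Validation statistics for aggregation-kinetics cohorts.

Covers the analyses used to validate the 5 s half-life as a measurement:
inter- and intra-individual coefficients of variation, normality testing
(Shapiro-Wilk), two-group comparison (two-tailed Student's t, pooled by
default, Welch available), Pearson correlation against hematocrit, and the
measurement-stability analysis (are readings taken an hour after blood
collection different from the first ones?).

All hypothesis tests delegate to scipy.stats; this module contributes the
domain conventions (pooled t as default, summary-statistic entry points so
published group tables can be re-analysed without raw data, CV defined
with the n-1 standard deviation) and uniform result containers.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike
from scipy import stats

__all__ = [
    "GroupSummary",
    "TestResult",
    "StabilityResult",
    "group_summary",
    "coefficient_of_variation",
    "cv_from_summary",
    "t_test_two_sample",
    "t_test_from_summary",
    "shapiro_wilk",
    "pearson_correlation",
    "stability_analysis",
    "cohort_report",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group descriptive row: n, mean +/- SD (s) and CV (%)."""

    n: int
    mean: float
    sd: float
    cv_pct: float
    label: str = ""

    def to_dict(self) -> dict:
        return {"label": self.label, "n": self.n, "mean_s": self.mean,
                "sd_s": self.sd, "cv_pct": self.cv_pct}


@dataclass(frozen=True)
class TestResult:
    """Uniform container for a hypothesis-test outcome."""

    statistic: float
    p_value: float
    method: str
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")

    def to_dict(self) -> dict:
        d = {"statistic": self.statistic, "p_value": self.p_value, "method": self.method}
        if self.df is not None:
            d["df"] = self.df
        return d


@dataclass(frozen=True)
class StabilityResult:
    """Outcome of the repeated-measurement stability analysis."""

    cv_pct: float
    first_vs_hour: TestResult
    n_first: int
    n_late: int

    def to_dict(self) -> dict:
        return {"cv_pct": self.cv_pct, "n_first": self.n_first, "n_late": self.n_late,
                "first_vs_hour": self.first_vs_hour.to_dict()}


def coefficient_of_variation(values: ArrayLike) -> float:
    """Interindividual CV in percent: 100 * sample SD (n-1) / sample mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for a CV")
    m = float(np.mean(x))
    if m <= 0:
        raise ValueError(f"CV undefined for non-positive mean ({m})")
    return 100.0 * float(np.std(x, ddof=1)) / m


def cv_from_summary(mean: float, sd: float) -> float:
    """CV in percent from published summary statistics: 100 * sd / mean."""
    if mean <= 0:
        raise ValueError(f"CV undefined for non-positive mean ({mean})")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return 100.0 * sd / mean


def group_summary(values: ArrayLike, label: str = "") -> GroupSummary:
    """Descriptive summary of one group's half-life values."""
    x = np.asarray(values, dtype=float)
    return GroupSummary(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        cv_pct=coefficient_of_variation(x) if x.size > 1 else 0.0,
        label=label,
    )


def t_test_two_sample(
    a: ArrayLike, b: ArrayLike, variant: str = "pooled"
) -> TestResult:
    """Two-tailed two-sample t-test.

    ``variant="pooled"`` is the classic Student test (equal variances
    assumed) and the default; ``"welch"`` drops that assumption.  When the
    two group SDs differ by more than a factor of two under the pooled
    variant, a warning suggests Welch — the pooled result is still
    returned, the choice stays explicit.
    """
    x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 and sy == 0:
        if np.mean(x) == np.mean(y):
            return TestResult(0.0, 1.0, "student-t-two-tailed",
                              df=float(x.size + y.size - 2))
        raise ValueError("zero variance in both groups with unequal means")
    if variant == "pooled":
        if min(x.size, y.size) >= 5 and min(sx, sy) > 0 and max(sx, sy) / min(sx, sy) > 2:
            warnings.warn(
                "group SDs differ by more than 2x; consider variant='welch'",
                stacklevel=2,
            )
        res = stats.ttest_ind(x, y, equal_var=True)
        return TestResult(float(res.statistic), float(res.pvalue),
                          "student-t-two-tailed", df=float(x.size + y.size - 2))
    res = stats.ttest_ind(x, y, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), "welch-t", df=float(res.df))


def t_test_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> TestResult:
    """Pooled two-tailed Student t-test from published group summaries.

    Lets a reported "n, mean +/- SD" table be tested without raw data;
    agrees exactly with :func:`t_test_two_sample` fed the same data's own
    summaries.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0 and mean1 != mean2):
        raise ValueError("invalid summary SDs")
    if sd1 == 0 and sd2 == 0:
        return TestResult(0.0, 1.0, "student-t-two-tailed", df=float(n1 + n2 - 2))
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "student-t-two-tailed", df=float(n1 + n2 - 2))


def shapiro_wilk(values: ArrayLike) -> TestResult:
    """Shapiro-Wilk normality test (W statistic, two-sided p)."""
    x = np.asarray(values, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant input")
    res = stats.shapiro(x)
    return TestResult(float(res.statistic), float(res.pvalue), "shapiro-wilk")


def pearson_correlation(x: ArrayLike, y: ArrayLike) -> TestResult:
    """Sample Pearson correlation with its two-sided p-value."""
    a, b = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if a.size != b.size:
        raise ValueError("x and y must have equal length")
    if a.size < 3:
        raise ValueError("need n >= 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.pearsonr(a, b)
    return TestResult(float(res.statistic), float(res.pvalue), "pearson",
                      df=float(a.size - 2))


def stability_analysis(
    measurements: pd.DataFrame,
    *,
    time_col: str = "minutes_after_draw",
    value_col: str = "eak5s",
    subject_col: str = "subject_id",
    first_window: float = 10.0,
    late_threshold: float = 60.0,
    paired: bool = False,
) -> StabilityResult:
    """Is the half-life stable over the hour after blood collection?

    Splits measurements into a "first" block (taken within ``first_window``
    minutes of the draw) and a "late" block (taken at or beyond
    ``late_threshold`` minutes) and compares them with a two-tailed t-test:
    unpaired pooled Student by default, or a paired test of per-subject
    block means when ``paired=True`` and a subject column is present.

    Also reports the repeat-measurement CV: the mean of per-subject CVs
    when several subjects are present, else the CV of all measurements.
    """
    df = measurements
    for col in (time_col, value_col):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    t = df[time_col].to_numpy(dtype=float)
    v = df[value_col].to_numpy(dtype=float)
    if len(df) < 2:
        raise ValueError("need at least 2 measurements")
    if np.max(t) < late_threshold:
        raise ValueError(
            f"insufficient time span: latest measurement at {np.max(t):.1f} min "
            f"< {late_threshold} min"
        )

    if subject_col in df.columns and df[subject_col].nunique() > 1:
        cvs = [
            coefficient_of_variation(g[value_col])
            for _, g in df.groupby(subject_col)
            if len(g) >= 2
        ]
        if not cvs:
            raise ValueError("no subject has repeated measurements")
        cv_pct = float(np.mean(cvs))
    else:
        cv_pct = coefficient_of_variation(v)

    first_mask = t <= first_window
    late_mask = t >= late_threshold
    first, late = v[first_mask], v[late_mask]
    if first.size == 0:
        raise ValueError(f"no measurements within the first {first_window} min")

    if paired and subject_col in df.columns:
        pairs = []
        for _, g in df.groupby(subject_col):
            gt = g[time_col].to_numpy(dtype=float)
            gv = g[value_col].to_numpy(dtype=float)
            f, l = gv[gt <= first_window], gv[gt >= late_threshold]
            if f.size and l.size:
                pairs.append((float(np.mean(f)), float(np.mean(l))))
        if len(pairs) < 2:
            raise ValueError("paired comparison needs >= 2 subjects with both blocks")
        fm, lm = np.array(pairs).T
        res = stats.ttest_rel(fm, lm)
        test = TestResult(float(res.statistic), float(res.pvalue),
                          "paired-t-two-tailed", df=float(len(pairs) - 1))
        return StabilityResult(cv_pct, test, n_first=len(pairs), n_late=len(pairs))

    test = t_test_two_sample(first, late, variant="pooled")
    return StabilityResult(cv_pct, test, n_first=int(first.size), n_late=int(late.size))


def cohort_report(
    table: pd.DataFrame,
    *,
    group_col: str = "group",
    value_col: str = "eak5s",
    reference: str | None = None,
) -> dict:
    """Group-table report: per-group n / mean +/- SD / CV, plus two-tailed
    Student t-tests of every group against a reference group.

    ``reference`` defaults to the first group in table order.  With a
    single group only the summary is produced.
    """
    for col in (group_col, value_col):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    groups = list(dict.fromkeys(table[group_col]))
    summaries = {
        g: group_summary(table.loc[table[group_col] == g, value_col], label=str(g))
        for g in groups
    }
    report: dict = {"groups": {str(g): s.to_dict() for g, s in summaries.items()}}
    if len(groups) > 1:
        ref = reference if reference is not None else groups[0]
        if ref not in groups:
            raise ValueError(f"reference group {ref!r} not in table")
        ref_vals = table.loc[table[group_col] == ref, value_col]
        tests = {}
        for g in groups:
            if g == ref:
                continue
            tests[str(g)] = t_test_two_sample(
                table.loc[table[group_col] == g, value_col], ref_vals
            ).to_dict()
        report["t_tests_vs_" + str(ref)] = tests
    return report
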