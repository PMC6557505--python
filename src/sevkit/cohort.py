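"""Cohort-level statistics for treatment comparison and observer grading.

The statistical layer mirrors a standard clinical comparison of two
topical treatments for radiation dermatitis: chi-square tests on
categorical patient characteristics and grade distributions, two-sample
t-tests on color summaries and ΔSEV, one-way ANOVA with Tukey–Kramer
post-hoc comparisons across CTCAE grades, and an inter-observer
comparison of grade distributions.

Defaults reproduce the conventions of mainstream clinical statistics
software: Pearson chi-square without continuity correction and pooled-
variance (Student) t-tests; Yates correction and Welch are available
behind flags.  Expected counts below 5 yield warnings, never silent
failures, since small strata are routine in cohorts of this size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .measurement import ColorSummary

__all__ = [
    "PatientRecord",
    "ContingencyTable",
    "TestResult",
    "PairwiseResult",
    "chi_square_test",
    "two_sample_t",
    "two_sample_t_from_samples",
    "anova_posthoc",
    "interobserver_comparison",
    "cohort_to_frame",
]

ARMS = ("Bepanthen", "R1R2")


@dataclass
class PatientRecord:
    """One patient's row: arm, Fitzpatrick type, per-area color summaries,
    ΔSEV and the observers' CTCAE grades (0–4)."""

    patient_id: str
    arm: str
    fitzpatrick: int | None = None
    control_summary: ColorSummary | None = None
    irradiated_summary: ColorSummary | None = None
    delta_sev: float | None = None
    grades: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.control_summary is None and self.irradiated_summary is None:
            raise ValueError("at least one area summary is required")
        for obs, g in self.grades.items():
            if not 0 <= int(g) <= 4:
                raise ValueError(f"grade {g} for observer {obs!r} outside CTCAE range 0–4")
        if self.fitzpatrick is not None and not 1 <= self.fitzpatrick <= 6:
            raise ValueError("Fitzpatrick type must be 1–6")


@dataclass
class ContingencyTable:
    """r×c table of nonnegative counts with row/column labels."""

    counts: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2×2")
        if np.any(self.counts < 0) or not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be nonnegative integers")
        self.counts = np.round(self.counts).astype(int)
        if self.row_labels is None:
            self.row_labels = [f"row{i}" for i in range(self.counts.shape[0])]
        if self.col_labels is None:
            self.col_labels = [f"col{j}" for j in range(self.counts.shape[1])]


@dataclass
class TestResult:
    """Statistic, degrees of freedom, p-value and (where applicable) the
    estimated effect with its 95% confidence interval."""

    statistic: float
    df: float
    p_value: float
    estimate: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.estimate is not None and self.ci_low is not None:
            if not (self.ci_low <= self.estimate <= self.ci_high):
                raise ValueError("estimate must lie inside its confidence interval")


@dataclass
class PairwiseResult:
    """One post-hoc pairwise comparison with Tukey-adjusted p."""

    group1: str
    group2: str
    estimate: float
    p_adjusted: float
    ci_low: float
    ci_high: float


def chi_square_test(table: ContingencyTable, correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a contingency table.

    No continuity correction by default (``correction=True`` applies
    Yates on 2×2 tables).  A warning is attached when any expected count
    falls below 5, the classical validity rule of thumb.
    """
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero row or column marginal")
    chi2, p, df, expected = stats.chi2_contingency(counts, correction=correction)
    warnings = []
    if expected.min() < 5:
        warnings.append(
            f"{int((expected < 5).sum())} expected cell count(s) below 5 "
            f"(minimum {expected.min():.2f}); chi-square approximation may be inaccurate"
        )
    return TestResult(statistic=float(chi2), df=float(df), p_value=float(p), warnings=warnings)


def _t_from_summaries(mean1, sd1, n1, mean2, sd2, n2, equal_var):
    diff = mean1 - mean2
    v1, v2 = sd1**2, sd2**2
    if equal_var:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        if se > 0:
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        else:
            df = n1 + n2 - 2
    return diff, se, df


def two_sample_t(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    equal_var: bool = True,
) -> TestResult:
    """Two-sided two-sample t-test from summary statistics.

    Pooled-variance Student's test by default (df = n1 + n2 − 2);
    ``equal_var=False`` switches to Welch.  Returns the mean difference
    with its 95% CI.  A degenerate zero-variance comparison with unequal
    means yields p = 0 with a warning rather than an exception.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be nonnegative")
    diff, se, df = _t_from_summaries(float(mean1), float(sd1), int(n1), float(mean2), float(sd2), int(n2), equal_var)
    warnings = []
    if se == 0:
        if diff == 0:
            t, p, half = 0.0, 1.0, 0.0
        else:
            t = np.inf if diff > 0 else -np.inf
            p, half = 0.0, 0.0
            warnings.append("zero pooled variance with unequal means; p set to 0")
    else:
        t = diff / se
        p = 2.0 * stats.t.sf(abs(t), df)
        half = stats.t.ppf(0.975, df) * se
    return TestResult(
        statistic=float(t),
        df=float(df),
        p_value=float(p),
        estimate=float(diff),
        ci_low=float(diff - half),
        ci_high=float(diff + half),
        warnings=warnings,
    )


def two_sample_t_from_samples(x, y, equal_var: bool = True) -> TestResult:
    """Overload of :func:`two_sample_t` taking the raw samples.

    Group SDs are the sample (n−1) values, matching the summary-statistic
    path exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return two_sample_t(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y), equal_var=equal_var
    )


def anova_posthoc(groups: dict[str, np.ndarray], alpha: float = 0.05, posthoc: bool = True):
    """One-way ANOVA plus Tukey–Kramer pairwise post-hoc comparisons.

    ``groups`` maps labels to raw samples (each n ≥ 2).  Returns
    ``(TestResult, list[PairwiseResult])``; the Tukey HSD studentized-
    range adjustment handles unequal group sizes (Tukey–Kramer).
    ``posthoc=False`` skips the pairwise stage (empty list) when only the
    omnibus F is wanted, e.g. in large simulation loops.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    warnings = []
    if any(s.std() == 0 for s in samples):
        warnings.append("at least one group has zero variance; F statistic may be unstable")
    k = len(samples)
    n_total = sum(len(s) for s in samples)
    if all(s.std() == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        anova = TestResult(0.0, float(k - 1), 1.0, warnings=warnings)
    else:
        f, p = stats.f_oneway(*samples)
        anova = TestResult(float(f), float(k - 1), float(min(max(p, 0.0), 1.0)), warnings=warnings)
    anova.warnings = warnings
    if not posthoc:
        return anova, []

    values = np.concatenate(samples)
    group_ids = np.concatenate([[lab] * len(s) for lab, s in zip(labels, samples)])
    tukey = pairwise_tukeyhsd(values, group_ids, alpha=alpha)
    order = [str(g) for g in tukey.groupsunique]
    from itertools import combinations

    pairwise = [
        PairwiseResult(
            group1=g1,
            group2=g2,
            estimate=float(tukey.meandiffs[i]),
            p_adjusted=float(tukey.pvalues[i]),
            ci_low=float(tukey.confint[i, 0]),
            ci_high=float(tukey.confint[i, 1]),
        )
        for i, (g1, g2) in enumerate(combinations(order, 2))
    ]
    return anova, pairwise


def interobserver_comparison(
    records: list[PatientRecord], obs1: str, obs2: str
) -> tuple[TestResult, pd.DataFrame]:
    """Compare two observers' CTCAE grade distributions.

    Builds the observer×grade table of marginal grade counts and tests it
    with the chi-square test; also returns the paired grade cross-tab
    (rows: obs1, columns: obs2) for inspection.  Every record must carry
    both observers' grades.
    """
    missing = [r.patient_id for r in records if obs1 not in r.grades or obs2 not in r.grades]
    if missing:
        raise ValueError(f"records missing grades for {obs1!r}/{obs2!r}: {missing}")
    g1 = np.array([r.grades[obs1] for r in records])
    g2 = np.array([r.grades[obs2] for r in records])
    levels = sorted(set(g1) | set(g2))
    counts = np.array([[int((g == lev).sum()) for lev in levels] for g in (g1, g2)])
    # drop grade levels nobody used on either margin (all-zero columns)
    keep = counts.sum(axis=0) > 0
    table = ContingencyTable(
        counts[:, keep],
        row_labels=[obs1, obs2],
        col_labels=[f"grade{lev}" for lev, k in zip(levels, keep) if k],
    )
    result = chi_square_test(table)
    crosstab = pd.crosstab(
        pd.Series(g1, name=obs1), pd.Series(g2, name=obs2), dropna=False
    )
    return result, crosstab


def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Flatten patient records to the cohort CSV schema."""
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "arm": r.arm, "fitzpatrick": r.fitzpatrick}
        for tag, s in (("ctrl", r.control_summary), ("irr", r.irradiated_summary)):
            if s is not None:
                row[f"mean_L_{tag}"] = s.mean_L
                row[f"mean_a_{tag}"] = s.mean_a
                row[f"mean_b_{tag}"] = s.mean_b
        row["delta_sev"] = r.delta_sev
        for i, obs in enumerate(sorted(r.grades), start=1):
            row[f"grade_obs{i}"] = r.grades[obs]
        rows.append(row)
    return pd.DataFrame(rows)
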