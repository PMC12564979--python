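"""Statistical analysis of heatmap entropy against response time.

The analysis mirrors a standard difficulty-stratified design: Pearson
correlation and simple OLS regression of response time (RT, seconds) on
heatmap entropy (HE, bits) over the full trial table and within each task
type, per-type descriptives (sample mean and SD, n-1 denominator), a
one-way ANOVA on 7-point Likert difficulty ratings across task types, and
Welch two-sample tests for gender differences in HE and RT. p-values are
two-tailed and uncorrected; alpha = 0.05 is only applied when rendering
reports. Gender tests pool trials within a type rather than averaging per
participant first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError, ValidationError

TASK_TYPES = (1, 2, 3)


@dataclass(frozen=True)
class RegressionFit:
    """Simple linear fit RT = intercept + slope * HE with its correlation.

    For simple regression ``r2`` equals ``r**2`` and the model p-value
    equals the correlation p-value; both identities are preserved here.
    """

    slope: float
    intercept: float
    r: float
    r2: float
    p: float
    n: int


@dataclass
class AnalysisResults:
    """Bundle of every analysis run on one trial table."""

    trials: pd.DataFrame
    overall: RegressionFit
    per_type: dict[int, RegressionFit]
    descriptives: pd.DataFrame
    anova: tuple[float, float] | None
    gender_tests: dict[tuple[str, str], tuple[float, float]]


def _check_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DomainError("x and y must have equal length")
    if x.size < 3:
        raise DomainError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for zero-variance input")
    return x, y


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-tailed p-value (t transform, n-2 df)."""
    x, y = _check_xy(x, y)
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def ols_fit(x, y) -> RegressionFit:
    """Least-squares simple regression of y on x."""
    x, y = _check_xy(x, y)
    res = sps.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r2=float(res.rvalue) ** 2,
        p=float(res.pvalue),
        n=int(x.size),
    )


def descriptives_by_type(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-type mean/SD of HE and RT plus counts.

    SD uses the n-1 denominator; a type with a single trial reports NaN SD.
    Types absent from the data are omitted.
    """
    rows = []
    for task_type, grp in trials.groupby("task_type", sort=True):
        rows.append(
            {
                "task_type": int(task_type),
                "n": len(grp),
                "he_mean": grp["he_bits"].mean(),
                "he_sd": grp["he_bits"].std(ddof=1),
                "rt_mean": grp["rt_s"].mean(),
                "rt_sd": grp["rt_s"].std(ddof=1),
            }
        )
    return pd.DataFrame(rows, columns=["task_type", "n", "he_mean", "he_sd", "rt_mean", "rt_sd"])


def oneway_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA over two or more groups."""
    if len(groups) < 2:
        raise DomainError("ANOVA requires at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise DomainError("each ANOVA group needs at least two values")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def two_sample_test(a, b) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t-test, two-tailed."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each sample needs at least two values")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def analyze_dataset(
    trials: pd.DataFrame, ratings: pd.DataFrame | None = None
) -> AnalysisResults:
    """Run the full analysis bundle on a trial table.

    Computes the overall HE-RT correlation and regression, the same per
    task type, per-type descriptives, the difficulty-rating ANOVA (when
    ratings are supplied) and per-type gender tests on HE and RT. All
    statistics are invariant to trial-row order.
    """
    if trials.empty:
        raise ValidationError("cannot analyze an empty trial table")
    required = {"task_type", "rt_s", "he_bits"}
    missing = required - set(trials.columns)
    if missing:
        raise ValidationError(f"trial table missing columns {sorted(missing)}")

    overall = ols_fit(trials["he_bits"], trials["rt_s"])

    per_type: dict[int, RegressionFit] = {}
    for task_type in TASK_TYPES:
        sub = trials[trials["task_type"] == task_type]
        if len(sub) >= 3:
            per_type[task_type] = ols_fit(sub["he_bits"], sub["rt_s"])

    anova = None
    if ratings is not None and not ratings.empty:
        groups = [
            ratings.loc[ratings["task_type"] == t, "rating"].to_numpy()
            for t in TASK_TYPES
            if (ratings["task_type"] == t).sum() >= 2
        ]
        if len(groups) >= 2:
            anova = oneway_anova(groups)

    gender_tests: dict[tuple[str, str], tuple[float, float]] = {}
    if "gender" in trials.columns and trials["gender"].nunique() == 2:
        g1, g2 = sorted(trials["gender"].unique())
        for task_type in TASK_TYPES:
            sub = trials[trials["task_type"] == task_type]
            a, b = sub[sub["gender"] == g1], sub[sub["gender"] == g2]
            if len(a) >= 2 and len(b) >= 2:
                for var in ("he_bits", "rt_s"):
                    gender_tests[(f"type{task_type}", var)] = two_sample_test(
                        a[var], b[var]
                    )

    return AnalysisResults(
        trials=trials,
        overall=overall,
        per_type=per_type,
        descriptives=descriptives_by_type(trials),
        anova=anova,
        gender_tests=gender_tests,
    )
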