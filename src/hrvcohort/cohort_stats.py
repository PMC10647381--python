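"""Cohort-level statistics: correlations, two-group tests, age binning and
linear age-dependency fits.

Conventions fixed here and used throughout the package:

* gender is coded numerically M=0, F=1, so a negative gender correlation
  means lower values in females;
* the t-test is Welch's (unequal variances); Mann-Whitney U uses the
  normal approximation with tie and continuity corrections; the
  two-sample KS test uses the asymptotic p-value;
* raw p-values are reported with n — no multiple-testing correction;
* cohort correlations are computed per subject (each subject contributes
  the mean of its window-level values per parameter), avoiding
  pseudo-replication from overlapping windows; per-window pooling is
  available through ``per_subject=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

GENDER_CODE = {"M": 0, "F": 1}

AGE_GROUPS = ("<30", "30-40", "40-50", "50-60", "60-70", ">70")


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # pearson / spearman / point_biserial
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class GroupTestResult:
    test: str  # welch_t / mann_whitney_u / ks
    statistic: float
    p: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class DependencyFit:
    """OLS fit y = intercept + slope*age of an HRV parameter on age."""

    intercept: float
    slope: float
    r: float
    p: float
    stderr: float
    n: int

    def predict(self, age: float) -> float:
        return self.intercept + self.slope * age


def _validate_xy(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    return x, y


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    x, y = _validate_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant variable")
    res = stats.pearsonr(x, y)
    return CorrelationResult("pearson", float(res.statistic), float(res.pvalue), x.size)


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    x, y = _validate_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant variable")
    res = stats.spearmanr(x, y)
    return CorrelationResult("spearman", float(res.statistic), float(res.pvalue), x.size)


def point_biserial(binary: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with a dichotomous (0/1-coded) variable."""
    b, y = _validate_xy(binary, y)
    if not set(np.unique(b)) <= {0.0, 1.0}:
        raise ValueError("binary variable must be coded 0/1")
    if len(np.unique(b)) < 2:
        raise ValueError("both groups must be non-empty")
    res = stats.pointbiserialr(b, y)
    return CorrelationResult(
        "point_biserial", float(res.statistic), float(res.pvalue), b.size
    )


def two_group_tests(
    a: Sequence[float], b: Sequence[float]
) -> list[GroupTestResult]:
    """Welch t, Mann-Whitney U and two-sample KS comparisons of two groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    t = stats.ttest_ind(a, b, equal_var=False)
    u = stats.mannwhitneyu(
        a, b, alternative="two-sided", use_continuity=True, method="asymptotic"
    )
    ks = stats.ks_2samp(a, b, method="asymp")
    return [
        GroupTestResult("welch_t", float(t.statistic), float(t.pvalue), a.size, b.size),
        GroupTestResult(
            "mann_whitney_u", float(u.statistic), float(u.pvalue), a.size, b.size
        ),
        GroupTestResult("ks", float(ks.statistic), float(ks.pvalue), a.size, b.size),
    ]


def fit_dependency(ages: Sequence[float], hrv: Sequence[float]) -> DependencyFit:
    """OLS age-dependency function y = intercept + slope*age."""
    x, y = _validate_xy(ages, hrv)
    if np.ptp(x) == 0:
        raise ValueError("ages must not be constant")
    res = stats.linregress(x, y)
    return DependencyFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r=float(res.rvalue),
        p=float(res.pvalue),
        stderr=float(res.stderr),
        n=x.size,
    )


def age_group(age: float) -> str:
    """Study age groups; half-open bins, 70 falls in '>70'."""
    if not 0 < age < 130:
        raise ValueError(f"age {age} outside (0, 130)")
    if age < 30:
        return "<30"
    if age < 40:
        return "30-40"
    if age < 50:
        return "40-50"
    if age < 60:
        return "50-60"
    if age < 70:
        return "60-70"
    return ">70"


_CORR_FUNCS = {"pearson": pearson, "spearman": spearman}


def correlation_matrix(
    cohort: pd.DataFrame,
    hrv_columns: Sequence[str],
    targets: Sequence[str] = ("age", "gender"),
    methods: Sequence[str] = ("pearson", "spearman"),
    group_by: str | None = None,
    min_n: int = 3,
) -> pd.DataFrame:
    """Correlation of each HRV column against age and gender, per group.

    ``cohort`` is a tidy per-subject table with columns ``age``, ``gender``
    (M/F) and the HRV parameters. Gender correlations use point-biserial
    (pearson on the 0/1 code) and Spearman on the same coding; rows with
    absent values are dropped per cell; undersized cells are emitted with a
    reason instead of a coefficient.
    """
    df = cohort.copy()
    df["_gender_code"] = df["gender"].map(GENDER_CODE)
    groups = [("all", df)] if group_by is None else list(df.groupby(group_by))
    rows = []
    for gname, gdf in groups:
        for col in hrv_columns:
            for target in targets:
                tcol = "_gender_code" if target == "gender" else target
                sub = gdf[[tcol, col]].dropna()
                for method in methods:
                    row = {
                        "group": gname,
                        "parameter": col,
                        "target": target,
                        "method": method,
                        "n": len(sub),
                        "r": np.nan,
                        "p": np.nan,
                        "reason": None,
                    }
                    if len(sub) < min_n:
                        row["reason"] = "insufficient n"
                    else:
                        try:
                            if target == "gender" and method == "pearson":
                                res = point_biserial(sub[tcol], sub[col])
                            else:
                                res = _CORR_FUNCS[method](sub[tcol], sub[col])
                            row["r"], row["p"] = res.r, res.p
                            row["method"] = res.method
                        except ValueError as exc:
                            row["reason"] = str(exc)
                    rows.append(row)
    return pd.DataFrame(rows)


def subject_mean_hrv(
    hrv_tables: dict[str, pd.DataFrame],
    method: str = "A",
    parameters: Sequence[str] = ("sdnn", "rmssd"),
) -> pd.DataFrame:
    """Per-subject mean of window-level HRV values for one method.

    ``hrv_tables`` maps subject_id to a ``windowed_hrv`` output table.
    Returns columns subject_id plus ``{method}_{PARAM}`` per parameter,
    e.g. ``A_SDNN``.
    """
    rows = []
    for sid, table in hrv_tables.items():
        sub = table[table["method"] == method]
        row: dict[str, object] = {"subject_id": sid}
        for p in parameters:
            vals = sub[p].dropna()
            row[f"{method}_{_param_name(p)}"] = (
                float(vals.mean()) if len(vals) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _param_name(p: str) -> str:
    return {"rmssd": "rMSSD"}.get(p, p.upper())
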