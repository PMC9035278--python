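"""Group-comparison statistics: OLS with an IQ covariate, per-strategy
regressions, group descriptives, Mann-Whitney U and one-way ANOVA.

Each behavioral metric is regressed on a diagnosis indicator plus IQ:

    metric_i = b0 + b1 * diagnosis_i + b2 * IQ_i + e_i

so the diagnosis coefficient is the adjusted group difference on the metric's
natural scale (IQ enters raw, not standardized).  The overall F tests the two
predictors jointly with df = (2, n - 3).  The diagnosis indicator defaults to
autism = 1 / control = 0 and is exposed as a flag because the coefficient's
sign flips with the coding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .metrics import METRIC_COLUMNS, STRATEGY_PREFIX
from .pd_engine import STRATEGIES

__all__ = [
    "RegressionResult",
    "Descriptives",
    "fit_ols",
    "diagnosis_regression",
    "per_strategy_regressions",
    "group_descriptives",
    "mann_whitney",
    "one_way_anova",
    "DIAGNOSIS_CODINGS",
]

#: diagnosis indicator codings: group label -> 0/1
DIAGNOSIS_CODINGS = {
    "autism1": {"autism": 1.0, "control": 0.0},
    "control1": {"autism": 0.0, "control": 1.0},
}


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of one metric on [intercept, diagnosis, IQ] (or a generic X)."""

    terms: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    F: float
    F_pvalue: float
    df: tuple[int, int]
    r_squared: float
    n: int

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.standard_errors[self.terms.index(term)])

    def p(self, term: str) -> float:
        return float(self.p_values[self.terms.index(term)])

    def tidy(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.coefficients,
                "se": self.standard_errors,
                "t": self.t_values,
                "p": self.p_values,
            }
        )


@dataclass(frozen=True)
class Descriptives:
    """Mean / median / quartiles of one metric in one group."""

    mean: float
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles must be ordered q1 <= median <= q3")


def fit_ols(
    y: Sequence[float],
    X: np.ndarray,
    terms: Optional[Sequence[str]] = None,
) -> RegressionResult:
    """Ordinary least squares with the usual unbiased-variance inference.

    ``X`` must already contain the intercept column.  The overall F tests all
    non-intercept terms jointly.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D design matrix")
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than columns ({k})")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    if terms is None:
        terms = ["intercept"] + [f"x{i}" for i in range(1, k)]
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        terms=tuple(terms),
        coefficients=np.asarray(fit.params, dtype=float),
        standard_errors=np.asarray(fit.bse, dtype=float),
        t_values=np.asarray(fit.tvalues, dtype=float),
        p_values=np.asarray(fit.pvalues, dtype=float),
        F=float(fit.fvalue),
        F_pvalue=float(fit.f_pvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        r_squared=float(fit.rsquared),
        n=n,
    )


def _diagnosis_design(
    data: pd.DataFrame, metric: str, coding: str
) -> tuple[np.ndarray, np.ndarray]:
    if coding not in DIAGNOSIS_CODINGS:
        raise ValueError(f"unknown diagnosis coding {coding!r}")
    code = DIAGNOSIS_CODINGS[coding]
    unknown = set(data["group"]) - set(code)
    if unknown:
        raise ValueError(f"unknown group labels {sorted(unknown)}")
    if data["iq"].isna().any():
        raise ValueError("missing IQ values")
    sub = data.dropna(subset=[metric])
    y = sub[metric].to_numpy(dtype=float)
    if np.allclose(y, y[0] if len(y) else 0.0):
        raise ValueError(f"metric {metric!r} is constant")
    diag = sub["group"].map(code).to_numpy(dtype=float)
    iq = sub["iq"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sub)), diag, iq])
    return y, X


def diagnosis_regression(
    data: pd.DataFrame,
    metric: str,
    coding: str = "autism1",
    drop_excluded: bool = True,
) -> RegressionResult:
    """Regress one participant-level metric on diagnosis + IQ.

    ``data`` is a summaries frame (one row per participant with ``group``,
    ``iq`` and metric columns).  Participants flagged by the task exclusion
    rule are dropped when ``drop_excluded``; rows with a NaN metric (e.g. an
    undefined failed ratio) are always dropped.
    """
    if metric not in data.columns:
        raise ValueError(f"no metric column {metric!r}")
    if drop_excluded and "excluded" in data.columns:
        data = data.loc[~data["excluded"].astype(bool)]
    y, X = _diagnosis_design(data, metric, coding)
    return fit_ols(y, X, terms=("intercept", "diagnosis", "iq"))


def per_strategy_regressions(
    data: pd.DataFrame, coding: str = "autism1"
) -> pd.DataFrame:
    """Diagnosis + IQ regression for each (strategy, metric) pair.

    Five metrics per strategy, mirroring the per-opponent exploratory table:
    correct predictions, declared inability, failed/attempted ratio, total
    score and cooperation count.
    """
    per_strategy_metrics = {
        "correct_predictions": "correct_predictions",
        "declared_inability": "declared_inability",
        "failed_ratio": "failed_ratio",
        "total_score": "total_score",
        "cooperation_count": "cooperation_count",
    }
    rows = []
    for strat in STRATEGIES:
        pre = STRATEGY_PREFIX[strat]
        for metric, col_suffix in per_strategy_metrics.items():
            col = f"{pre}_{col_suffix}"
            res = diagnosis_regression(data, col, coding=coding)
            rows.append(
                {
                    "strategy": strat.value,
                    "metric": metric,
                    "diagnosis_beta": res.coef("diagnosis"),
                    "diagnosis_se": res.se("diagnosis"),
                    "diagnosis_p": res.p("diagnosis"),
                    "F": res.F,
                    "df1": res.df[0],
                    "df2": res.df[1],
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)


def group_descriptives(
    data: pd.DataFrame,
    metrics: Sequence[str] = ("correct_predictions", "declared_inability", "failed_ratio"),
) -> pd.DataFrame:
    """Mean, median and quartiles per group per metric.

    Quartiles use linear interpolation between order statistics (the common
    spreadsheet/statistics convention), so interquartile ranges are
    reproducible.
    """
    rows = []
    for group, sub in data.groupby("group", sort=True):
        for metric in metrics:
            vals = sub[metric].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                raise ValueError(f"no data for {metric!r} in group {group!r}")
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {
                    "group": group,
                    "metric": metric,
                    "n": len(vals),
                    "mean": float(np.mean(vals)),
                    "median": float(med),
                    "q1": float(q1),
                    "q3": float(q3),
                }
            )
    return pd.DataFrame(rows)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U for sample ``a`` vs ``b``.

    U is the number of (a, b) pairs where a wins (ties count half).  The
    p-value is exact for min(n) <= 8 without ties, otherwise a normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def one_way_anova(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """One-way ANOVA for two groups; for two groups F equals the squared
    equal-variance two-sample t statistic."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples must have size >= 2")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        raise ValueError("zero within-group variance")
    res = scipy.stats.f_oneway(a, b)
    return float(res.statistic), float(res.pvalue)
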