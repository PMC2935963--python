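"""Cohort comparison statistics: sympercent differences and agreement fits.

Group differences are expressed as *sympercents*: outcomes are transformed
to natural logarithms and regressed on a 0/1 group indicator (plus optional
covariates); 100 times the group coefficient is the symmetric percentage
difference between the groups. Sympercents are additive, symmetric in the
group ordering up to sign, and invariant to the measurement units of the
outcome.

Agreement between two measurement methods (e.g. shape-sensitive vs
manufacturer's software) is summarized by Pearson's r and an ordinary
least-squares y-on-x line with standard errors.

All model fitting is ordinary least squares via statsmodels; no
multiple-testing correction is applied, and significance is flagged with
stars at 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

SIGNIFICANCE_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class SympercentResult:
    """A covariate-adjusted sympercent group difference."""

    estimate: float  # sympercent, %
    standard_error: float  # %
    p_value: float
    covariates_used: tuple[str, ...]

    def __post_init__(self):
        if not self.standard_error > 0:
            raise ValueError("standard error must be positive")
        if not (0 < self.p_value <= 1):
            raise ValueError("p value must lie in (0, 1]")

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass
class AgreementResult:
    """OLS y-on-x agreement summary between two methods."""

    r: float
    intercept: float
    intercept_se: float
    slope: float
    slope_se: float
    p_value: float


def significance_stars(p: float) -> str:
    for level, stars in SIGNIFICANCE_LEVELS:
        if p < level:
            return stars
    return ""


def _validate_table(table: pd.DataFrame, outcome: str, group: str, covariates):
    cols = [group, outcome, *covariates]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing column(s): {', '.join(missing)}")
    sub = table[cols]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise ValueError(f"missing values in fitted columns at rows {bad}")
    groups = set(np.unique(sub[group]))
    if groups != {0, 1}:
        raise ValueError(
            f"group column must contain both labels 0 and 1, found {sorted(groups)}"
        )
    nonpos = sub.index[sub[outcome] <= 0].tolist()
    if nonpos:
        raise ValueError(
            f"outcome '{outcome}' must be strictly positive for the log "
            f"transform; offending rows: {nonpos}"
        )
    return sub


def sympercent_difference(
    table: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = (),
    group: str = "group",
) -> SympercentResult:
    """Sympercent difference of `outcome` between group 1 and group 0.

    OLS of ln(outcome) on the group indicator plus covariates; the estimate
    is 100 x the group coefficient, with its (x100) standard error and the
    two-sided p value from the coefficient's t statistic.
    """
    sub = _validate_table(table, outcome, group, covariates)
    X = sm.add_constant(sub[[group, *covariates]].astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear covariates)")
    fit = sm.OLS(np.log(sub[outcome].astype(float)), X).fit()
    return SympercentResult(
        estimate=100.0 * float(fit.params[group]),
        standard_error=100.0 * float(fit.bse[group]),
        p_value=float(fit.pvalues[group]),
        covariates_used=tuple(covariates),
    )


def agreement_regression(x, y) -> AgreementResult:
    """Pearson r and OLS y-on-x line between two measurement methods."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression is undefined")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    r = float(np.corrcoef(x, y)[0, 1]) if np.ptp(y) > 0 else 1.0
    return AgreementResult(
        r=r,
        intercept=float(fit.params[0]),
        intercept_se=float(fit.bse[0]),
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
    )


def _median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    """Median and interquartile bounds, lower-interpolation convention."""
    med = float(np.percentile(values, 50, method="lower"))
    q1 = float(np.percentile(values, 25, method="lower"))
    q3 = float(np.percentile(values, 75, method="lower"))
    return med, q1, q3


def compare_cohorts(
    table: pd.DataFrame,
    outcomes: list[str],
    covariates: tuple[str, ...] = ("age", "height", "weight"),
    adjust: bool = True,
    group: str = "group",
) -> pd.DataFrame:
    """Per-outcome cohort comparison report.

    One row per outcome: group medians and interquartile ranges, the
    unadjusted sympercent difference with significance stars, and (when
    ``adjust``) the covariate-adjusted sympercent.
    """
    rows = []
    for outcome in outcomes:
        un = sympercent_difference(table, outcome, (), group=group)
        g0 = table.loc[table[group] == 0, outcome].to_numpy(dtype=float)
        g1 = table.loc[table[group] == 1, outcome].to_numpy(dtype=float)
        m0, lo0, hi0 = _median_iqr(g0)
        m1, lo1, hi1 = _median_iqr(g1)
        row = {
            "outcome": outcome,
            "median_group0": m0,
            "iqr_group0": f"{lo0:g}-{hi0:g}",
            "median_group1": m1,
            "iqr_group1": f"{lo1:g}-{hi1:g}",
            "pct_diff": un.estimate,
            "pct_diff_se": un.standard_error,
            "pct_diff_stars": un.stars,
        }
        if adjust:
            adj = sympercent_difference(table, outcome, covariates, group=group)
            row.update(
                pct_diff_adj=adj.estimate,
                pct_diff_adj_se=adj.standard_error,
                pct_diff_adj_stars=adj.stars,
            )
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "SympercentResult",
    "AgreementResult",
    "sympercent_difference",
    "agreement_regression",
    "compare_cohorts",
    "significance_stars",
]
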