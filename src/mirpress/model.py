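"""Expression-repression modeling and Ago-1 occupancy analysis.

The central model is ordinary least squares of percent repression on
log10(RPM + pseudocount): its slope is the increase in repression per
10-fold increase in miRNA abundance.  Companions: Pearson correlation on the
raw (linear) RPM scale, refits excluding named miRNAs, predicted change in
repression for a given expression fold change, expression-corrected
repression (repression / log10 RPM), and the cell-vs-Ago-1 occupancy
correlations computed on log10 RPM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: RPM added before log10; the assayed panels contain no zeros but general
#: inputs may
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class FitResult:
    """OLS fit of repression (%) on log10(RPM + pseudocount)."""

    slope: float  # % repression per decade of expression
    intercept: float
    ci_lo: float  # 95% CI bounds on the slope
    ci_hi: float
    pearson_r: float  # r of log10 RPM vs repression
    n: int


def _align(x, y) -> tuple[pd.Series, pd.Series]:
    xs = pd.Series(x, dtype=float) if not isinstance(x, pd.Series) else x.astype(float)
    ys = pd.Series(y, dtype=float) if not isinstance(y, pd.Series) else y.astype(float)
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        common = xs.index.intersection(ys.index)
        xs, ys = xs.loc[common], ys.loc[common]
    elif len(xs) != len(ys):
        raise ValueError("expression and repression have different lengths")
    mask = xs.notna() & ys.notna()
    return xs[mask], ys[mask]


def fit_loglinear(
    expr_rpm,
    repression_pct,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FitResult:
    """Fit repression on log10 expression with a t-based 95% CI on the slope.

    Pearson r is computed on the same (log10 RPM, repression) pairs; when
    repression is constant r is reported as 0.
    """
    xs, ys = _align(expr_rpm, repression_pct)
    if len(xs) < 3:
        raise ValueError("need at least 3 paired observations")
    if (xs < 0).any():
        raise ValueError("negative RPM")
    logx = np.log10(xs.to_numpy() + pseudocount)
    y = ys.to_numpy()
    if np.ptp(logx) == 0:
        raise ValueError("zero variance in log expression")
    ols = sm.OLS(y, sm.add_constant(logx)).fit()
    lo, hi = ols.conf_int(alpha=0.05)[1]
    if np.ptp(y) == 0:
        r = 0.0
    else:
        r = float(stats.pearsonr(logx, y).statistic)
    return FitResult(
        slope=float(ols.params[1]),
        intercept=float(ols.params[0]),
        ci_lo=float(lo),
        ci_hi=float(hi),
        pearson_r=r,
        n=len(xs),
    )


def pearson_linear(expr_rpm, repression_pct) -> float:
    """Pearson r of repression against untransformed RPM."""
    xs, ys = _align(expr_rpm, repression_pct)
    if len(xs) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(xs.to_numpy()) == 0 or np.ptp(ys.to_numpy()) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(xs, ys).statistic)


def refit_excluding(
    expr_rpm: pd.Series,
    repression_pct: pd.Series,
    exclude: Iterable[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FitResult:
    """Repeat the log-linear fit with the named miRNAs removed."""
    exclude = set(exclude)
    keep = [i for i in expr_rpm.index if i not in exclude]
    if len(keep) < 3:
        raise ValueError("fewer than 3 observations remain after exclusion")
    return fit_loglinear(expr_rpm.loc[keep], repression_pct.loc[keep], pseudocount)


def predict_delta_repression(fit: FitResult | float, fold_change: float) -> float:
    """Change in repression (%) implied by an expression fold change."""
    if fold_change <= 0:
        raise ValueError("fold change must be positive")
    slope = fit.slope if isinstance(fit, FitResult) else float(fit)
    return slope * np.log10(fold_change)


def expression_corrected_repression(
    repression_pct: pd.Series,
    expr_rpm: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Repression divided by log10(RPM + pseudocount), the per-decade activity.

    Where the denominator is not strictly positive (RPM + pseudocount <= 1)
    the ratio is undefined and returned as NaN, to be excluded from
    downstream correlations.
    """
    xs, ys = _align(expr_rpm, repression_pct)
    denom = np.log10(xs + pseudocount)
    out = ys / denom.where(denom > 0)
    out.name = "expression_corrected_repression"
    return out


@dataclass
class OccupancyResult:
    records: pd.DataFrame  # mirna, cell_rpm, ago_rpm, occupancy_ratio
    r_cell_ago: float  # Pearson r of log10 cell vs log10 Ago RPM
    r_ago_repression: float | None  # Pearson r of log10 Ago RPM vs repression


def occupancy_analysis(
    cell_rpm: pd.Series,
    ago_rpm: pd.Series,
    repression_pct: pd.Series | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> OccupancyResult:
    """Relate cellular and Ago-1-associated miRNA levels.

    Both profiles must be normalized in the same mode.  The occupancy ratio
    ago/cell is defined only where the cellular RPM is positive.
    Correlations are computed on log10(RPM + pseudocount).
    """
    common = cell_rpm.index.intersection(ago_rpm.index)
    if len(common) == 0:
        raise ValueError("no shared miRNA names between profiles")
    cell = cell_rpm.loc[common].astype(float)
    ago = ago_rpm.loc[common].astype(float)
    ratio = (ago / cell.where(cell > 0)).rename("occupancy_ratio")
    records = pd.DataFrame(
        {"cell_rpm": cell, "ago_rpm": ago, "occupancy_ratio": ratio}
    )
    records.index.name = "mirna"
    log_cell = np.log10(cell + pseudocount)
    log_ago = np.log10(ago + pseudocount)
    r_ca = float(stats.pearsonr(log_cell, log_ago).statistic)
    r_ar = None
    if repression_pct is not None:
        shared = common.intersection(repression_pct.index)
        if len(shared) < 3:
            raise ValueError("fewer than 3 miRNAs shared with repression data")
        r_ar = float(
            stats.pearsonr(
                np.log10(ago.loc[shared] + pseudocount), repression_pct.loc[shared]
            ).statistic
        )
    return OccupancyResult(records=records, r_cell_ago=r_ca, r_ago_repression=r_ar)


def fit_to_frame(fits: Mapping[str, FitResult]) -> pd.DataFrame:
    rows = {
        label: {
            "slope": f.slope,
            "intercept": f.intercept,
            "ci_lo": f.ci_lo,
            "ci_hi": f.ci_hi,
            "pearson_r": f.pearson_r,
            "n": f.n,
        }
        for label, f in fits.items()
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "fit"
    return out
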