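"""OLS linear trend on annual diagnosed-diabetes counts, with projections.

The diagnosed-prevalence series (QOF register counts, millions) is close
to perfectly linear; an ordinary least-squares fit of count on calendar
year summarises it, and the fitted line is extrapolated to future years
with a 95% confidence interval for the *mean response* (the expected
value of the line, not a prediction interval for a new annual count —
the stability of the series makes the mean-response band the quantity
of interest).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class AnnualSeries:
    """Annual diagnosed counts; fiscal years keyed by starting calendar year."""

    years: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.years) != len(self.values):
            raise ValueError("years and values must have equal length")
        ys = np.asarray(self.years)
        if len(ys) >= 2 and not np.all(np.diff(ys) > 0):
            raise ValueError("years must be strictly increasing")
        if np.any(np.asarray(self.values, dtype=float) < 0):
            raise ValueError("counts must be >= 0")

    def __len__(self) -> int:
        return len(self.years)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fiscal_year_start": self.years, "diagnosed_millions": self.values}
        )


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of diagnosed counts on calendar year, with the sufficient
    statistics needed for mean-response intervals at new years."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    t_intercept: float
    t_slope: float
    p_intercept: float
    p_slope: float
    df: int
    adj_r2: float
    ci_intercept: tuple[float, float]
    ci_slope: tuple[float, float]
    n: int
    x_mean: float
    sxx: float
    resid_sd: float

    def predict(self, year) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(year, dtype=float)


def fit_linear_trend(series: AnnualSeries) -> TrendFit:
    """Least-squares trend of counts on raw (uncentred) calendar years."""
    if len(series) < 3:
        raise ValueError(f"need at least 3 points to fit a trend, got {len(series)}")
    x = np.asarray(series.years, dtype=float)
    y = np.asarray(series.values, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("years have zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    n = len(series)
    df = n - 2
    # residual SD from the fit; guard the noiseless case where ssr ~ 0
    resid_sd = float(np.sqrt(max(res.ssr, 0.0) / df))
    return TrendFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        se_intercept=float(res.bse[0]),
        se_slope=float(res.bse[1]),
        t_intercept=float(res.tvalues[0]),
        t_slope=float(res.tvalues[1]),
        p_intercept=float(res.pvalues[0]),
        p_slope=float(res.pvalues[1]),
        df=df,
        adj_r2=float(res.rsquared_adj),
        ci_intercept=(float(ci[0][0]), float(ci[0][1])),
        ci_slope=(float(ci[1][0]), float(ci[1][1])),
        n=n,
        x_mean=float(x.mean()),
        sxx=float(np.sum((x - x.mean()) ** 2)),
        resid_sd=resid_sd,
    )


def project_with_interval(
    fit: TrendFit, target_years, level: float = 0.95
) -> pd.DataFrame:
    """Point projections with mean-response confidence intervals.

    The half-width at year x is t(df, 1-a/2) * s * sqrt(1/n + (x-xbar)^2/Sxx),
    growing with distance from the centre of the observed years.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level!r}")
    years = np.asarray(list(target_years), dtype=float)
    point = fit.predict(years)
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, fit.df))
    half = (
        tcrit
        * fit.resid_sd
        * np.sqrt(1.0 / fit.n + (years - fit.x_mean) ** 2 / fit.sxx)
    )
    return pd.DataFrame(
        {"year": years, "point": point, "lo": point - half, "hi": point + half}
    )
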