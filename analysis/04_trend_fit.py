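#!/usr/bin/env python
"""Fit the diagnosed-diabetes trend and project it to 2035.

OLS of diagnosed counts (millions) on calendar year, then point
projections with 95% mean-response intervals, converted to the true scale
(x 4/3 for the 75% diagnosed share) and to T2D (x 0.9).  Writes
results/trend/.
"""

from pathlib import Path

from t2dproj import io as tio
from t2dproj.comparison import DEFAULT_RATIOS, diagnosed_to_true, diabetes_to_t2d
from t2dproj.trend import fit_linear_trend, project_with_interval

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "trend"


def main() -> None:
    series = tio.read_series_csv(ROOT / "results" / "inputs" / "qof_series.csv")
    fit = fit_linear_trend(series)
    print(f"diagnosed trend: slope {fit.slope:.3f} M/year (SE {fit.se_slope:.3f}), "
          f"intercept {fit.intercept:.0f}, adjusted R2 {fit.adj_r2:.3f}")

    proj = project_with_interval(fit, range(2015, 2036), level=0.95)
    r = DEFAULT_RATIOS
    for col in ("point", "lo", "hi"):
        proj[f"diabetes_true_{col}"] = diagnosed_to_true(proj[col].to_numpy(), r)
        proj[f"t2d_true_{col}"] = diabetes_to_t2d(proj[f"diabetes_true_{col}"], r)

    OUT.mkdir(parents=True, exist_ok=True)
    proj.to_csv(OUT / "trend_projections.csv", index=False, float_format="%.6g")
    at2025 = proj[proj.year == 2025].iloc[0]
    print(f"2025 true diabetes: {at2025.diabetes_true_point:.2f} "
          f"({at2025.diabetes_true_lo:.2f}-{at2025.diabetes_true_hi:.2f}) million")
    print(f"2025 true T2D:      {at2025.t2d_true_point:.2f} "
          f"({at2025.t2d_true_lo:.2f}-{at2025.t2d_true_hi:.2f}) million")
    print(f"wrote {OUT / 'trend_projections.csv'}")


if __name__ == "__main__":
    main()
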