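"""End-to-end driver: baseline -> matrices -> projections -> trend -> table.

``run_pipeline`` wires the modules together from a validated config:
builds the 2015 baseline, assembles and runs the three Markov models
(plus their IH=0 sensitivity variants), fits the diagnosed-count trend
(from a series CSV, or the synthetic generator when none is given),
applies the scale conversions and assembles the comparison table.  Every
parameter and seed is logged and recorded in a run manifest.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

from . import comparison as cmp
from . import io as tio
from . import markov, synthetic
from .calibrate import calibrate_transition
from .models import BaselineEstimate, baseline_state, make_model
from .trend import fit_linear_trend, project_with_interval

log = logging.getLogger("t2dproj")

DEFAULT_COMPARE_YEARS = [2015, 2020, 2025, 2030, 2035]


def _baseline_from_config(mk: dict[str, Any]) -> BaselineEstimate:
    return BaselineEstimate(
        diabetes_total=mk.get("diabetes_total", 3.81),
        ih_total=mk.get("ih_total", 5.05),
        adult_population=mk["adult_population"],
        year=mk.get("baseline_year", 2015),
        t2d_share=mk.get("t2d_share", 0.90),
    )


def run_pipeline(cfg: dict[str, Any], out_dir) -> "cmp.pd.DataFrame":
    """Run the full comparison pipeline; returns the comparison table.

    Writes per-model state trajectories and matrices, the trend fit and
    projections, the comparison CSV and a run manifest under ``out_dir``.
    """
    cfg = tio.validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    seeds = {"top_level": seed, "synth_qof": seed}

    mk = cfg.get("markov", {})
    baseline = _baseline_from_config(mk)
    log.info("baseline: %s", baseline)
    horizon = mk.get("horizon", 2035)
    ng_inflow = mk.get("ng_inflow", 0.0)
    model_names = mk.get("models", ["model1", "model2", "model3"])

    sources: list[cmp.SourceProjection] = []
    compare_cfg = cfg.get("compare", {})
    years = list(compare_cfg.get("years", DEFAULT_COMPARE_YEARS))

    if compare_cfg.get("include_published", True):
        sources.append(cmp.PUBLISHED_SOURCES["PHE"])

    # ------------------------------------------------------------- trend fit
    trend_cfg = cfg.get("trend", {})
    synth_cfg = cfg.get("synth", {})
    if "series_csv" in trend_cfg:
        series = tio.read_series_csv(trend_cfg["series_csv"])
        log.info("diagnosed series read from %s (%d years)", trend_cfg["series_csv"], len(series))
    else:
        series = synthetic.gen_qof_series(
            intercept=synth_cfg.get("intercept", synthetic.QOF_INTERCEPT),
            slope=synth_cfg.get("slope", synthetic.QOF_SLOPE),
            noise_sd=synth_cfg.get("noise_sd", synthetic.QOF_NOISE_SD),
            years=range(
                synth_cfg.get("year_start", 2004), synth_cfg.get("year_end", 2017) + 1
            ),
            seed=seeds["synth_qof"],
        )
        log.info("synthetic diagnosed series generated (seed %d)", seeds["synth_qof"])
        tio.write_series_csv(series, out / "qof_series.csv")
    fit = fit_linear_trend(series)
    log.info("trend fit: slope %.4f (SE %.4f), adj R2 %.4f", fit.slope, fit.se_slope, fit.adj_r2)
    proj_years = trend_cfg.get("project_years", list(range(2015, horizon + 1)))
    level = trend_cfg.get("level", 0.95)
    trend_proj = project_with_interval(fit, proj_years, level=level)
    ratios = cmp.DEFAULT_RATIOS
    # diagnosed -> true conversion applied to points and interval endpoints
    for col in ("point", "lo", "hi"):
        trend_proj[col] = cmp.diagnosed_to_true(trend_proj[col].to_numpy(), ratios)
    trend_proj.to_csv(out / "trend_projections.csv", index=False)
    sources.append(
        cmp.SourceProjection(
            label="QOF-trend",
            scale="diabetes",
            values={int(r.year): float(r.point) for r in trend_proj.itertuples()},
            ci={int(r.year): (float(r.lo), float(r.hi)) for r in trend_proj.itertuples()},
            series_first=(series.years[0], cmp.diagnosed_to_true(series.values[0], ratios)),
            series_last=(series.years[-1], cmp.diagnosed_to_true(series.values[-1], ratios)),
        )
    )

    # ------------------------------------------------------- markov projections
    start = baseline_state(baseline)
    for name in model_names:
        spec = make_model(name)
        m = markov.build_matrix(spec)
        tio.write_matrix_csv(m, out / f"matrix_{name}.csv")
        traj = markov.project(start, m, horizon, ng_inflow=ng_inflow)
        tio.write_states_csv(traj, out / f"states_{name}.csv")
        sources.append(
            cmp.SourceProjection(
                label=name,
                scale="t2d",
                values={y: traj.t2d(y) for y in years if y <= horizon},
            )
        )
        log.info("%s: T2D 2025 = %.3f M", name, traj.t2d(2025))

    if mk.get("ih_zero_variants", True):
        b0 = BaselineEstimate(
            diabetes_total=baseline.diabetes_total,
            ih_total=0.0,
            adult_population=baseline.adult_population,
            year=baseline.year,
            t2d_share=baseline.t2d_share,
        )
        start0 = baseline_state(b0)
        for name in model_names:
            if name == "model2":
                continue  # the calibrated model is defined for the IH=5.05 baseline
            traj = markov.project(start0, markov.build_matrix(make_model(name)), horizon)
            tio.write_states_csv(traj, out / f"states_{name}_ih0.csv")
            sources.append(
                cmp.SourceProjection(
                    label=f"{name}-IH0",
                    scale="t2d",
                    values={y: traj.t2d(y) for y in years if y <= horizon},
                )
            )

    table = cmp.build_comparison_table(sources, ratios, years=None)
    table = table[table["year"].isin(years)].reset_index(drop=True)
    tio.write_comparison_csv(table, out / "comparison.csv")
    if compare_cfg.get("plot", False):
        cmp.plot_projections(table, str(out / "projections_t2d.png"))
    tio.write_manifest(out / "manifest.json", cfg, seeds)
    return table


def calibrate_from_config(cfg: dict[str, Any], free_param: str = "p_ih_t2d",
                          bounds: tuple[float, float] = (0.0, 0.2)):
    """Calibrate model 1 to the PHE T2D trajectory under the config baseline."""
    cfg = tio.validate_config(cfg)
    baseline = _baseline_from_config(cfg.get("markov", {}))
    ratios = cmp.DEFAULT_RATIOS
    phe = cmp.PUBLISHED_SOURCES["PHE"]
    target = {y: cmp.diabetes_to_t2d(v, ratios) for y, v in phe.values.items()}
    return calibrate_transition(
        make_model("model1"), free_param, target, bounds, baseline
    )
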