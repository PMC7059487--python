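"""CSV dialects, config parsing and the run manifest.

All value columns are written with 17 significant digits, so
read(write(x)) reproduces every float exactly.  Configs are flat
JSON or YAML mappings with module-namespaced sections; unknown keys are
hard errors to prevent silent misconfiguration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .markov import STATES, StateVector, Trajectory, TransitionMatrix
from .mortality import AgeSchedule
from .trend import AnnualSeries

#: exact float round-trip through text
_FLOAT_FMT = "%.17g"

# ---------------------------------------------------------------- states CSV


def write_states_csv(traj: Trajectory, path) -> None:
    """Header ``year,ng,ih,t2d,dead``; one row per year, values in millions."""
    traj.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_states_csv(path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["year", "ng", "ih", "t2d", "dead"]
    if list(df.columns) != expected:
        raise ValueError(f"states CSV must have columns {expected}, got {list(df.columns)}")
    states = tuple(
        StateVector(year=int(r.year), ng=r.ng, ih=r.ih, t2d=r.t2d, dead=r.dead)
        for r in df.itertuples()
    )
    return Trajectory(states=states)


# ---------------------------------------------------------------- matrix CSV


def write_matrix_csv(m: TransitionMatrix, path) -> None:
    """4x4 with header and row labels NG,IH,T2D,DEAD."""
    pd.DataFrame(m.p, index=list(STATES), columns=list(STATES)).to_csv(
        path, index_label="state", float_format=_FLOAT_FMT
    )


def read_matrix_csv(path) -> TransitionMatrix:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if list(df.columns) != list(STATES) or list(df.index) != list(STATES):
        raise ValueError(f"matrix CSV must be labelled {STATES} on both axes")
    return TransitionMatrix(p=df.to_numpy(dtype=float))


# ---------------------------------------------------------------- series CSV


def write_series_csv(series: AnnualSeries, path) -> None:
    """Header ``fiscal_year_start,diagnosed_millions``."""
    series.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_series_csv(path) -> AnnualSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["fiscal_year_start", "diagnosed_millions"]
    if list(df.columns) != expected:
        raise ValueError(f"series CSV must have columns {expected}, got {list(df.columns)}")
    return AnnualSeries(
        years=tuple(int(y) for y in df["fiscal_year_start"]),
        values=tuple(float(v) for v in df["diagnosed_millions"]),
    )


# ---------------------------------------------------------- age schedule CSV


def write_age_schedule_csv(sched: AgeSchedule, path) -> None:
    """Header ``band_label,age_lo,age_hi,weight,ref_rate``."""
    pd.DataFrame(
        {
            "band_label": sched.labels,
            "age_lo": sched.age_lo,
            "age_hi": sched.age_hi,
            "weight": sched.weights,
            "ref_rate": sched.ref_rates,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_age_schedule_csv(path) -> AgeSchedule:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["band_label", "age_lo", "age_hi", "weight", "ref_rate"]
    if list(df.columns) != expected:
        raise ValueError(
            f"age schedule CSV must have columns {expected}, got {list(df.columns)}"
        )
    return AgeSchedule(
        labels=tuple(str(v) for v in df["band_label"]),
        age_lo=tuple(float(v) for v in df["age_lo"]),
        age_hi=tuple(float(v) for v in df["age_hi"]),
        weights=tuple(float(v) for v in df["weight"]),
        ref_rates=tuple(float(v) for v in df["ref_rate"]),
    )


# ------------------------------------------------------------ comparison CSV


def write_comparison_csv(table: pd.DataFrame, path) -> None:
    """Header ``source,year,diabetes_true,t2d_true,ci_lo,ci_hi,mean_annual_increase``."""
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_comparison_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


# ------------------------------------------------------------------- config

#: Allowed keys per namespaced section; a hard allow-list.
CONFIG_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "out_dir"},
    "markov": {
        "adult_population",
        "diabetes_total",
        "ih_total",
        "t2d_share",
        "baseline_year",
        "horizon",
        "models",
        "ih_zero_variants",
        "ng_inflow",
    },
    "trend": {"series_csv", "project_years", "level"},
    "synth": {"intercept", "slope", "noise_sd", "year_start", "year_end"},
    "compare": {"years", "include_published", "plot"},
}

REQUIRED_KEYS = [("markov", "adult_population")]


def load_config(path) -> dict[str, Any]:
    """Read a JSON or YAML config and validate keys against the schema."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return validate_config(cfg)


def validate_config(cfg: dict[str, Any]) -> dict[str, Any]:
    for key, val in cfg.items():
        if key in CONFIG_SCHEMA[""]:
            continue
        if key not in CONFIG_SCHEMA:
            raise ValueError(f"unknown config key {key!r}")
        if not isinstance(val, dict):
            raise ValueError(f"config section {key!r} must be a mapping")
        for sub in val:
            if sub not in CONFIG_SCHEMA[key]:
                raise ValueError(f"unknown config key '{key}.{sub}'")
    for section, key in REQUIRED_KEYS:
        if key not in cfg.get(section, {}):
            raise ValueError(f"missing required config key {section}.{key}")
    return cfg


def config_hash(cfg: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def write_manifest(path, cfg: dict[str, Any], seeds: dict[str, int]) -> None:
    """Run manifest: package version, config hash, and every seed used."""
    from . import __version__

    manifest = {
        "package": "t2dproj",
        "version": __version__,
        "config_sha256": config_hash(cfg),
        "seeds": seeds,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
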