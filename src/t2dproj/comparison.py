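"""Cross-model comparison: conversion ratios, summary statistics, tables.

Different sources report prevalence on different scales.  Two fixed ratios
put them on a common footing: diagnosed counts are 75% of the true
(diagnosed + undiagnosed) prevalence of diabetes, so true = diagnosed x 4/3;
and T2D is 90% of all diabetes, so T2D = 0.9 x diabetes.  The comparison
table carries every source on both true scales, with the mean annual
increase from each source's first to last estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RatioSet",
    "DEFAULT_RATIOS",
    "PrevalenceBasedInputs",
    "SourceProjection",
    "PUBLISHED_SOURCES",
    "diagnosed_to_true",
    "diabetes_to_t2d",
    "mean_annual_increase",
    "prevalence_based_projection",
    "build_comparison_table",
    "plot_projections",
]


@dataclass(frozen=True)
class RatioSet:
    """Scale-conversion factors between reporting conventions."""

    diagnosed_to_true: float = 4.0 / 3.0  # diagnosed is 75% of true prevalence
    t2d_share: float = 0.90  # T2D is 90% of all diabetes

    def __post_init__(self) -> None:
        for name in ("diagnosed_to_true", "t2d_share"):
            v = getattr(self, name)
            if not 0.0 < v <= 2.0:
                raise ValueError(f"{name} must be in (0, 2], got {v!r}")


DEFAULT_RATIOS = RatioSet()


def diagnosed_to_true(x: float, r: RatioSet = DEFAULT_RATIOS) -> float:
    """True prevalence (millions) from a diagnosed count."""
    if np.any(np.asarray(x) < 0):
        raise ValueError("diagnosed count must be >= 0")
    return x * r.diagnosed_to_true


def diabetes_to_t2d(x: float, r: RatioSet = DEFAULT_RATIOS) -> float:
    """T2D prevalence (millions) from an all-diabetes prevalence."""
    if np.any(np.asarray(x) < 0):
        raise ValueError("diabetes prevalence must be >= 0")
    return x * r.t2d_share


def mean_annual_increase(
    first_year: int, first_value: float, last_year: int, last_value: float
) -> float:
    """Average increase per year from a source's first to last estimate."""
    if last_year <= first_year:
        raise ValueError(
            f"last_year must exceed first_year, got {first_year} -> {last_year}"
        )
    return (last_value - first_value) / (last_year - first_year)


@dataclass(frozen=True)
class PrevalenceBasedInputs:
    """Per-stratum prevalence proportions and projected populations.

    The prevalence-based projection is N(t) = sum over age-sex strata of
    D(t) x P(t): stratum prevalence times stratum population (millions).
    """

    groups: tuple[str, ...]
    d: tuple[float, ...]  # prevalence proportion per stratum
    p: tuple[float, ...]  # projected population per stratum, millions

    def __post_init__(self) -> None:
        if not (len(self.groups) == len(self.d) == len(self.p)):
            raise ValueError("groups, d and p must be aligned (equal lengths)")
        if np.any((np.asarray(self.d) < 0) | (np.asarray(self.d) > 1)):
            raise ValueError("prevalence proportions must lie in [0, 1]")
        if np.any(np.asarray(self.p) < 0):
            raise ValueError("populations must be >= 0")


def prevalence_based_projection(inp: PrevalenceBasedInputs) -> float:
    """N(t) = sum_strata D(t) x P(t), in millions."""
    return float(np.asarray(inp.d) @ np.asarray(inp.p))


@dataclass(frozen=True)
class SourceProjection:
    """One source's projections keyed by year, on a declared scale.

    ``scale`` is 'diabetes' (true all-diabetes prevalence) or 't2d' (true
    T2D prevalence).  ``series_first``/``series_last`` optionally carry the
    (year, value) endpoints of the source's underlying series for the mean
    annual increase; otherwise the endpoints of ``values`` are used.
    """

    label: str
    scale: str
    values: Mapping[int, float]
    ci: Optional[Mapping[int, tuple[float, float]]] = None
    series_first: Optional[tuple[int, float]] = None
    series_last: Optional[tuple[int, float]] = None

    def __post_init__(self) -> None:
        if self.scale not in ("diabetes", "t2d"):
            raise ValueError(f"scale must be 'diabetes' or 't2d', got {self.scale!r}")
        if not self.values:
            raise ValueError(f"source {self.label!r} has no values")


#: Published point estimates of true diabetes prevalence (millions) from the
#: prevalence-based models' own reports (PHE; the APHO model as used by
#: Holman et al; and the three global models), consumed as constants.
PUBLISHED_SOURCES: dict[str, SourceProjection] = {
    "PHE": SourceProjection(
        label="PHE",
        scale="diabetes",
        values={2015: 3.81, 2020: 4.09, 2025: 4.39, 2030: 4.68, 2035: 4.94},
        series_first=(2015, 3.81),
        series_last=(2035, 4.94),
    ),
    "Holman": SourceProjection(
        label="Holman",
        scale="diabetes",
        values={2015: 3.47, 2020: 3.82, 2025: 4.19, 2030: 4.60},
        ci={
            2015: (2.47, 5.07),
            2020: (2.70, 5.62),
            2025: (2.93, 6.19),
            2030: (3.25, 6.88),
        },
        series_first=(2010, 3.10),
        series_last=(2030, 4.60),
    ),
    "Shaw": SourceProjection(
        label="Shaw",
        scale="diabetes",
        values={2030: 2.55},
        series_first=(2010, 2.14),
        series_last=(2030, 2.55),
    ),
    "Whiting": SourceProjection(
        label="Whiting",
        scale="diabetes",
        values={2030: 3.65},
        series_first=(2011, 3.06),
        series_last=(2030, 3.65),
    ),
    "Guariguata": SourceProjection(
        label="Guariguata",
        scale="diabetes",
        values={2035: 3.62},
        series_first=(2013, 2.98),
        series_last=(2035, 3.62),
    ),
}


def _source_mai(src: SourceProjection) -> float:
    if src.series_first is not None and src.series_last is not None:
        (fy, fv), (ly, lv) = src.series_first, src.series_last
    else:
        years = sorted(src.values)
        fy, ly = years[0], years[-1]
        if fy == ly:
            return float("nan")
        fv, lv = src.values[fy], src.values[ly]
    return mean_annual_increase(fy, fv, ly, lv)


def build_comparison_table(
    sources: Sequence[SourceProjection],
    r: RatioSet = DEFAULT_RATIOS,
    years: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Assemble the per-source, per-year comparison on both true scales.

    Columns: source, year, diabetes_true, t2d_true, ci_lo, ci_hi,
    mean_annual_increase (per source, on its declared scale).  Interval
    bounds are converted onto the T2D scale alongside ``t2d_true``.  If
    ``years`` is given, every source must supply every requested year.
    """
    rows = []
    for src in sources:
        wanted = list(years) if years is not None else sorted(src.values)
        mai = _source_mai(src)
        for y in wanted:
            if y not in src.values:
                raise ValueError(f"source {src.label!r} has no value for year {y}")
            v = src.values[y]
            if src.scale == "diabetes":
                diab, t2d = v, diabetes_to_t2d(v, r)
                ci_scale = r.t2d_share
            else:
                diab, t2d = v / r.t2d_share, v
                ci_scale = 1.0
            ci = src.ci.get(y) if src.ci else None
            if ci is not None:
                ci = (ci[0] * ci_scale, ci[1] * ci_scale)
            rows.append(
                {
                    "source": src.label,
                    "year": y,
                    "diabetes_true": diab,
                    "t2d_true": t2d,
                    "ci_lo": ci[0] if ci else np.nan,
                    "ci_hi": ci[1] if ci else np.nan,
                    "mean_annual_increase": mai,
                }
            )
    cols = [
        "source",
        "year",
        "diabetes_true",
        "t2d_true",
        "ci_lo",
        "ci_hi",
        "mean_annual_increase",
    ]
    return pd.DataFrame(rows, columns=cols)


def plot_projections(
    table: pd.DataFrame, path: str, scale: str = "t2d_true", title: str = ""
) -> None:
    """Line chart of each source's projections over time (writes a file)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, grp in table.groupby("source"):
        grp = grp.sort_values("year")
        ax.plot(grp["year"], grp[scale], marker="o", label=label)
        if grp["ci_lo"].notna().any():
            ax.fill_between(grp["year"], grp["ci_lo"], grp["ci_hi"], alpha=0.15)
    ax.set_xlabel("year")
    ax.set_ylabel(f"{scale.replace('_', ' ')} (millions)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
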