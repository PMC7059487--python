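"""Synthetic stand-ins for the external inputs, so every stage is testable.

Three generators emulate the data the analysis otherwise downloads:

* a QOF-like annual diagnosed-diabetes series — near-perfectly linear
  counts in millions over fiscal years 2004/05–2017/18, i.i.d. Gaussian
  noise on counts (the simplest structure consistent with an adjusted R²
  around 0.995);
* age schedules standing in for survey age distributions and national
  life-table mortality, with a skew knob shifting population weight
  toward older bands and geometrically increasing rates;
* baseline prevalence estimates from a population total and fractions.

Defaults reproduce the magnitudes of the real series: diagnosed counts
rising ~0.110 million/year from ~1.77 million in 2004/05.
"""

from __future__ import annotations

import numpy as np

from .models import BaselineEstimate
from .mortality import AgeSchedule
from .trend import AnnualSeries

#: Default generating line for the QOF-like series (diagnosed millions).
QOF_SLOPE = 0.110
QOF_INTERCEPT = 1.77 - QOF_SLOPE * 2004  # count ~1.77M in fiscal 2004/05
QOF_NOISE_SD = 0.03
QOF_YEARS = range(2004, 2018)


def gen_qof_series(
    intercept: float = QOF_INTERCEPT,
    slope: float = QOF_SLOPE,
    noise_sd: float = QOF_NOISE_SD,
    years=QOF_YEARS,
    seed: int = 0,
) -> AnnualSeries:
    """Noisy linear annual diagnosed-count series, clipped at zero."""
    years = list(years)
    if not years:
        raise ValueError("years range is empty")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd!r}")
    rng = np.random.default_rng(seed)
    x = np.asarray(years, dtype=float)
    y = intercept + slope * x + rng.normal(0.0, noise_sd, size=len(years))
    y = np.clip(y, 0.0, None)
    return AnnualSeries(years=tuple(int(v) for v in years), values=tuple(float(v) for v in y))


def gen_age_schedule(
    skew: float = 0.0,
    n_bands: int = 7,
    base_rate: float = 0.001,
    gradient: float = 2.2,
    seed: int | None = None,
) -> AgeSchedule:
    """Age schedule with tunable age skew and geometric mortality gradient.

    Weights are proportional to exp(skew * position), position running 0..1
    across bands: skew 0 gives uniform weights, positive skew shifts mass to
    older bands.  Reference rates are base_rate * gradient**band.  The
    schedule is a deterministic function of its parameters; ``seed`` is
    accepted for interface uniformity with the other generators.
    """
    if n_bands < 2:
        raise ValueError(f"n_bands must be >= 2, got {n_bands}")
    pos = np.arange(n_bands) / (n_bands - 1)
    w = np.exp(skew * pos)
    w = w / w.sum()
    rates = base_rate * gradient ** np.arange(n_bands)
    if np.any(rates > 1.0):
        raise ValueError(
            f"rate overflow: base_rate {base_rate} with gradient {gradient} "
            f"exceeds 1 within {n_bands} bands"
        )
    lo = 18.0 + 10.0 * np.arange(n_bands)
    hi = lo + 10.0
    labels = tuple(f"{int(a)}-{int(b) - 1}" for a, b in zip(lo, hi))
    return AgeSchedule(
        labels=labels,
        age_lo=tuple(lo),
        age_hi=tuple(hi),
        weights=tuple(float(v) for v in w),
        ref_rates=tuple(float(v) for v in rates),
    )


def gen_baseline(
    population: float, diabetes_frac: float, ih_frac: float
) -> BaselineEstimate:
    """Baseline prevalences from a population total and state fractions."""
    if diabetes_frac < 0 or ih_frac < 0:
        raise ValueError("fractions must be >= 0")
    if diabetes_frac + ih_frac >= 1.0:
        raise ValueError(
            f"diabetes_frac + ih_frac = {diabetes_frac + ih_frac} must be < 1"
        )
    return BaselineEstimate(
        diabetes_total=population * diabetes_frac,
        ih_total=population * ih_frac,
        adult_population=population,
        year=2015,
    )
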