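"""State mortality from age structure, reference mortality and hazard ratios.

A glycaemic state's annual mortality probability is built as

    m_state = HR x sum_bands( weight_band x ref_rate_band )

i.e. the state's age distribution is used to weight an age-specific
reference mortality schedule, and the result is scaled by the state's
hazard ratio versus the reference group.  With HR = 1 and the general
adult age distribution this reproduces the reference rate; a state with a
younger age profile (normoglycaemia) comes out below the general adult
rate even at HR = 1, which is how a 0.6% NG rate coexists with a 0.9%
all-adult rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class AgeSchedule:
    """Age bands with a state's population weights and reference mortality.

    ``weights`` are the proportions of the state's population in each band
    (must sum to 1); ``ref_rates`` are annual reference mortality
    probabilities per band.
    """

    labels: tuple[str, ...]
    age_lo: tuple[float, ...]
    age_hi: tuple[float, ...]
    weights: tuple[float, ...]
    ref_rates: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        for name in ("age_lo", "age_hi", "weights", "ref_rates"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have {n} entries like labels")
        if n < 1:
            raise ValueError("schedule needs at least one band")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be >= 0")
        if abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"weights sum to {w.sum()!r}, not 1")
        r = np.asarray(self.ref_rates, dtype=float)
        if np.any((r < 0) | (r > 1)):
            raise ValueError("ref_rates must lie in [0, 1]")
        lo = np.asarray(self.age_lo, dtype=float)
        hi = np.asarray(self.age_hi, dtype=float)
        if np.any(hi <= lo):
            raise ValueError("each band must have age_hi > age_lo")
        if np.any(lo[1:] < hi[:-1]):
            raise ValueError("bands must be ordered and non-overlapping")


@dataclass(frozen=True)
class HazardRatioSet:
    """Mortality hazard ratios used by the England models.

    The IH ratio for HbA1c-defined hyperglycaemia (0.97, CI 0.88–1.07) is
    not significantly different from 1 and is applied as exactly 1.
    """

    hr_diabetes: float = 1.32
    hr_t2d: float = 1.28
    hr_ih_igt: float = 1.32
    hr_ih_igt_ci: tuple[float, float] = (1.23, 1.40)
    hr_ih_hba1c: float = 0.97
    hr_ih_hba1c_ci: tuple[float, float] = (0.88, 1.07)
    hr_ih_hba1c_applied: float = field(default=1.0)
    reference: str = "normoglycaemia"

    def __post_init__(self) -> None:
        for name in ("hr_diabetes", "hr_t2d", "hr_ih_igt", "hr_ih_hba1c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.hr_ih_hba1c_applied != 1.0:
            raise ValueError("the applied HbA1c IH hazard ratio is fixed at 1.0")


DEFAULT_HAZARD_RATIOS = HazardRatioSet()


def state_mortality(sched: AgeSchedule, hr: float) -> float:
    """Annual mortality probability of a state: HR x age-weighted reference rate.

    Capped at 1 (with a warning) if the scaled rate exceeds a probability.
    """
    if hr <= 0:
        raise ValueError(f"hazard ratio must be > 0, got {hr!r}")
    w = np.asarray(sched.weights, dtype=float)
    r = np.asarray(sched.ref_rates, dtype=float)
    m = hr * float(w @ r)
    if m > 1.0:
        warnings.warn(
            f"hr x weighted rate = {m:.4g} exceeds 1; capping at 1", stacklevel=2
        )
        return 1.0
    return m


def hr_policy(measure: str, hrset: HazardRatioSet = DEFAULT_HAZARD_RATIOS) -> float:
    """Hazard ratio applied for IH under a given glycaemic risk measure.

    IGT keeps its significant estimate (1.32); HbA1c is applied as 1
    because its estimate is not significantly different from 1.  No rule
    exists for other measures.
    """
    if measure == "IGT":
        return hrset.hr_ih_igt
    if measure == "HbA1c":
        return hrset.hr_ih_hba1c_applied
    raise ValueError(
        f"no hazard-ratio policy for measure {measure!r}; supported: IGT, HbA1c"
    )
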