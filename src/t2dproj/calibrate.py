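"""Calibrate one transition probability against a target T2D trajectory.

This reproduces how the PHE-matching model was constructed: starting from
a published parameter set, the IH→T2D probability is tuned so that the
cohort projection tracks a target trajectory (the PHE projections on the
T2D scale) in a least-squares sense.  The objective is smooth but can be
near-flat in explosive regimes, so a deterministic 101-point grid pre-pass
brackets the minimum before bounded scalar minimisation refines it.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping

import numpy as np
from scipy.optimize import minimize_scalar

from . import markov
from .models import BaselineEstimate, ModelSpec, baseline_state

_GRID_POINTS = 101

_PROB_FIELDS = {
    f.name for f in fields(ModelSpec) if f.name.startswith(("p_", "m_"))
}


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted probability with the optimiser's diagnostics."""

    free_param: str
    value: float
    objective: float
    converged: bool
    bounds: tuple[float, float]


def _t2d_at_years(
    spec: ModelSpec, baseline: BaselineEstimate, years: tuple[int, ...]
) -> np.ndarray:
    traj = markov.project(baseline_state(baseline), markov.build_matrix(spec), max(years))
    return np.array([traj.t2d(y) for y in years])


def calibrate_transition(
    spec: ModelSpec,
    free_param: str,
    target: Mapping[int, float],
    bounds: tuple[float, float],
    baseline: BaselineEstimate,
    tol: float = 1e-8,
) -> CalibrationResult:
    """Least-squares fit of one ModelSpec probability to a year→T2D target.

    Returns the probability in ``bounds`` minimising the unweighted sum of
    squared differences between the projected T2D compartment and the
    target values at the target years.  Deterministic: same inputs, same
    result.
    """
    if free_param not in _PROB_FIELDS:
        raise ValueError(
            f"free_param must be one of {sorted(_PROB_FIELDS)}, got {free_param!r}"
        )
    lo, hi = bounds
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"bounds must satisfy 0 <= lo < hi <= 1, got {bounds!r}")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    years = tuple(sorted(target))
    if not years:
        raise ValueError("target trajectory is empty")
    if min(years) < baseline.year:
        raise ValueError("target years precede the baseline year")
    tvals = np.array([float(target[y]) for y in years])

    # a negative residual diagonal anywhere in [lo, hi] means the bounds are
    # inconsistent with the rest of the parameter set; outflow is monotone in
    # the free parameter, so checking both ends suffices
    for b in (lo, hi):
        markov.build_matrix(spec.with_(**{free_param: b}))

    def objective(x: float) -> float:
        resid = _t2d_at_years(spec.with_(**{free_param: float(x)}), baseline, years) - tvals
        val = float(resid @ resid)
        if not np.isfinite(val):
            raise ValueError(f"non-finite objective at {free_param}={x!r}")
        return val

    grid = np.linspace(lo, hi, _GRID_POINTS)
    fgrid = np.array([objective(x) for x in grid])
    k = int(np.argmin(fgrid))
    blo = grid[max(k - 1, 0)]
    bhi = grid[min(k + 1, _GRID_POINTS - 1)]
    res = minimize_scalar(
        objective, bounds=(blo, bhi), method="bounded", options={"xatol": tol}
    )
    # keep whichever candidate is best (grid point may tie or beat on flat stretches)
    if fgrid[k] < res.fun:
        value, obj = float(grid[k]), float(fgrid[k])
    else:
        value, obj = float(res.x), float(res.fun)
    return CalibrationResult(
        free_param=free_param,
        value=value,
        objective=obj,
        converged=bool(res.success),
        bounds=(float(lo), float(hi)),
    )
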