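"""Discrete-time Markov cohort engine for glycaemic-state progression.

The cohort moves annually between four states — normoglycaemia (NG),
intermediate hyperglycaemia (IH, "pre-diabetes"), type 2 diabetes (T2D)
and death (absorbing).  Counts are real-valued millions of adults; the
cohort is closed by default (no entrants), with an optional constant
annual inflow into NG.

The transition matrix is assembled from named off-diagonal probabilities
under the residual rule: the probability of remaining in a live state is
one minus the sum of all exits from it (other-state moves plus state
mortality), so every row sums to exactly one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .models import ModelSpec

#: Fixed state order used by every array, CSV header and matrix in the package.
STATES: tuple[str, ...] = ("NG", "IH", "T2D", "DEAD")
NG, IH, T2D, DEAD = range(4)

_ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class StateVector:
    """Compartment counts (millions) at a calendar year.

    ``dead`` is the cumulative number of deaths since the baseline year,
    so that a closed cohort conserves ``ng + ih + t2d + dead``.
    """

    year: int
    ng: float
    ih: float
    t2d: float
    dead: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ng", "ih", "t2d", "dead"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v!r}")

    @property
    def total(self) -> float:
        return self.ng + self.ih + self.t2d + self.dead

    def as_array(self) -> np.ndarray:
        return np.array([self.ng, self.ih, self.t2d, self.dead], dtype=float)

    @classmethod
    def from_array(cls, year: int, arr: np.ndarray) -> "StateVector":
        arr = np.asarray(arr, dtype=float)
        # guard tiny negative round-off from the matrix product
        arr = np.where((arr < 0) & (arr > -1e-12), 0.0, arr)
        return cls(year=int(year), ng=arr[NG], ih=arr[IH], t2d=arr[T2D], dead=arr[DEAD])


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 4x4 annual transition probabilities, DEAD absorbing."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got shape {p.shape}")
        if np.any(p < -_ROW_SUM_TOL) or np.any(p > 1 + _ROW_SUM_TOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rowsums = p.sum(axis=1)
        bad = np.abs(rowsums - 1.0) > _ROW_SUM_TOL
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"row {STATES[i]} sums to {rowsums[i]!r}, not 1 (tol {_ROW_SUM_TOL})"
            )
        if not np.array_equal(p[DEAD], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("DEAD row must be (0, 0, 0, 1): death is absorbing")
        object.__setattr__(self, "p", p)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TransitionMatrix):
            return NotImplemented
        return np.array_equal(self.p, other.p)


@dataclass(frozen=True)
class Trajectory:
    """One StateVector per year from baseline to horizon (inclusive)."""

    states: tuple[StateVector, ...] = field(default=())

    def __post_init__(self) -> None:
        states = tuple(self.states)
        if not states:
            raise ValueError("a trajectory needs at least one state")
        for a, b in zip(states, states[1:]):
            if b.year != a.year + 1:
                raise ValueError(f"years must be consecutive: {a.year} -> {b.year}")
            if b.dead < a.dead - 1e-12:
                raise ValueError(f"dead count decreased between {a.year} and {b.year}")
        object.__setattr__(self, "states", states)

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    def __getitem__(self, i):
        return self.states[i]

    @property
    def years(self) -> list[int]:
        return [s.year for s in self.states]

    def at(self, year: int) -> StateVector:
        for s in self.states:
            if s.year == year:
                return s
        raise KeyError(f"year {year} not in trajectory ({self.years[0]}..{self.years[-1]})")

    def t2d(self, year: int) -> float:
        """T2D prevalence (millions) at a year of the trajectory."""
        return self.at(year).t2d

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "year": self.years,
                "ng": [s.ng for s in self.states],
                "ih": [s.ih for s in self.states],
                "t2d": [s.t2d for s in self.states],
                "dead": [s.dead for s in self.states],
            }
        )


def build_matrix(spec: "ModelSpec") -> TransitionMatrix:
    """Assemble the annual transition matrix from named probabilities.

    Diagonals are always recomputed under the residual rule; a negative
    residual signals an inconsistent parameter set and raises ``ValueError``
    naming the offending row and its outflow sum.
    """
    p = np.zeros((4, 4))
    p[NG, IH] = spec.p_ng_ih
    p[NG, T2D] = spec.p_ng_t2d
    p[NG, DEAD] = spec.m_ng
    p[IH, NG] = spec.p_ih_ng
    p[IH, T2D] = spec.p_ih_t2d
    p[IH, DEAD] = spec.m_ih
    p[T2D, IH] = spec.p_t2d_ih
    p[T2D, DEAD] = spec.m_t2d
    p[DEAD, DEAD] = 1.0
    for s in (NG, IH, T2D):
        outflow = p[s].sum()
        if outflow > 1 + _ROW_SUM_TOL:
            raise ValueError(
                f"state {STATES[s]}: outflow sum {outflow:.6g} exceeds 1; "
                "residual diagonal would be negative (inconsistent parameters)"
            )
        p[s, s] = 1.0 - outflow
    return TransitionMatrix(p=p)


def step(state: StateVector, m: TransitionMatrix, ng_inflow: float = 0.0) -> StateVector:
    """Advance the cohort by one annual cycle (counts @ matrix, year + 1)."""
    if ng_inflow < 0:
        raise ValueError("ng_inflow must be >= 0")
    nxt = state.as_array() @ m.p
    nxt[NG] += ng_inflow
    return StateVector.from_array(state.year + 1, nxt)


def project(
    initial: StateVector,
    m: TransitionMatrix,
    horizon_year: int,
    ng_inflow: float = 0.0,
) -> Trajectory:
    """Deterministic cohort projection from baseline to ``horizon_year``."""
    if horizon_year < initial.year:
        raise ValueError(
            f"horizon_year {horizon_year} is before the baseline year {initial.year}"
        )
    states = [initial]
    for _ in range(horizon_year - initial.year):
        states.append(step(states[-1], m, ng_inflow=ng_inflow))
    return Trajectory(states=tuple(states))


def _allocate_agents(counts: np.ndarray, n_agents: int) -> np.ndarray:
    """Largest-remainder apportionment of n_agents across compartments."""
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot allocate agents: total population is zero")
    quota = counts / total * n_agents
    base = np.floor(quota).astype(np.int64)
    short = n_agents - int(base.sum())
    if short:
        order = np.argsort(-(quota - base))
        base[order[:short]] += 1
    return base


def simulate_individuals(
    initial: StateVector,
    m: TransitionMatrix,
    horizon_year: int,
    n_agents: int,
    seed: int,
) -> Trajectory:
    """Monte-Carlo oracle: agent-level simulation of the same chain.

    Each agent samples its next state from its row of the matrix every
    year.  Counts are rescaled back to millions so the returned trajectory
    is directly comparable with :func:`project`; its expectation equals
    the deterministic projection, which the test-suite exploits.
    """
    if n_agents <= 0:
        raise ValueError("n_agents must be > 0")
    if horizon_year < initial.year:
        raise ValueError("horizon_year is before the baseline year")
    rng = np.random.default_rng(seed)
    counts = _allocate_agents(initial.as_array(), n_agents)
    scale = initial.total / n_agents
    states = [StateVector.from_array(initial.year, counts * scale)]
    for year in range(initial.year + 1, horizon_year + 1):
        nxt = np.zeros(4, dtype=np.int64)
        for s in range(4):
            if counts[s] == 0:
                continue
            nxt += rng.multinomial(counts[s], m.p[s])
        counts = nxt
        states.append(StateVector.from_array(year, counts * scale))
    return Trajectory(states=tuple(states))
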