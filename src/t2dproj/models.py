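"""The three published-parameter Markov models and the 2015 baseline.

Model 1 uses the HbA1c transition probabilities of Roberts et al with the
IH→T2D rate recommended by meta-analysis (0.036); model 2 is model 1 with
IH→T2D lowered to 0.013 (the value that reproduces the PHE trajectory);
model 3 uses the IGT probabilities of Neumann et al, the only reviewed
model allowing T2D→IH reversion (0.005).  State mortality probabilities
were derived for England 2015 from age-specific reference mortality and
hazard ratios (see :mod:`t2dproj.mortality`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .markov import StateVector

#: Fraction of all diabetes that is type 2, used to initialise the T2D compartment.
DEFAULT_T2D_SHARE = 0.90


@dataclass(frozen=True)
class ModelSpec:
    """Named annual transition and mortality probabilities of one model."""

    name: str
    p_ng_ih: float  # NG -> IH
    p_ih_ng: float  # IH -> NG
    p_ng_t2d: float  # NG -> T2D (0 in all built-in models)
    p_ih_t2d: float  # IH -> T2D
    p_t2d_ih: float  # T2D -> IH (reversion; model 3 only)
    m_ng: float  # annual mortality, NG
    m_ih: float  # annual mortality, IH
    m_t2d: float  # annual mortality, T2D
    risk_measure: str = "unspecified"  # HbA1c | IGT | IFG | FPG | unspecified

    def __post_init__(self) -> None:
        probs = {
            f: getattr(self, f)
            for f in (
                "p_ng_ih",
                "p_ih_ng",
                "p_ng_t2d",
                "p_ih_t2d",
                "p_t2d_ih",
                "m_ng",
                "m_ih",
                "m_t2d",
            )
        }
        for f, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be a probability in [0, 1], got {v!r}")
        outflows = {
            "NG": self.p_ng_ih + self.p_ng_t2d + self.m_ng,
            "IH": self.p_ih_ng + self.p_ih_t2d + self.m_ih,
            "T2D": self.p_t2d_ih + self.m_t2d,
        }
        for state, s in outflows.items():
            if s > 1.0 + 1e-12:
                raise ValueError(f"outflow from {state} sums to {s:.6g} > 1")

    def with_(self, **kwargs) -> "ModelSpec":
        """A copy with some fields replaced (used by calibration)."""
        return replace(self, **kwargs)


_MODEL1 = ModelSpec(
    name="model1",
    p_ng_ih=0.0686,
    p_ih_ng=0.0897,
    p_ng_t2d=0.0,
    p_ih_t2d=0.036,
    p_t2d_ih=0.0,
    m_ng=0.006,
    m_ih=0.019,
    m_t2d=0.023,
    risk_measure="HbA1c",
)

BUILTIN_MODELS: dict[str, ModelSpec] = {
    "model1": _MODEL1,
    "model2": _MODEL1.with_(name="model2", p_ih_t2d=0.013),
    "model3": ModelSpec(
        name="model3",
        p_ng_ih=0.163,
        p_ih_ng=0.162,
        p_ng_t2d=0.0,
        p_ih_t2d=0.060,
        p_t2d_ih=0.005,
        m_ng=0.006,
        m_ih=0.023,
        m_t2d=0.022,
        risk_measure="IGT",
    ),
}


def make_model(name: str) -> ModelSpec:
    """Return a built-in model specification by name."""
    try:
        return BUILTIN_MODELS[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; available: {', '.join(sorted(BUILTIN_MODELS))}"
        ) from None


@dataclass(frozen=True)
class BaselineEstimate:
    """2015 starting prevalences (millions) for the cohort projection.

    ``adult_population`` is the England adult population total and must be
    supplied (the ONS mid-2015 estimate is the documented choice); NG is
    derived as the residual after removing diabetes and IH.
    """

    diabetes_total: float
    ih_total: float
    adult_population: float
    year: int = 2015
    t2d_share: float = DEFAULT_T2D_SHARE

    def __post_init__(self) -> None:
        if self.ih_total < 0 or self.diabetes_total < 0:
            raise ValueError("prevalence totals must be >= 0")
        if not 0.0 < self.t2d_share <= 1.0:
            raise ValueError(f"t2d_share must be in (0, 1], got {self.t2d_share!r}")
        ng = self.adult_population - self.diabetes_total - self.ih_total
        if ng < 0:
            raise ValueError(
                f"adult_population {self.adult_population} is smaller than "
                f"diabetes + IH ({self.diabetes_total + self.ih_total}); "
                "residual normoglycaemia would be negative"
            )


def baseline_state(b: BaselineEstimate) -> StateVector:
    """Initial state: T2D = share x diabetes, NG the population residual."""
    return StateVector(
        year=b.year,
        ng=b.adult_population - b.diabetes_total - b.ih_total,
        ih=b.ih_total,
        t2d=b.t2d_share * b.diabetes_total,
        dead=0.0,
    )
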