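"""Matrix assembly, cohort stepping and the agent-level oracle."""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from t2dproj import markov
from t2dproj.markov import (
    DEAD,
    IH,
    NG,
    T2D,
    StateVector,
    Trajectory,
    TransitionMatrix,
    build_matrix,
    project,
    simulate_individuals,
    step,
)
from t2dproj.models import ModelSpec, make_model

prob = st.floats(min_value=0.0, max_value=0.3, allow_nan=False)


@st.composite
def model_specs(draw):
    """Random but internally consistent parameter sets (outflows < 1)."""
    return ModelSpec(
        name="random",
        p_ng_ih=draw(prob),
        p_ih_ng=draw(prob),
        p_ng_t2d=draw(prob),
        p_ih_t2d=draw(prob),
        p_t2d_ih=draw(prob),
        m_ng=draw(prob),
        m_ih=draw(prob),
        m_t2d=draw(prob),
    )


@st.composite
def state_vectors(draw):
    counts = st.floats(min_value=0.0, max_value=100.0, allow_nan=False)
    return StateVector(
        year=2015, ng=draw(counts), ih=draw(counts), t2d=draw(counts), dead=draw(counts)
    )


# ------------------------------------------------------------- build_matrix


@pytest.mark.parametrize(
    "model, state, expected_diag",
    [
        ("model3", NG, 1 - (0.163 + 0.0 + 0.006)),  # 0.831
        ("model2", IH, 1 - (0.0897 + 0.013 + 0.019)),  # 0.8783 -> prints 0.878
        ("model1", T2D, 1 - (0.0 + 0.023)),
    ],
)
def test_residual_diagonals(model, state, expected_diag):
    m = build_matrix(make_model(model))
    assert m.p[state, state] == pytest.approx(expected_diag, abs=1e-12)


def test_model2_ih_diagonal_rounds_to_published_value():
    m = build_matrix(make_model("model2"))
    assert round(m.p[IH, IH], 3) == 0.878


def test_zero_parameters_give_identity_live_rows():
    spec = ModelSpec(
        name="null", p_ng_ih=0, p_ih_ng=0, p_ng_t2d=0, p_ih_t2d=0, p_t2d_ih=0,
        m_ng=0, m_ih=0, m_t2d=0,
    )
    assert np.array_equal(build_matrix(spec).p, np.eye(4))


def test_inconsistent_outflow_names_row_and_sum():
    bad = SimpleNamespace(
        p_ng_ih=0.9, p_ng_t2d=0.2, m_ng=0.1,
        p_ih_ng=0.0, p_ih_t2d=0.0, m_ih=0.0, p_t2d_ih=0.0, m_t2d=0.0,
    )
    with pytest.raises(ValueError, match="state NG.*1.2"):
        build_matrix(bad)


@given(model_specs())
def test_assembled_matrices_are_row_stochastic(spec):
    p = build_matrix(spec).p
    assert np.all(np.abs(p.sum(axis=1) - 1.0) <= 1e-12)
    assert np.all((p >= 0) & (p <= 1))
    assert np.array_equal(p[DEAD], [0, 0, 0, 1])


# --------------------------------------------------------------------- step


def test_step_zero_state_stays_zero():
    m = build_matrix(make_model("model1"))
    nxt = step(StateVector(year=2015, ng=0, ih=0, t2d=0), m)
    assert nxt == StateVector(year=2016, ng=0, ih=0, t2d=0)


def test_step_half_split():
    spec = ModelSpec(
        name="half", p_ng_ih=0.5, p_ih_ng=0, p_ng_t2d=0, p_ih_t2d=0, p_t2d_ih=0,
        m_ng=0, m_ih=0, m_t2d=0,
    )
    nxt = step(StateVector(year=2015, ng=100, ih=0, t2d=0), build_matrix(spec))
    assert (nxt.ng, nxt.ih, nxt.t2d, nxt.dead) == (50.0, 50.0, 0.0, 0.0)


def test_step_matches_hand_multiplied_product():
    # model 1 matrix applied once to (10, 5, 3, 0), multiplied out by hand:
    # ng'  = 10*0.9254 + 5*0.0897            = 9.7025
    # ih'  = 10*0.0686 + 5*0.8553            = 4.9625
    # t2d' =             5*0.036  + 3*0.977  = 3.111
    # dead'= 10*0.006  + 5*0.019  + 3*0.023  = 0.224
    nxt = step(
        StateVector(year=2015, ng=10, ih=5, t2d=3), build_matrix(make_model("model1"))
    )
    assert nxt.ng == pytest.approx(9.7025, abs=1e-12)
    assert nxt.ih == pytest.approx(4.9625, abs=1e-12)
    assert nxt.t2d == pytest.approx(3.111, abs=1e-12)
    assert nxt.dead == pytest.approx(0.224, abs=1e-12)
    assert nxt.total == pytest.approx(18.0, rel=1e-12)


# ------------------------------------------------------------------ project


def test_project_horizon_equal_baseline_is_length_one(baseline_vector):
    traj = project(baseline_vector, build_matrix(make_model("model1")), 2015)
    assert len(traj) == 1 and traj[0] == baseline_vector


def test_project_before_baseline_raises(baseline_vector):
    with pytest.raises(ValueError, match="before the baseline"):
        project(baseline_vector, build_matrix(make_model("model1")), 2014)


def test_two_cycles_compose(baseline_vector):
    m = build_matrix(make_model("model3"))
    traj = project(baseline_vector, m, 2017)
    assert traj[2] == step(step(baseline_vector, m), m)


@given(model_specs(), state_vectors())
def test_cohort_is_conserved_over_twenty_cycles(spec, x0):
    traj = project(x0, build_matrix(spec), x0.year + 20)
    totals = np.array([s.total for s in traj])
    assert np.all(np.abs(totals - x0.total) <= 1e-9 * max(x0.total, 1.0))


@given(model_specs(), state_vectors())
def test_dead_compartment_is_monotone(spec, x0):
    traj = project(x0, build_matrix(spec), x0.year + 10)
    dead = np.array([s.dead for s in traj])
    assert np.all(np.diff(dead) >= -1e-12)


@given(model_specs(), st.floats(min_value=0.1, max_value=5.0))
def test_more_baseline_ih_never_lowers_future_t2d(spec, extra_ih):
    m = build_matrix(spec)
    lo = project(StateVector(year=2015, ng=30, ih=5, t2d=3), m, 2030)
    hi = project(StateVector(year=2015, ng=30, ih=5 + extra_ih, t2d=3), m, 2030)
    for a, b in zip(lo, hi):
        assert b.t2d >= a.t2d - 1e-12


def test_frozen_dynamics_leave_trajectory_constant():
    spec = ModelSpec(
        name="frozen", p_ng_ih=0, p_ih_ng=0, p_ng_t2d=0, p_ih_t2d=0, p_t2d_ih=0,
        m_ng=0, m_ih=0, m_t2d=0,
    )
    traj = project(StateVector(year=2015, ng=10, ih=5, t2d=3), build_matrix(spec), 2025)
    assert all((s.ng, s.ih, s.t2d, s.dead) == (10, 5, 3, 0) for s in traj)


def test_ng_inflow_grows_the_cohort(baseline_vector):
    m = build_matrix(make_model("model1"))
    traj = project(baseline_vector, m, 2020, ng_inflow=0.5)
    assert traj[-1].total == pytest.approx(baseline_vector.total + 0.5 * 5, rel=1e-12)


# --------------------------------------------------------------- trajectory


def test_trajectory_rejects_gap_years():
    a = StateVector(year=2015, ng=1, ih=0, t2d=0)
    b = StateVector(year=2017, ng=1, ih=0, t2d=0)
    with pytest.raises(ValueError, match="consecutive"):
        Trajectory(states=(a, b))


def test_matrix_rejects_nonstochastic_rows():
    p = np.eye(4)
    p[0, 0] = 0.9
    with pytest.raises(ValueError, match="row NG"):
        TransitionMatrix(p=p)


# ------------------------------------------------------ agent-level oracle


def test_all_dead_cohort_is_constant():
    m = build_matrix(make_model("model1"))
    start = StateVector(year=2015, ng=0, ih=0, t2d=0, dead=2.0)
    traj = simulate_individuals(start, m, 2020, n_agents=1000, seed=7)
    assert all(s.dead == pytest.approx(2.0) and s.total == pytest.approx(2.0) for s in traj)


def test_same_seed_reproduces_simulation(baseline_vector):
    m = build_matrix(make_model("model3"))
    a = simulate_individuals(baseline_vector, m, 2020, n_agents=5000, seed=42)
    b = simulate_individuals(baseline_vector, m, 2020, n_agents=5000, seed=42)
    assert a.states == b.states


def test_zero_agents_rejected(baseline_vector):
    m = build_matrix(make_model("model1"))
    with pytest.raises(ValueError, match="n_agents"):
        simulate_individuals(baseline_vector, m, 2020, n_agents=0, seed=1)


def test_simulation_conserves_agents(baseline_vector):
    m = build_matrix(make_model("model2"))
    traj = simulate_individuals(baseline_vector, m, 2025, n_agents=20_000, seed=3)
    for s in traj:
        assert s.total == pytest.approx(baseline_vector.total, rel=1e-12)
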