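"""Objective components: E, C_DE, OF, and the batched evaluator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from defit.derivatives import DerivativeSettings
from defit.elimination import lie_derivatives
from defit.objective import (
    ObjectiveEvaluator,
    ObjectiveSpec,
    constraint_C,
    error_E,
    objective_OF,
)
from defit.simulate import simulate
from defit.trajectory import Trajectory


def _traj(times, y, role="measured", name="y"):
    return Trajectory(times=times, values={name: y}, role=role)


# -- error_E --------------------------------------------------------------


def test_error_zero_on_identical_trajectories(ref1):
    obs = ref1.subset(["x_AB"])
    assert error_E(obs, obs.with_role("measured")) == 0.0


def test_error_closed_form_ten_percent_offset():
    """x^c = 1.1 x^m on a 100-point grid gives E = 100 * 0.1 = 10."""
    t = np.linspace(0.01, 1.0, 100)
    ym = np.linspace(1.0, 3.0, 100)
    E = error_E(_traj(t, 1.1 * ym, "calculated"), _traj(t, ym))
    assert E == pytest.approx(10.0, abs=1e-9)


def test_error_matches_two_loop_reference(m1, ref1):
    """Vectorised E equals a hand-rolled double loop, exactly."""
    calc = simulate(m1, {"k_p": 0.07, "k_m": 0.5})
    E = error_E(calc, ref1.with_role("measured"), observed=["x_AB"])
    brute = 0.0
    for var in ["x_AB"]:
        for i in range(len(ref1)):
            xm = ref1[var][i]
            brute += abs(calc[var][i] - xm) / max(abs(xm), 1e-12)
    # identical term set; only the accumulation order differs
    assert E == pytest.approx(brute, rel=1e-13)


def test_error_requires_shared_grid():
    t1 = np.linspace(0.01, 1.0, 100)
    t2 = np.linspace(0.01, 1.0, 50)
    with pytest.raises(ValueError, match="grid"):
        error_E(_traj(t1, t1, "calculated"), _traj(t2, t2))


# -- objective_OF ---------------------------------------------------------


@settings(max_examples=50, deadline=None)
@given(
    E=st.floats(0, 1e6, allow_nan=False),
    C=st.floats(0, 1e6, allow_nan=False),
    alpha=st.floats(0, 1, allow_nan=False),
)
def test_objective_blend_identities(E, C, alpha):
    of = objective_OF(E, C, alpha)
    assert objective_OF(E, C, 0.0) == E
    assert objective_OF(E, C, 1.0) == C
    assert min(E, C) - 1e-9 <= of <= max(E, C) + 1e-9


def test_objective_arithmetic_example():
    assert objective_OF(10.0, 2.0, 0.1) == pytest.approx(9.2)


# -- constraint_C ---------------------------------------------------------


@pytest.fixture(scope="module")
def m1_constraint_inputs(m1, sys1, ref1):
    measured = ref1.subset(["x_AB"]).with_role("measured")
    derivs = {("x_AB", 1): lie_derivatives(m1, "x_AB", 1, traj=ref1)[1]}
    states = {s: ref1[s] for s in m1.states}
    return measured, derivs, states


def test_constraint_vanishes_at_truth(m1, sys1, m1_constraint_inputs):
    measured, derivs, states = m1_constraint_inputs
    C = constraint_C(sys1, m1.param_dict(), measured, derivs, state_values=states)
    assert C < 1e-4


def test_constraint_grows_under_kp_doubling(m1, sys1, m1_constraint_inputs):
    measured, derivs, states = m1_constraint_inputs
    true_C = constraint_C(sys1, m1.param_dict(), measured, derivs, state_values=states)
    bad = m1.param_dict()
    bad["k_p"] *= 2
    bad_C = constraint_C(sys1, bad, measured, derivs, state_values=states)
    assert bad_C > 10 * max(true_C, 1e-12)


def test_constraint_zero_for_empty_system(m1, sys1, m1_constraint_inputs):
    from dataclasses import replace

    measured, derivs, _ = m1_constraint_inputs
    empty = replace(sys1, equations=(), leaders=())
    assert constraint_C(empty, m1.param_dict(), measured, derivs) == 0.0


def test_constraint_skips_equations_above_max_order(m2, sys2, ref2):
    measured = ref2.subset(["x_1"]).with_role("measured")
    derivs = {("x_1", k): v for k, v in lie_derivatives(m2, "x_1", 4, traj=ref2).items()}
    states = {s: ref2[s] for s in m2.states}
    with pytest.warns(UserWarning, match="skipped"):
        C = constraint_C(
            sys2, m2.param_dict(), measured, derivs, state_values=states, max_order=4
        )
    assert np.isfinite(C)


def test_constraint_monotone_in_kp_near_truth(m1, sys1, ref1):
    """On noiseless data, C_DE over a k_p grid (k_m at truth) attains its
    minimum at the generating k_p within one grid step."""
    spec = ObjectiveSpec(alpha=0.1, et_threshold=0.01)
    ev = ObjectiveEvaluator(m1, ref1.subset(["x_AB"]).with_role("measured"), spec, system=sys1)
    kp_grid = np.linspace(0.01, 0.1, 101)
    P = np.column_stack([kp_grid, np.full(kp_grid.size, 0.5)])
    C = ev.evaluate(P)["C"]
    best = kp_grid[np.argmin(C)]
    assert abs(best - 0.05) <= (kp_grid[1] - kp_grid[0]) + 1e-12


# -- evaluator ------------------------------------------------------------


def test_evaluator_alpha_zero_is_pure_error(m1, ref1):
    measured = ref1.subset(["x_AB"]).with_role("measured")
    ev = ObjectiveEvaluator(m1, measured, ObjectiveSpec(alpha=0.0))
    out = ev.evaluate(np.array([[0.07, 0.5]]))
    assert out["OF"][0] == pytest.approx(out["E"][0])
    assert out["C"][0] == 0.0


def test_evaluator_batch_matches_accurate_path(m1, sys1, ref1):
    measured = ref1.subset(["x_AB"]).with_role("measured")
    ev = ObjectiveEvaluator(m1, measured, ObjectiveSpec(alpha=0.1), system=sys1)
    p = np.array([0.06, 0.7])
    out = ev.evaluate(p[None, :])
    E_acc, C_acc = ev.accurate(p)
    assert out["E"][0] == pytest.approx(E_acc, rel=1e-4)
    assert out["C"][0] == pytest.approx(C_acc, rel=1e-3)


def test_evaluator_flags_divergent_candidates(m1, ref1):
    from defit.objective import BAD_OBJECTIVE
    from defit.models import ODEModel

    blow = ODEModel(
        name="blow",
        states=("x",),
        params=("k",),
        rhs={"x": "k*x**2"},
        init={"x": 1.0},
        observed=("x",),
        ranking=("x",),
        bounds={"k": (0.0, 100.0)},
    )
    t = np.linspace(0.01, 0.95, 50)
    measured = Trajectory(times=t, values={"x": 1.0 / (1.0 - t)}, role="measured")
    ev = ObjectiveEvaluator(blow, measured, ObjectiveSpec(alpha=0.0))
    out = ev.evaluate(np.array([[0.5], [80.0]]))
    assert out["OF"][1] == BAD_OBJECTIVE
    assert np.isfinite(out["OF"][0]) and out["OF"][0] < BAD_OBJECTIVE


def test_pareto_scan_prefers_error_at_alpha_zero(m1, sys1, ref1):
    """In a tiny alpha scan, the alpha = 0 row attains the smallest
    median E (it optimises E alone)."""
    from defit.objective import pareto_alpha_scan
    from defit.optimizers import OptimizerConfig

    measured = ref1.subset(["x_AB"]).with_role("measured")
    cfg = OptimizerConfig(
        population=30, max_generations=60, polish=True, restart_generations=None
    )
    table, suggested = pareto_alpha_scan(
        m1, sys1, measured, [0.0, 1.0], optimizer_config=cfg, trials_per_alpha=3, seed=3
    )
    assert table.loc[table["alpha"] == 0.0, "median_E"].iloc[0] == table["median_E"].min()
    assert 0.0 <= suggested <= 1.0


def test_pareto_scan_single_point_grid(m1, sys1, ref1):
    from defit.objective import pareto_alpha_scan
    from defit.optimizers import OptimizerConfig

    measured = ref1.subset(["x_AB"]).with_role("measured")
    cfg = OptimizerConfig(
        population=10, max_generations=10, polish=False, restart_generations=None
    )
    table, suggested = pareto_alpha_scan(
        m1, sys1, measured, [0.3], optimizer_config=cfg, trials_per_alpha=1, seed=1
    )
    assert suggested == 0.3
    assert len(table) == 1
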