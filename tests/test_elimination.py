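"""Differential elimination: structure, soundness, and serialization.

The central oracle: every equation of the eliminated system, evaluated
along an exact trajectory with exact Lie-derivative inputs at the
generating parameters, vanishes (to cancellation-aware tolerance).
"""

import numpy as np
import pytest
import sympy as sp

from defit.elimination import (
    EliminationError,
    deriv_symbol,
    eliminate,
    equation_order,
    evaluate_equations,
    get_system,
    lie_derivatives,
    lie_exprs,
    load_fixture,
    parse_system,
    serialize_system,
    solve_states,
)
from defit.models import ODEModel
from defit.simulate import simulate


def _max_relative_residual(model, sys, params):
    traj = simulate(model, params, rtol=1e-12, atol=1e-12)
    y = model.observed[0]
    order = max(sys.equation_orders())
    derivs = {(y, k): v for k, v in lie_derivatives(model, y, order, params, traj).items()}
    res = evaluate_equations(
        sys,
        model.param_dict(params),
        {y: traj[y]},
        derivs,
        state_values={s: traj[s] for s in model.states},
        relative=True,
    )
    return max(np.max(np.abs(r)) for r in res)


# -- structure ------------------------------------------------------------


def test_equation_counts(sys1, sys2, sysb):
    """The equivalent system has 2 members for the binding model and 5
    for the cascade (one per unmeasured state plus the input-output
    member)."""
    assert sys1.L == 2
    assert sys2.L == 5
    assert sysb.L == 2


def test_input_output_member_is_free_of_unmeasured_states(all_models):
    for m in all_models:
        sys = get_system(m)
        io = sys.io_equation
        assert not ({s.name for s in io.free_symbols} & set(m.unobserved))


def test_model1_io_equation_matches_conservation_reduction(m1, sys1):
    """IO member equals dx_AB/dt - k_p(A0+AB0-x_AB)(B0+AB0-x_AB) + k_m x_AB
    up to a nonzero constant factor."""
    x = sp.Symbol("x_AB")
    kp, km = sp.symbols("k_p k_m")
    expected = deriv_symbol("x_AB", 1) - kp * (10 - x) * (20 - x) + km * x
    ratio = sp.simplify(sys1.io_equation / expected)
    assert ratio.is_number and ratio != 0


def test_model1_second_member_expresses_x_A(sys1):
    idx = sys1.leaders.index("x_A")
    eq = sys1.equations[idx]
    sol = sp.solve(eq, sp.Symbol("x_A"))
    assert len(sol) == 1
    assert sp.simplify(sol[0] - (10 - sp.Symbol("x_AB"))) == 0


def test_compartment_example_io_structure(sysb, mb):
    """Input-output member of the two-compartment example contains x_1,
    its first and second derivatives, and the four parameters only."""
    io = sysb.io_equation
    names = {s.name for s in io.free_symbols}
    assert "x_2" not in names
    assert {"x_1", "x_1__d1", "x_1__d2"} <= names
    assert names <= {"x_1", "x_1__d1", "x_1__d2", *mb.params}
    assert equation_order(io, "x_1") == 2
    # x_2 is recoverable from x_1, its first derivative, and parameters
    sol = sysb.state_solutions["x_2"]
    assert equation_order(sol, "x_1") == 1


def test_unmeasured_leaders_are_linearly_solvable(sys2):
    """Every non-IO member is linear in its leader state."""
    for eq, lead in zip(sys2.equations, sys2.leaders):
        if lead is None:
            continue
        assert sp.degree(sp.Poly(eq, sp.Symbol(lead))) == 1


# -- soundness (the central oracle) --------------------------------------


@pytest.mark.parametrize("model_name", ["model1", "model2", "boulier_example"])
def test_soundness_on_random_parameter_draws(model_name, all_models, rng):
    """Equations vanish on exact trajectories for random in-bounds draws."""
    model = {m.name: m for m in all_models}[model_name]
    sys = get_system(model)
    b = model.bounds_array
    worst = 0.0
    for _ in range(5):
        p = rng.uniform(b[:, 0] + 0.05 * (b[:, 1] - b[:, 0]), b[:, 1])
        worst = max(worst, _max_relative_residual(model, sys, p))
    assert worst < 1e-6


def test_perturbed_parameters_break_the_io_equation(m1, sys1, ref1):
    """Evaluating at 1.5*k_p on data from k_p raises the residual by >100x."""
    y = "x_AB"
    derivs = {(y, 1): lie_derivatives(m1, y, 1, traj=ref1)[1]}
    data = {y: ref1[y]}
    states = {s: ref1[s] for s in m1.states}
    true_res = evaluate_equations(sys1, m1.param_dict(), data, derivs, state_values=states)
    bad = m1.param_dict()
    bad["k_p"] *= 1.5
    bad_res = evaluate_equations(sys1, bad, data, derivs, state_values=states)
    io = sys1.leaders.index(None)
    assert np.max(np.abs(bad_res[io])) > 100 * max(np.max(np.abs(true_res[io])), 1e-12)


def test_solved_states_match_simulated_states(m2, sys2, ref2):
    """The recorded resolutions reproduce each unmeasured state from the
    observed series and its exact derivatives."""
    y = "x_1"
    derivs = {(y, k): v for k, v in lie_derivatives(m2, y, 4, traj=ref2).items()}
    solved = solve_states(sys2, m2.param_dict(), {y: ref2[y]}, derivs)
    for s in m2.unobserved:
        scale = np.max(np.abs(ref2[s])) or 1.0
        assert np.max(np.abs(solved[s] - ref2[s])) / scale < 1e-8


# -- Lie derivatives ------------------------------------------------------


def test_lie_derivative_at_t0_hand_value(m1):
    """d(x_AB)/dt at t=0 equals k_p*10*20 - k_m*0 = 10."""
    times = np.concatenate(([0.0], m1.default_times()))
    traj = simulate(m1, times=times)
    d1 = lie_derivatives(m1, "x_AB", 1, traj=traj)[1]
    assert d1[0] == pytest.approx(10.0, abs=1e-8)


def test_lie_derivatives_match_finite_differences(mb, refb):
    d = lie_derivatives(mb, "x_1", 2, traj=refb)
    y = refb["x_1"]
    h = refb.times[1] - refb.times[0]
    fd1 = (y[2:] - y[:-2]) / (2 * h)
    assert np.max(np.abs(fd1 - d[1][1:-1])) < 50 * h**2 * np.max(np.abs(d[2]))


def test_zero_dynamics_has_zero_derivatives():
    m = ODEModel(
        name="frozen",
        states=("x",),
        params=("k",),
        rhs={"x": "0*k"},
        init={"x": 2.0},
        observed=("x",),
        ranking=("x",),
        bounds={"k": (0.0, 1.0)},
    )
    traj = simulate(m, {"k": 0.5}, np.linspace(0.01, 1, 20))
    d = lie_derivatives(m, "x", 3, {"k": 0.5}, traj)
    for k in (1, 2, 3):
        assert np.allclose(d[k], 0.0)


# -- serialization --------------------------------------------------------


def test_serialize_parse_round_trip(sys1, sysb):
    for sys in (sys1, sysb):
        text = serialize_system(sys)
        back = parse_system(text)
        assert back.L == sys.L
        assert back.leaders == sys.leaders
        for a, b in zip(back.equations, sys.equations):
            assert sp.simplify(a - b) == 0
        # determinism: serialize twice -> byte-identical
        assert serialize_system(back) == text


def test_fixtures_match_fresh_derivation(m1, mb):
    """Shipped eliminated-system fixtures equal a fresh derivation."""
    for m in (m1, mb):
        fresh = eliminate(m)
        assert serialize_system(load_fixture(m.name)) == serialize_system(fresh)


def test_parse_rejects_undeclared_derivative_order():
    text = (
        "model: t\nobserved: y\nranking: a,y\norder: y=1\n"
        "equation -: y__d2 + y\n"
    )
    with pytest.raises(ValueError, match="order"):
        parse_system(text)


def test_parse_rejects_malformed_expression():
    text = "model: t\nobserved: y\nranking: y\norder: y=1\nequation -: y +* 2\n"
    with pytest.raises(ValueError, match="cannot parse"):
        parse_system(text)


# -- error paths ----------------------------------------------------------


def test_multi_observed_not_supported(m1):
    from dataclasses import replace as dc_replace

    m = ODEModel(
        name="two_obs",
        states=m1.states,
        params=m1.params,
        rhs={s: str(m1.rhs_exprs()[s]) for s in m1.states},
        init=dict(m1.init),
        observed=("x_B", "x_AB"),
        ranking=("x_A", "x_B", "x_AB"),
        bounds=dict(m1.bounds),
    )
    with pytest.raises(EliminationError):
        eliminate(m)


def test_size_budget_exceeded_names_blocking_state(m2):
    with pytest.raises(EliminationError):
        eliminate(m2, size_budget=10)
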