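"""Model definitions, validation, simulation, and conservation laws."""

import numpy as np
import pytest
import sympy as sp

from defit.models import ODEModel, conserved_quantities, get_model, load_model
from defit.simulate import IntegrationError, simulate, simulate_batch


def test_bundled_models_load_and_validate(all_models):
    for m in all_models:
        assert m.observed and set(m.observed) <= set(m.states)
        assert sorted(m.ranking) == sorted(m.states)
        # observed ranked lowest
        assert set(m.ranking[-len(m.observed):]) == set(m.observed)
        for p in m.params:
            lo, hi = m.bounds[p]
            assert np.isfinite(lo) and np.isfinite(hi) and lo < hi


@pytest.mark.parametrize(
    "field,value,message",
    [
        ("observed", (), "observed"),
        ("observed", ("nope",), "declared states"),
        ("ranking", ("x_AB", "x_A", "x_B"), "ranked lowest"),
        ("bounds", {"k_p": (0.0, np.inf), "k_m": (0.0, 5.0)}, "finite"),
    ],
)
def test_invalid_model_definitions_rejected(m1, field, value, message):
    cfg = dict(
        name="bad",
        states=m1.states,
        params=m1.params,
        rhs={s: str(m1.rhs_exprs()[s]) for s in m1.states},
        init=dict(m1.init),
        observed=m1.observed,
        ranking=m1.ranking,
        bounds=dict(m1.bounds),
    )
    cfg[field] = value
    with pytest.raises(ValueError, match=message):
        ODEModel(**cfg)


def test_rhs_with_undeclared_symbol_rejected(m1):
    with pytest.raises(ValueError, match="undeclared"):
        ODEModel(
            name="bad",
            states=("x",),
            params=("k",),
            rhs={"x": "-k*x + q"},
            init={"x": 1.0},
            observed=("x",),
            ranking=("x",),
            bounds={"k": (0.0, 1.0)},
        )


def test_model_roundtrip_via_yaml(tmp_path, m1):
    import yaml

    path = tmp_path / "m.yaml"
    cfg = dict(
        name="copy",
        states=list(m1.states),
        params=list(m1.params),
        rhs={s: str(m1.rhs_exprs()[s]) for s in m1.states},
        init=dict(m1.init),
        observed=list(m1.observed),
        ranking=list(m1.ranking),
        bounds={p: list(m1.bounds[p]) for p in m1.params},
    )
    path.write_text(yaml.safe_dump(cfg))
    m = load_model(path)
    assert m.states == m1.states
    assert sp.simplify(m.rhs_exprs()["x_AB"] - m1.rhs_exprs()["x_AB"]) == 0


def test_get_model_unknown_name():
    with pytest.raises(KeyError, match="unknown model"):
        get_model("not_a_model")


# -- simulation -----------------------------------------------------------


def test_reference_initial_value_and_saturation(m1):
    """x_AB starts at 0 and rises monotonically toward binding saturation."""
    times = np.concatenate(([0.0], m1.default_times()))
    traj = simulate(m1, times=times)
    assert traj["x_AB"][0] == pytest.approx(0.0, abs=1e-12)
    assert np.all(np.diff(traj["x_AB"]) > 0)
    # equilibrium of A+B<->AB with k_p=0.05, k_m=0.5 lies below min(A0,B0)
    assert traj["x_AB"][-1] < 10.0


def test_zero_rates_freeze_the_state(m1):
    traj = simulate(m1, {"k_p": 0.0, "k_m": 0.0})
    for s in m1.states:
        assert np.allclose(traj[s], m1.init[s], atol=1e-12)


def test_simulation_matches_fixed_step_rk4_oracle(m1):
    """LSODA at rtol 1e-8 agrees with a tiny-step RK4 integration."""
    times = m1.default_times()
    p = np.array([0.05, 0.5])
    traj = simulate(m1, p, times)
    # independent fixed-step RK4 at dt = 1e-5
    f = lambda x: np.array(
        [
            -p[0] * x[0] * x[1] + p[1] * x[2],
            -p[0] * x[0] * x[1] + p[1] * x[2],
            p[0] * x[0] * x[1] - p[1] * x[2],
        ]
    )
    x = np.array([10.0, 20.0, 0.0])
    dt = 1e-5
    out = {}
    targets = {round(t, 8): i for i, t in enumerate(times)}
    t = 0.0
    for step in range(int(round(1.0 / dt))):
        k1 = f(x)
        k2 = f(x + 0.5 * dt * k1)
        k3 = f(x + 0.5 * dt * k2)
        k4 = f(x + dt * k3)
        x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = round(t + dt, 10)
        if round(t, 8) in targets:
            out[round(t, 8)] = x.copy()
    assert abs(out[1.0][2] - traj["x_AB"][-1]) < 1e-6


def test_simulation_grid_refinement_stable(m2):
    coarse = simulate(m2)
    t = m2.default_times()
    fine_t = np.sort(np.concatenate([t, t - 0.005]))
    fine = simulate(m2, times=fine_t)
    idx = np.searchsorted(fine_t, t)
    for s in m2.states:
        scale = np.max(np.abs(coarse[s])) or 1.0
        assert np.max(np.abs(fine[s][idx] - coarse[s])) / scale < 1e-6


def test_integration_failure_is_explicit():
    m = ODEModel(
        name="blowup",
        states=("x",),
        params=("k",),
        rhs={"x": "k*x**2"},
        init={"x": 1.0},
        observed=("x",),
        ranking=("x",),
        bounds={"k": (0.0, 100.0)},
    )
    with pytest.raises(IntegrationError) as err:
        simulate(m, {"k": 50.0}, np.linspace(0.01, 1.0, 100))
    assert err.value.params is not None


def test_batch_simulation_matches_reference(m2, ref2):
    states, ok = simulate_batch(m2, m2.param_vector()[None, :], m2.default_times(), substeps=2)
    assert ok.all()
    for i, s in enumerate(m2.states):
        scale = np.max(np.abs(ref2[s])) or 1.0
        assert np.max(np.abs(states[:, i, 0] - ref2[s])) / scale < 1e-5


def test_batch_simulation_flags_divergent_candidates(m1):
    P = np.array([[0.05, 0.5], [0.5, 5.0]])
    states, ok = simulate_batch(m1, P, m1.default_times(), substeps=2)
    assert ok[0]  # truth stays finite
    assert states.shape == (100, 3, 2)


# -- conservation laws ----------------------------------------------------


def test_model1_conservation_span(m1):
    """Mass balance: x_A + x_AB and x_B + x_AB are conserved."""
    basis = conserved_quantities(m1)
    assert len(basis) == 2
    xa, xb, xab = sp.symbols("x_A x_B x_AB")
    span = sp.Matrix([[e.coeff(v) for v in (xa, xb, xab)] for e in basis])
    for target in (sp.Matrix([[1, 0, 1]]), sp.Matrix([[0, 1, 1]])):
        aug = sp.Matrix.vstack(span, target)
        assert aug.rank() == span.rank()  # target in row span


def test_compartment_example_has_no_conservation(mb):
    assert conserved_quantities(mb) == []


def test_conserved_quantities_constant_along_trajectories(m1, ref1):
    for law in conserved_quantities(m1):
        fn = sp.lambdify([sp.Symbol(s) for s in m1.states], law)
        vals = fn(*[ref1[s] for s in m1.states])
        drift = np.max(np.abs(vals - vals[0])) / max(abs(vals[0]), 1.0)
        assert drift < 1e-6
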