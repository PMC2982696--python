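"""Optimizer smoke tests: convergence on analytic objectives,
determinism, bounds handling, campaign accounting."""

import numpy as np
import pytest

from defit.optimizers import (
    OptimizerConfig,
    modal_bin_center,
    run_ga,
    run_powell,
    run_pso,
    trial_seeds,
)

BOUNDS_1D = np.array([[0.0, 1.0]])
BOUNDS_3D = np.array([[-2.0, 2.0]] * 3)

FAST = dict(max_generations=60, restart_generations=None, polish=False)


def quadratic(p):
    return float((p[0] - 0.3) ** 2)


def sphere(p):
    return float(np.sum(np.asarray(p) ** 2))


def test_ga_minimises_a_parabola():
    cfg = OptimizerConfig(population=20, **FAST)
    hits = 0
    for s in range(40):
        r = run_ga(quadratic, BOUNDS_1D, cfg, seed=s)
        hits += abs(r.params_hat[0] - 0.3) < 0.01
    assert hits >= 38  # >= 95%


def test_ga_deterministic_given_seed():
    cfg = OptimizerConfig(population=20, max_generations=40)
    a = run_ga(quadratic, BOUNDS_1D, cfg, seed=11)
    b = run_ga(quadratic, BOUNDS_1D, cfg, seed=11)
    assert np.array_equal(a.params_hat, b.params_hat)
    assert a.objective_value == b.objective_value
    assert a.generations_used == b.generations_used


def test_ga_respects_bounds():
    cfg = OptimizerConfig(population=16, **FAST)
    r = run_ga(lambda p: float(-p[0]), BOUNDS_1D, cfg, seed=2)
    assert 0.0 <= r.params_hat[0] <= 1.0
    assert r.params_hat[0] > 0.99  # pushed to the active bound


def test_ga_survives_exploding_objective():
    def nasty(p):
        if p[0] > 0.5:
            return float("inf")
        return float((p[0] - 0.2) ** 2)

    cfg = OptimizerConfig(population=20, **FAST)
    r = run_ga(nasty, BOUNDS_1D, cfg, seed=0)
    assert abs(r.params_hat[0] - 0.2) < 0.05


def test_pso_minimises_sphere():
    cfg = OptimizerConfig(method="pso", swarm=25, max_generations=120,
                          restart_generations=None, polish=False)
    hits = 0
    for s in range(20):
        r = run_pso(sphere, BOUNDS_3D, cfg, seed=s)
        hits += sphere(r.params_hat) < 1e-3
    assert hits >= 19  # >= 95%


def test_pso_zero_coefficients_keep_swarm_stationary():
    """With zero inertia and zero cognitive/social pull the swarm never
    moves: the answer is the best initial particle."""
    cfg = OptimizerConfig(
        method="pso", swarm=12, max_generations=15, inertia=0.0,
        cognitive=0.0, social=0.0, restart_generations=None, polish=False,
    )
    rng = np.random.default_rng(7)
    X0 = rng.uniform(BOUNDS_3D[:, 0], BOUNDS_3D[:, 1], size=(12, 3))
    expected = X0[np.argmin([sphere(x) for x in X0])]
    r = run_pso(sphere, BOUNDS_3D, cfg, seed=7)
    assert np.allclose(r.params_hat, expected)


def test_pso_deterministic_given_seed():
    cfg = OptimizerConfig(method="pso", swarm=15, max_generations=30)
    a = run_pso(sphere, BOUNDS_3D, cfg, seed=5)
    b = run_pso(sphere, BOUNDS_3D, cfg, seed=5)
    assert np.array_equal(a.params_hat, b.params_hat)


def test_powell_finds_quadratic_minimum_exactly():
    cfg = OptimizerConfig(method="powell")
    r = run_powell(sphere, BOUNDS_3D, start=np.array([1.0, -1.0, 0.5]), config=cfg)
    assert sphere(r.params_hat) < 1e-8


def test_powell_rejects_nonfinite_start():
    def bad(p):
        return float("nan")

    with pytest.raises(ValueError, match="non-finite"):
        run_powell(bad, BOUNDS_1D, start=np.array([0.5]))


def test_powell_rejects_out_of_bounds_start():
    with pytest.raises(ValueError, match="outside"):
        run_powell(sphere, BOUNDS_1D, start=np.array([2.0]))


# -- bins and seeds -------------------------------------------------------


def test_modal_bin_center_convention():
    # bins are centered on multiples of the width: 5.0 covers [4.5, 5.5)
    assert modal_bin_center([4.6, 5.2, 5.4, 7.0], 1.0) == 5.0
    assert modal_bin_center([0.051, 0.049, 0.044], 0.01) == 0.05
    assert modal_bin_center([], 1.0) is None
    # ties resolve to the smallest center
    assert modal_bin_center([1.0, 2.0], 1.0) == 1.0


def test_trial_seeds_distinct_and_reproducible():
    a = trial_seeds(42, 50)
    b = trial_seeds(42, 50)
    assert a == b
    assert len(set(a)) == 50
    assert all(0 <= s < 2**31 for s in a)
    assert trial_seeds(43, 50) != a
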