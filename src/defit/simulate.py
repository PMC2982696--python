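"""Numerical integration of ODEModels.

Two paths are provided.  :func:`simulate` is the reference integrator
(adaptive LSODA at rtol 1e-8 / atol 1e-10) used for reference curves and
for final trial diagnostics.  :func:`simulate_batch` is a fixed-step
classic Runge-Kutta integrator vectorised over a whole population of
candidate parameter vectors; it is the optimizer inner-loop fast path
and its accuracy on the benchmark models is far below the success
thresholds (see docs/methods.md).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .models import ODEModel
from .trajectory import Trajectory

__all__ = [
    "IntegrationError",
    "simulate",
    "simulate_batch",
    "compile_rhs",
    "linear_system_matrix",
]


class IntegrationError(RuntimeError):
    """Raised when integration fails; carries the offending parameters."""

    def __init__(self, message: str, params=None):
        super().__init__(message)
        self.params = params


_RHS_CACHE: dict = {}


def compile_rhs(model: ODEModel):
    """Lambdified RHS ``f(state_rows, param_rows) -> list of d/dt rows``.

    Accepts scalars or broadcastable arrays, so a single call evaluates
    the vector field for a whole population of parameter vectors.
    """
    key = (model.name, id(model._rhs_exprs))
    fn = _RHS_CACHE.get(key)
    if fn is None:
        args = (*model.state_symbols, *model.param_symbols)
        exprs = [model._rhs_exprs[s] for s in model.states]
        fn = sp.lambdify(args, exprs, modules="numpy")
        _RHS_CACHE[key] = fn
    return fn


def simulate(
    model: ODEModel,
    params: Mapping[str, float] | Sequence[float] | None = None,
    times: np.ndarray | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model and sample all states at ``times``.

    Integration starts from t = 0 with the model's declared initial
    conditions; ``times`` (default: the model's reference grid) must be
    non-empty and strictly increasing.  Failure (stiffness, divergence,
    non-finite states) raises :class:`IntegrationError` carrying the
    offending parameter vector — never a silent NaN.
    """
    p = model.param_vector(params)
    if times is None:
        times = model.default_times()
    times = np.asarray(times, dtype=float)
    if times.size == 0 or (times.size > 1 and not np.all(np.diff(times) > 0)):
        raise ValueError("times must be non-empty and strictly increasing")
    fn = compile_rhs(model)

    def rhs(t, x):
        return np.asarray(fn(*x, *p), dtype=float)

    def blow_up(t, x):  # terminal guard against finite-time divergence
        with np.errstate(invalid="ignore"):
            return 1e12 - float(np.max(np.abs(x)))

    blow_up.terminal = True

    t0 = min(0.0, float(times[0]))
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        sol = solve_ivp(
            rhs,
            (t0, float(times[-1])),
            model.init_vector,
            t_eval=times,
            method=method,
            rtol=rtol,
            atol=atol,
            events=[blow_up],
        )
    if (
        not sol.success
        or sol.status != 0
        or sol.y.shape[1] != times.size
        or not np.all(np.isfinite(sol.y))
    ):
        raise IntegrationError(
            f"integration of {model.name!r} failed: {sol.message}", params=p
        )
    values = {s: sol.y[i] for i, s in enumerate(model.states)}
    return Trajectory(
        times=times,
        values=values,
        role="calculated",
        provenance={"model": model.name, "params": dict(zip(model.params, map(float, p)))},
    )


def linear_system_matrix(model: ODEModel) -> sp.Matrix | None:
    """System matrix J with x' = J x, or None if the model is not
    linear homogeneous in its states."""
    syms = list(model.state_symbols)
    rows = []
    for s in model.states:
        expr = sp.expand(model._rhs_exprs[s])
        row = []
        for t in syms:
            c = sp.expand(expr.coeff(t, 1))
            if c.free_symbols & set(syms):
                return None
            row.append(c)
        if sp.expand(expr - sum(c * t for c, t in zip(row, syms))) != 0:
            return None
        rows.append(row)
    return sp.Matrix(rows)


_LINEAR_CACHE: dict = {}


def _linear_stepper(model: ODEModel):
    """Lambdified J(params) for the linear fast path (None if nonlinear)."""
    key = (model.name, id(model._rhs_exprs))
    if key not in _LINEAR_CACHE:
        J = linear_system_matrix(model)
        if J is None:
            _LINEAR_CACHE[key] = None
        else:
            _LINEAR_CACHE[key] = sp.lambdify(model.param_symbols, J.tolist(), modules="numpy")
    return _LINEAR_CACHE[key]


def _simulate_batch_linear(model, P, times, substeps, Jfn):
    """Exact RK4-equivalent propagation for linear models: the RK4 step
    is the degree-4 Taylor matrix I + hJ + .. + (hJ)^4/24, applied as a
    per-candidate matrix power."""
    m = P.shape[0]
    n = len(model.states)
    raw = Jfn(*(P[:, j] for j in range(P.shape[1])))
    J = np.empty((m, n, n))
    for i in range(n):
        for j in range(n):
            J[:, i, j] = np.broadcast_to(np.asarray(raw[i][j], dtype=float), (m,))
    grid = np.concatenate(([0.0], times)) if times[0] > 0 else times
    dts = np.diff(grid)
    if not np.allclose(dts, dts[0], rtol=1e-9):
        return None  # non-uniform grid: fall back to the generic path
    h = dts[0] / substeps
    hJ = h * J
    with np.errstate(over="ignore", invalid="ignore"):
        step = np.broadcast_to(np.eye(n), (m, n, n)).copy()
        term = np.broadcast_to(np.eye(n), (m, n, n)).copy()
        for k in range(1, 5):
            term = np.einsum("mij,mjk->mik", term, hJ) / k
            step += term
        A = step
        for _ in range(substeps - 1):
            A = np.einsum("mij,mjk->mik", A, step)
        X = np.broadcast_to(model.init_vector, (m, n)).copy()
        out = np.empty((times.size, n, m))
        k_out = 0
        if times[0] == 0.0:
            out[0] = X.T
            k_out = 1
        for _ in range(len(dts)):
            X = np.einsum("mij,mj->mi", A, X)
            out[k_out] = X.T
            k_out += 1
    with np.errstate(invalid="ignore"):
        ok = np.all(np.isfinite(out) & (np.abs(out) < 1e12), axis=(0, 1))
    return out, ok


_STEP_CACHE: dict = {}


def _rk4_step_fn(model: ODEModel):
    """One full classic Runge-Kutta step compiled to a single vectorised
    call ``step(h, *states, *params) -> new states`` (CSE-shared stages)."""
    key = (model.name, id(model._rhs_exprs))
    fn = _STEP_CACHE.get(key)
    if fn is None:
        xs = list(model.state_symbols)
        ps = list(model.param_symbols)
        h = sp.Symbol("_h_")

        def f(vals):
            sub = dict(zip(xs, vals))
            return [model._rhs_exprs[s].xreplace(sub) for s in model.states]

        k1 = f(xs)
        k2 = f([x + h / 2 * k for x, k in zip(xs, k1)])
        k3 = f([x + h / 2 * k for x, k in zip(xs, k2)])
        k4 = f([x + h * k for x, k in zip(xs, k3)])
        step = [
            x + h / 6 * (a + 2 * b + 2 * c + d)
            for x, a, b, c, d in zip(xs, k1, k2, k3, k4)
        ]
        fn = sp.lambdify((h, *xs, *ps), step, modules="numpy", cse=True)
        _STEP_CACHE[key] = fn
    return fn


def simulate_batch(
    model: ODEModel,
    param_matrix: np.ndarray,
    times: np.ndarray,
    *,
    substeps: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step RK4 integration of many parameter vectors at once.

    Parameters
    ----------
    param_matrix : (m, n_params) array
        One candidate parameter vector per row.
    times : (T,) strictly increasing output grid.
    substeps : int
        RK4 steps per output interval (and from t = 0 to ``times[0]``).

    Returns
    -------
    states : (T, n_states, m) array of state values (NaN where diverged).
    ok : (m,) boolean mask of candidates that stayed finite and bounded.
    """
    P = np.atleast_2d(np.asarray(param_matrix, dtype=float))
    m = P.shape[0]
    times = np.asarray(times, dtype=float)
    Jfn = _linear_stepper(model)
    if Jfn is not None:
        res = _simulate_batch_linear(model, P, times, substeps, Jfn)
        if res is not None:
            return res
    step = _rk4_step_fn(model)
    n_states = len(model.states)
    grid0 = np.concatenate(([0.0], times)) if times[0] > 0 else times
    if m == 1:
        # single candidate: plain-float stepping avoids numpy small-array
        # overhead (the local-refinement loop lives here)
        pvals = [float(v) for v in P[0]]
        xs = [float(v) for v in model.init_vector]
        out = np.empty((times.size, n_states, 1))
        ti = grid0[0]
        k_out = 0
        if times[0] == ti:
            out[0, :, 0] = xs
            k_out = 1
        ok_flag = True
        try:
            for t_next in grid0[1:]:
                h = (t_next - ti) / substeps
                for _ in range(substeps):
                    xs = step(h, *xs, *pvals)
                ti = t_next
                out[k_out, :, 0] = xs
                k_out += 1
        except (ZeroDivisionError, OverflowError, ValueError):
            out[k_out:] = np.nan
            ok_flag = False
        with np.errstate(invalid="ignore"):
            ok = np.array([ok_flag and bool(np.all(np.isfinite(out) & (np.abs(out) < 1e12)))])
        return out, ok

    pcols = [P[:, j] for j in range(P.shape[1])]
    X = [np.broadcast_to(model.init_vector[i], (m,)).copy() for i in range(n_states)]
    out = np.empty((times.size, n_states, m))
    grid = np.concatenate(([0.0], times)) if times[0] > 0 else times
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        ti = grid[0]
        k_out = 0
        if times[0] == ti:
            out[0] = np.stack(X)
            k_out = 1
        for t_next in grid[1:]:
            h = (t_next - ti) / substeps
            for _ in range(substeps):
                X = [
                    np.broadcast_to(np.asarray(row, dtype=float), (m,))
                    for row in step(h, *X, *pcols)
                ]
            ti = t_next
            out[k_out] = np.stack(X)
            k_out += 1
    with np.errstate(invalid="ignore"):
        ok = np.all(np.isfinite(out) & (np.abs(out) < 1e12), axis=(0, 1))
    return out, ok
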