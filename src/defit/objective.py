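"""Objective function: relative error E, constraint penalty C_DE, and OF.

The fitting objective combines the classic sum of absolute relative
errors between the candidate simulation and the measured series,

    E = sum_i sum_t |x^c_{i,t} - x^m_{i,t}| / |x^m_{i,t}|,

with the differential-elimination constraint penalty

    C_DE = sum_{l=1..L} sum_{t=1..T} |C_{l,t}|,

the absolute residuals of the eliminated system's equations evaluated
at the candidate parameters on the measured series and its estimated
derivatives.  They are blended as OF = (1 - alpha) * E + alpha * C_DE.
At the generating parameters every constraint residual vanishes, so the
penalty carries cost-free information about the curve's *shape* (its
derivatives), which is what rescues parameters that E alone cannot pin
down when most states are unmeasured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import sympy as sp

from .derivatives import DerivativeSettings, estimate_derivatives
from .elimination import (
    EliminatedSystem,
    _DERIV_RE,
    equation_order,
    get_system,
    solve_states,
)
from .models import ODEModel
from .simulate import simulate, simulate_batch
from .trajectory import Trajectory

__all__ = [
    "ObjectiveSpec",
    "error_E",
    "constraint_C",
    "objective_OF",
    "ObjectiveEvaluator",
    "pareto_alpha_scan",
    "BAD_OBJECTIVE",
]

#: objective value assigned to candidates whose simulation diverges
BAD_OBJECTIVE = 1e15


@dataclass(frozen=True)
class ObjectiveSpec:
    """Weighting and evaluation settings for the combined objective.

    alpha : float in [0, 1]
        Constraint weight; 0 recovers the standard relative-error fit.
    et_threshold : float
        Success criterion on the per-time-point error E/T.
    constraint_normalization : "raw_sum", "per_equation_scaled", or "pareto_balanced"
        raw_sum adds absolute residuals with unit weights;
        per_equation_scaled divides each equation's contribution by its
        residual range over a reference sample of in-bounds parameters
        (useful when equations differ by orders of magnitude);
        pareto_balanced additionally rescales the penalty so that, at
        the study's alpha, alpha*C_DE and (1-alpha)*E carry comparable
        weight at near-optimal fits — the same trade-off calibration the
        weight itself is chosen by (see docs/methods.md).
    epsilon_rel : float
        Guard for near-zero measured denominators in E.
    derivative_settings : DerivativeSettings
        Data-side derivative estimator for the constraint equations.
    """

    alpha: float = 0.0
    et_threshold: float = 0.01
    constraint_normalization: str = "raw_sum"
    epsilon_rel: float = 1e-12
    derivative_settings: DerivativeSettings = field(default_factory=DerivativeSettings)

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.et_threshold <= 0:
            raise ValueError("et_threshold must be positive")
        if self.constraint_normalization not in (
            "raw_sum",
            "per_equation_scaled",
            "pareto_balanced",
        ):
            raise ValueError(
                f"unknown constraint normalization {self.constraint_normalization!r}"
            )


def error_E(
    calculated: Trajectory,
    measured: Trajectory,
    observed=None,
    epsilon_rel: float = 1e-12,
) -> float:
    """Total relative error E between a candidate and the measured data.

    Sums ``|x^c - x^m| / max(|x^m|, epsilon_rel)`` over the observed
    variables and all shared time points.  Both trajectories must be on
    the same grid.
    """
    if len(calculated) != len(measured) or not np.allclose(
        calculated.times, measured.times, rtol=0, atol=1e-12
    ):
        raise ValueError("trajectories are not on the same time grid")
    if observed is None:
        observed = [v for v in measured.variables if v in calculated.variables]
    total = 0.0
    for var in observed:
        xc, xm = calculated[var], measured[var]
        total += float(np.sum(np.abs(xc - xm) / np.maximum(np.abs(xm), epsilon_rel)))
    return total


def objective_OF(E: float, C: float, alpha: float) -> float:
    """Combined objective OF = (1 - alpha) * E + alpha * C."""
    return (1.0 - alpha) * E + alpha * C


def constraint_C(
    sys: EliminatedSystem,
    params: Mapping[str, float],
    measured: Trajectory,
    derivs: Mapping[tuple[str, int], np.ndarray],
    normalization: str = "raw_sum",
    *,
    state_values: Mapping[str, np.ndarray] | None = None,
    max_order: int | None = None,
    scales=None,
) -> float:
    """Constraint penalty C_DE at the given candidate parameters.

    ``state_values`` supplies the residual unmeasured states (normally
    the candidate-simulated trajectory); when omitted they are resolved
    from the recorded elimination expressions.  Equations requiring
    derivative orders above ``max_order`` are skipped with a warning.
    With ``normalization='per_equation_scaled'``, ``scales`` (one value
    per equation; skipped members ignored) must be supplied.
    """
    from .elimination import _symbol_value

    data = {v: measured[v] for v in sys.observed}
    yname = sys.observed[0]
    use_member_form = state_values is not None
    if state_values is None:
        state_values = solve_states(sys, params, data, derivs)
    total = 0.0
    for l, eq in enumerate(sys.equations):
        expr = sys.member_constraint_expr(l) if use_member_form else eq
        order = equation_order(expr, yname)
        if max_order is not None and order > max_order:
            warnings.warn(
                f"constraint equation {l} needs derivative order {order} > "
                f"max_order {max_order}; skipped",
                stacklevel=2,
            )
            continue
        syms = sorted(expr.free_symbols, key=lambda s: s.name)
        vals = [_symbol_value(s, params, data, derivs, state_values) for s in syms]
        fn = sp.lambdify(syms, expr, modules="numpy")
        with np.errstate(all="ignore"):
            res = np.asarray(fn(*vals), dtype=float)
        contrib = float(np.sum(np.abs(res)))
        if normalization in ("per_equation_scaled", "pareto_balanced"):
            if scales is None:
                raise ValueError(f"{normalization} requires precomputed scales")
            contrib /= max(float(scales[l]), 1e-300)
        total += contrib
    return total


class ObjectiveEvaluator:
    """Compiled, population-batched evaluator of E, C_DE, and OF.

    Precomputes data-side derivative estimates and lambdified constraint
    residual functions once, then evaluates whole candidate populations
    with a single vectorised RK4 simulation per generation.  Candidates
    whose simulation diverges receive :data:`BAD_OBJECTIVE`.
    """

    def __init__(
        self,
        model: ODEModel,
        measured: Trajectory,
        spec: ObjectiveSpec,
        system: EliminatedSystem | None = None,
        *,
        substeps: int = 2,
    ):
        if len(model.observed) != 1:
            raise NotImplementedError("evaluator supports one observed variable")
        self.model = model
        self.spec = spec
        self.substeps = substeps
        self.yname = model.observed[0]
        self.times = measured.times
        self.T = len(measured)
        self.measured = measured
        self.ydata = measured[self.yname]
        self._ycol = self.ydata[:, None]
        self._denom = np.maximum(np.abs(self._ycol), spec.epsilon_rel)
        self._iy = model.states.index(self.yname)
        self.system = None
        self._eqs = []
        self.scales = None
        if spec.alpha > 0.0:
            self.system = system if system is not None else get_system(model)
            self.derivs = estimate_derivatives(
                measured, spec.derivative_settings, variables=[self.yname]
            )
            self._compile_equations()
            if spec.constraint_normalization in ("per_equation_scaled", "pareto_balanced"):
                self.scales = self._reference_scales()
            if spec.constraint_normalization == "pareto_balanced":
                self.scales = self.scales * self._balance_factor()

    # -- compilation -----------------------------------------------------

    def _compile_equations(self):
        """Collect each polynomial equation as sum_j c_j(params) * b_j(data, states).

        The data factor of every monomial is precomputed once on the
        grid; evaluation per generation reduces to a handful of
        coefficient evaluations and (T, m) outer products.
        """
        settings = self.spec.derivative_settings
        skipped = []
        for l in range(self.system.L):
            expr = self.system.member_constraint_expr(l)
            order = equation_order(expr, self.yname)
            if order > settings.max_order:
                skipped.append((l, order))
                continue
            num, den = sp.fraction(sp.together(expr))
            terms = self._collect_terms(sp.expand(num))
            den = sp.expand(den)
            den_terms = self._collect_terms(den) if den != 1 else None
            self._eqs.append((l, terms, den_terms))
        if skipped:
            warnings.warn(
                f"constraint equations {[l for l, _ in skipped]} need derivative "
                f"orders {[o for _, o in skipped]} > max_order "
                f"{settings.max_order}; they are not evaluated on data",
                stacklevel=3,
            )

    def _collect_terms(self, expr: sp.Expr):
        """Decompose a polynomial expression into
        ``(param_coeff_fn, data_column, state_factors)`` triples."""
        non_param = sorted(
            (s for s in expr.free_symbols if s.name not in self.model.params),
            key=lambda s: s.name,
        )
        param_syms = list(self.model.param_symbols)
        poly_terms = sp.Poly(expr, *non_param).terms() if non_param else [((), expr)]
        terms = []
        for monom, coeff in poly_terms:
            cfn = (
                sp.lambdify(param_syms, coeff, modules="numpy")
                if coeff.free_symbols
                else float(coeff)
            )
            data_vec = np.ones(self.T)
            state_factors = []
            for s, e in zip(non_param, monom):
                if e == 0:
                    continue
                mder = _DERIV_RE.match(s.name)
                if mder:
                    data_vec = data_vec * self.derivs[(mder.group(1), int(mder.group(2)))] ** e
                elif s.name == self.yname:
                    data_vec = data_vec * self.ydata**e
                elif s.name in self.model.states:
                    state_factors.append((self.model.states.index(s.name), int(e)))
                else:
                    raise ValueError(f"equation symbol {s.name} is not recognised")
            terms.append((cfn, data_vec[:, None], tuple(state_factors)))
        return terms

    def _term_sum(self, tt, states, pcols) -> np.ndarray:
        res = 0.0
        for cfn, data_col, state_factors in tt:
            c = cfn if isinstance(cfn, float) else np.asarray(cfn(*pcols), dtype=float)[None, :]
            t = c * data_col
            for idx, e in state_factors:
                t = t * (states[:, idx, :] if e == 1 else states[:, idx, :] ** e)
            res = res + t
        return np.asarray(res)

    def _eq_residual(self, terms, lead_terms, states: np.ndarray, pcols) -> np.ndarray:
        """(T, m) residual of one compiled equation, monic in its leader."""
        res = self._term_sum(terms, states, pcols)
        if lead_terms is not None:
            res = res / self._term_sum(lead_terms, states, pcols)
        return res

    def _balance_factor(self, n_probes: int = 6, seed: int = 421_793) -> float:
        """Scale multiplier aligning alpha*C_DE with (1-alpha)*E at fits.

        Runs a few short seeded error-only optimisations to obtain
        near-optimal parameter sets, then returns the factor that makes
        the weighted penalty comparable to the weighted error there, so
        the printed alpha realises the Pareto trade-off it encodes
        rather than being distorted by the arbitrary units of the
        constraint residuals.
        """
        from dataclasses import replace as dc_replace

        from .optimizers import OptimizerConfig, run_ga, trial_seeds

        if self.spec.alpha >= 1.0:
            return 1.0
        probe_spec = dc_replace(self.spec, alpha=0.0)
        probe_ev = ObjectiveEvaluator(
            self.model, self.measured, probe_spec, substeps=self.substeps
        )
        cfg = OptimizerConfig(population=30, max_generations=150, trials=n_probes)
        E_vals, C_vals = [], []
        for s in trial_seeds(seed, n_probes):
            r = run_ga(probe_ev, self.model.bounds_array, cfg, seed=s)
            out = self.evaluate(r.params_hat[None, :])
            if not out["bad"][0]:
                E_vals.append(out["E"][0])
                C_vals.append(out["C"][0])
        if not E_vals:
            return 1.0
        want = (1.0 - self.spec.alpha) * float(np.median(E_vals))
        have = self.spec.alpha * float(np.median(C_vals))
        if want <= 0 or have <= 0:
            return 1.0
        return have / want

    def _reference_scales(self, n_samples: int = 32, seed: int = 932_145) -> np.ndarray:
        """Residual range of each equation over a fixed in-bounds sample."""
        rng = np.random.default_rng(seed)
        b = self.model.bounds_array
        P = rng.uniform(b[:, 0], b[:, 1], size=(n_samples, b.shape[0]))
        states, ok = simulate_batch(self.model, P, self.times, substeps=self.substeps)
        pcols = [P[:, j] for j in range(P.shape[1])]
        scales = np.ones(self.system.L)
        for l, terms, lead_terms in self._eqs:
            with np.errstate(all="ignore"):
                res = self._eq_residual(terms, lead_terms, states, pcols)
            sums = np.sum(np.abs(res), axis=0)
            sums = sums[ok & np.isfinite(sums)]
            if sums.size:
                rng_l = float(np.max(sums) - np.min(sums))
                scales[l] = rng_l if rng_l > 0 else max(float(np.max(sums)), 1.0)
        return scales

    # -- evaluation ------------------------------------------------------

    def evaluate(self, P: np.ndarray) -> dict[str, np.ndarray]:
        """E, C, OF and E/T for a (m, n_params) candidate matrix."""
        P = np.atleast_2d(np.asarray(P, dtype=float))
        m = P.shape[0]
        states, ok = simulate_batch(self.model, P, self.times, substeps=self.substeps)
        with np.errstate(all="ignore"):
            sim_y = states[:, self._iy, :]
            E = np.sum(np.abs(sim_y - self._ycol) / self._denom, axis=0)
            C = np.zeros(m)
            if self.spec.alpha > 0.0:
                pcols = [P[:, j] for j in range(P.shape[1])]
                for l, terms, lead_terms in self._eqs:
                    res = self._eq_residual(terms, lead_terms, states, pcols)
                    contrib = np.sum(np.abs(res), axis=0)
                    if self.scales is not None:
                        contrib = contrib / max(float(self.scales[l]), 1e-300)
                    C += contrib
        bad = ~ok | ~np.isfinite(E) | ~np.isfinite(C)
        E = np.where(bad, BAD_OBJECTIVE, E)
        C = np.where(bad, BAD_OBJECTIVE, C)
        OF = (1.0 - self.spec.alpha) * E + self.spec.alpha * C
        OF = np.where(bad, BAD_OBJECTIVE, OF)
        return {"E": E, "C": C, "OF": OF, "ET": E / self.T, "bad": bad}

    def __call__(self, p) -> float:
        """Scalar OF for a single parameter vector."""
        return float(self.evaluate(np.atleast_2d(p))["OF"][0])

    def accurate(self, p) -> tuple[float, float]:
        """(E, C_DE) at ``p`` using the adaptive reference integrator."""
        from .simulate import IntegrationError

        try:
            traj = simulate(self.model, p, self.times)
        except IntegrationError:
            return BAD_OBJECTIVE, BAD_OBJECTIVE
        E = error_E(
            traj, self.measured, observed=self.model.observed, epsilon_rel=self.spec.epsilon_rel
        )
        C = 0.0
        if self.spec.alpha > 0.0:
            params = self.model.param_dict(p)
            state_values = {s: traj[s] for s in self.model.states}
            C = constraint_C(
                self.system,
                params,
                self.measured,
                self.derivs,
                normalization=self.spec.constraint_normalization,
                state_values=state_values,
                max_order=self.spec.derivative_settings.max_order,
                scales=self.scales,
            )
        return E, C


def pareto_alpha_scan(
    model: ODEModel,
    sys: EliminatedSystem,
    measured: Trajectory,
    alpha_grid,
    optimizer_config=None,
    *,
    trials_per_alpha: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Advisory scan of the constraint weight over a grid of alphas.

    Runs a small budget of seeded optimizations per alpha and reports
    the medians of final E and C_DE; the suggested alpha is the knee of
    the (median E, median C) front — the point of maximum perpendicular
    distance from the chord joining the front's endpoints.  The final
    weight remains a manual choice.
    """
    from .optimizers import OptimizerConfig, run_ga

    alpha_grid = sorted(alpha_grid)
    if not alpha_grid:
        raise ValueError("alpha_grid must contain at least one value")
    config = optimizer_config or OptimizerConfig(
        population=30, max_generations=60, trials=trials_per_alpha
    )
    rows = []
    for alpha in alpha_grid:
        spec = ObjectiveSpec(
            alpha=alpha,
            et_threshold=model.et_threshold or 0.01,
            derivative_settings=DerivativeSettings(
                max_order=min(4, max(1, max(equation_order(eq, model.observed[0]) for eq in sys.equations)))
            ),
        )
        ev = ObjectiveEvaluator(model, measured, spec, system=sys)
        Es, Cs = [], []
        ss = np.random.SeedSequence([seed, int(alpha * 10_000_000)])
        for child in ss.spawn(trials_per_alpha):
            trial_seed = int(child.generate_state(1)[0] % (2**31))
            res = run_ga(ev, model.bounds_array, config, seed=trial_seed)
            if np.isfinite(res.final_E_over_T):
                Es.append(res.final_E_over_T * ev.T)
                Cs.append(res.final_C)
        rows.append(
            {
                "alpha": alpha,
                "median_E": float(np.median(Es)) if Es else np.nan,
                "median_C": float(np.median(Cs)) if Cs else np.nan,
                "n_ok": len(Es),
            }
        )
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["median_E", "median_C"])
    if len(valid) == 1:
        return table, float(valid["alpha"].iloc[0])
    if valid.empty:
        return table, float("nan")
    # knee by maximum perpendicular distance on the normalised front
    e = valid["median_E"].to_numpy()
    c = valid["median_C"].to_numpy()

    def _norm(v):
        rng = np.ptp(v)
        return (v - np.min(v)) / (rng if rng > 0 else 1.0)

    en, cn = _norm(e), _norm(c)
    p0 = np.array([en[0], cn[0]])
    p1 = np.array([en[-1], cn[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        idx = 0
    else:
        pts = np.stack([en, cn], axis=1) - p0
        dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
        idx = int(np.argmax(dist))
    return table, float(valid["alpha"].iloc[idx])
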