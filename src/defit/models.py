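"""Declarative ODE network models.

An :class:`ODEModel` is a small symbolic description of a kinetic network:
named states, named parameters, rational right-hand sides, initial
conditions, the set of observed (measurable) states, an elimination
ranking, and finite search bounds per parameter.  Models are defined in
YAML configuration files; three benchmark networks ship with the package
(``model1``, ``model2``, ``boulier_example``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import sympy as sp
import yaml

__all__ = [
    "ODEModel",
    "load_model",
    "get_model",
    "model1",
    "model2",
    "boulier_example",
    "conserved_quantities",
    "BUNDLED_MODELS",
]

BUNDLED_MODELS = ("model1", "model2", "boulier_example")


@dataclass(frozen=True)
class ODEModel:
    """Symbolic rational ODE system with named parameters and bounds.

    Parameters
    ----------
    name : str
        Identifier for the model.
    states : tuple of str
        Ordered state-variable names.
    params : tuple of str
        Ordered parameter names.
    rhs : mapping state -> str or sympy expression
        Right-hand side d(state)/dt as a rational expression in states
        and parameters.
    init : mapping state -> float
        Non-negative initial conditions (concentration units).
    observed : tuple of str
        Measurable subset of the states (non-empty).
    ranking : tuple of str
        Total order over the states used by differential elimination,
        highest (eliminated first) to lowest; observed states must be
        ranked lowest.
    bounds : mapping parameter -> (low, high)
        Finite search interval per parameter, ``low < high``.
    true_params : mapping parameter -> float, optional
        Reference values used to generate synthetic benchmark data.
    hist_bin_width : mapping parameter -> float, optional
        Histogram bin width per parameter for campaign summaries.
    time : mapping, optional
        Default sampling grid ``{start, stop, step}`` for reference data.
    et_threshold : float, optional
        Default success threshold on E/T for this model.
    alpha : float, optional
        Default constraint weight for this model.
    """

    name: str
    states: tuple[str, ...]
    params: tuple[str, ...]
    rhs: Mapping[str, object]
    init: Mapping[str, float]
    observed: tuple[str, ...]
    ranking: tuple[str, ...]
    bounds: Mapping[str, tuple[float, float]]
    true_params: Mapping[str, float] | None = None
    hist_bin_width: Mapping[str, float] | None = None
    time: Mapping[str, float] | None = None
    et_threshold: float | None = None
    alpha: float | None = None
    constraint_normalization: str | None = None
    _rhs_exprs: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        states = tuple(self.states)
        params = tuple(self.params)
        if set(states) & set(params):
            raise ValueError("state and parameter names overlap")
        syms = self.symbols()
        exprs = {}
        for s in states:
            if s not in self.rhs:
                raise ValueError(f"missing rhs for state {s!r}")
            expr = sp.sympify(self.rhs[s], locals=dict(syms))
            extra = expr.free_symbols - set(syms.values())
            if extra:
                raise ValueError(
                    f"rhs of {s!r} uses undeclared symbols: {sorted(map(str, extra))}"
                )
            exprs[s] = expr
        object.__setattr__(self, "_rhs_exprs", exprs)
        if not self.observed:
            raise ValueError("observed set is empty")
        if not set(self.observed) <= set(states):
            raise ValueError("observed variables must be declared states")
        if sorted(self.ranking) != sorted(states):
            raise ValueError("ranking must be a permutation of the states")
        n_obs = len(self.observed)
        if set(self.ranking[-n_obs:]) != set(self.observed):
            raise ValueError("observed states must be ranked lowest")
        for s in states:
            if s not in self.init:
                raise ValueError(f"missing initial condition for {s!r}")
            if self.init[s] < 0:
                raise ValueError(f"negative initial condition for {s!r}")
        for p in params:
            lo, hi = self.bounds[p]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {p!r} must be finite with low < high")

    # -- symbolic access -------------------------------------------------

    def symbols(self) -> dict[str, sp.Symbol]:
        """Name -> sympy symbol for every state and parameter."""
        return {n: sp.Symbol(n) for n in (*self.states, *self.params)}

    @property
    def state_symbols(self) -> tuple[sp.Symbol, ...]:
        return tuple(sp.Symbol(s) for s in self.states)

    @property
    def param_symbols(self) -> tuple[sp.Symbol, ...]:
        return tuple(sp.Symbol(p) for p in self.params)

    def rhs_exprs(self) -> dict[str, sp.Expr]:
        """State name -> sympy right-hand-side expression."""
        return dict(self._rhs_exprs)

    @property
    def unobserved(self) -> tuple[str, ...]:
        return tuple(s for s in self.ranking if s not in self.observed)

    # -- numeric helpers -------------------------------------------------

    @property
    def init_vector(self) -> np.ndarray:
        return np.array([float(self.init[s]) for s in self.states])

    def param_vector(self, params: Mapping[str, float] | Sequence[float] | None = None) -> np.ndarray:
        """Coerce a mapping/sequence (default: true_params) to bound order."""
        if params is None:
            if self.true_params is None:
                raise ValueError(f"model {self.name!r} has no reference parameter values")
            params = self.true_params
        if isinstance(params, Mapping):
            return np.array([float(params[p]) for p in self.params])
        arr = np.asarray(params, dtype=float)
        if arr.shape != (len(self.params),):
            raise ValueError(f"expected {len(self.params)} parameters, got shape {arr.shape}")
        return arr

    def param_dict(self, params=None) -> dict[str, float]:
        vec = self.param_vector(params)
        return dict(zip(self.params, vec))

    @property
    def bounds_array(self) -> np.ndarray:
        """(n_params, 2) array of search bounds in parameter order."""
        return np.array([self.bounds[p] for p in self.params], dtype=float)

    def default_times(self) -> np.ndarray:
        """The model's reference sampling grid (T points, t=0 excluded)."""
        t = self.time or {"start": 0.01, "stop": 1.0, "step": 0.01}
        step = float(t["step"])
        n = int(round((float(t["stop"]) - float(t["start"])) / step)) + 1
        return float(t["start"]) + step * np.arange(n)


def _as_model(cfg: Mapping, name: str | None = None) -> ODEModel:
    bounds = {p: (float(lo), float(hi)) for p, (lo, hi) in cfg["bounds"].items()}
    return ODEModel(
        name=cfg.get("name", name or "model"),
        states=tuple(cfg["states"]),
        params=tuple(cfg["params"]),
        rhs=dict(cfg["rhs"]),
        init={k: float(v) for k, v in cfg["init"].items()},
        observed=tuple(cfg["observed"]),
        ranking=tuple(cfg["ranking"]),
        bounds=bounds,
        true_params={k: float(v) for k, v in cfg["true_params"].items()}
        if cfg.get("true_params")
        else None,
        hist_bin_width={k: float(v) for k, v in cfg["hist_bin_width"].items()}
        if cfg.get("hist_bin_width")
        else None,
        time=cfg.get("time"),
        et_threshold=cfg.get("et_threshold"),
        alpha=cfg.get("alpha"),
        constraint_normalization=cfg.get("constraint_normalization"),
    )


def load_model(path: str | Path) -> ODEModel:
    """Load a model definition from a YAML configuration file."""
    path = Path(path)
    try:
        cfg = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"cannot parse model file {path}: {exc}") from exc
    if not isinstance(cfg, Mapping):
        raise ValueError(f"model file {path} does not contain a mapping")
    missing = {"states", "params", "rhs", "init", "observed", "ranking", "bounds"} - set(cfg)
    if missing:
        raise ValueError(f"model file {path} missing fields: {sorted(missing)}")
    return _as_model(cfg, name=path.stem)


def get_model(name: str) -> ODEModel:
    """Return a bundled model by name, or load ``name`` as a file path."""
    if name in BUNDLED_MODELS:
        ref = importlib.resources.files("defit") / "configs" / f"{name}.yaml"
        return _as_model(yaml.safe_load(ref.read_text()), name=name)
    path = Path(name)
    if path.exists():
        return load_model(path)
    raise KeyError(f"unknown model {name!r}; bundled models: {BUNDLED_MODELS}")


def model1() -> ODEModel:
    """Mass-action binding/dissociation A + B <-> AB; x_AB observed."""
    return get_model("model1")


def model2() -> ODEModel:
    """Linear pool-fed activation cascade; x_1 observed."""
    return get_model("model2")


def boulier_example() -> ODEModel:
    """Two-compartment exchange with Michaelis-Menten elimination; x_1 observed."""
    return get_model("boulier_example")


def conserved_quantities(model: ODEModel) -> list[sp.Expr]:
    """Linear combinations of states that are constant along trajectories.

    Finds the rational null space of ``c . f(x)`` over all state/parameter
    monomials, i.e. all ``c`` with ``d(c.x)/dt == 0`` identically.  Returns
    a basis of combinations with primitive integer coefficients (empty
    list if the model has no linear conservation law).
    """
    states = model.state_symbols
    f = [sp.together(model.rhs_exprs()[s]) for s in model.states]
    # clear each denominator separately would change the law; instead work on
    # the common polynomial numerator of c.f over the lcm denominator.
    c = sp.symbols(f"_c0:{len(states)}")
    total = sp.cancel(sp.together(sum(ci * fi for ci, fi in zip(c, f))))
    num, _den = sp.fraction(total)
    gens = (*states, *model.param_symbols)
    poly = sp.Poly(sp.expand(num), *gens)
    rows = []
    for coeff in poly.coeffs():
        # each monomial coefficient is linear homogeneous in c
        rows.append([sp.expand(coeff).coeff(ci) for ci in c])
    mat = sp.Matrix(rows)
    basis = mat.nullspace()
    out = []
    for vec in basis:
        denoms = [sp.fraction(sp.nsimplify(v))[1] for v in vec]
        scale = sp.lcm([sp.Integer(d) if d.is_Integer else 1 for d in denoms])
        ivec = [sp.nsimplify(v * scale) for v in vec]
        g = sp.gcd([v for v in ivec if v != 0])
        ivec = [sp.simplify(v / g) for v in ivec]
        if sum(1 for v in ivec if v != 0) and next(v for v in ivec if v != 0) < 0:
            ivec = [-v for v in ivec]
        out.append(sum(v * s for v, s in zip(ivec, states)))
    return out
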