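"""Differential elimination for small rational ODE systems.

Rewrites an :class:`~defit.models.ODEModel` into an equivalent system of
polynomial equations in the observed variable, its time derivatives
(symbols ``y__d1, y__d2, ...``), the parameters, and — one per equation —
a residual unmeasured state.  Unmeasured states are eliminated according
to the model ranking by (i) conservation-law reduction with known
initial conditions and (ii) prolongation of the observed variable's
equation by its Lie-derivative chain followed by algebraic elimination.

The equivalent system always contains one *input-output* equation free
of every unmeasured state; each remaining equation is linear in its
leader state, whose resolution in terms of the observed variable, its
derivatives and the parameters is recorded in ``state_solutions``.
Evaluated on an exact trajectory at the generating parameters, every
equation vanishes (the soundness oracle of the test suite).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import sympy as sp

from .models import ODEModel, conserved_quantities
from .trajectory import Trajectory

__all__ = [
    "EliminatedSystem",
    "EliminationError",
    "eliminate",
    "lie_exprs",
    "lie_derivatives",
    "deriv_symbol",
    "equation_order",
    "leader_coefficient",
    "serialize_system",
    "parse_system",
    "get_system",
    "load_fixture",
    "evaluate_equations",
    "solve_states",
]


class EliminationError(RuntimeError):
    """Elimination exceeded its budget or could not resolve a state."""

    def __init__(self, message: str, blocking_state: str | None = None):
        super().__init__(message)
        self.blocking_state = blocking_state


def leader_coefficient(eq: sp.Expr, leader: str | None, yname: str) -> sp.Expr:
    """Coefficient of an equation's leader (the residual state, or the
    highest observed derivative for the input-output member).

    Dividing an equation by this makes it monic in its leader, putting
    residuals on the scale of the leader quantity itself; the constraint
    penalty uses this normalisation so that shrinking an equation's
    overall parameter-dependent content cannot fake a small residual.
    """
    if leader is not None:
        c = sp.expand(eq.coeff(sp.Symbol(leader), 1))
    else:
        k = equation_order(eq, yname)
        c = sp.expand(eq.coeff(deriv_symbol(yname, k), 1)) if k else sp.Integer(1)
    return c if c != 0 else sp.Integer(1)


def deriv_symbol(var: str, order: int) -> sp.Symbol:
    """Symbol standing for the ``order``-th time derivative of ``var``."""
    return sp.Symbol(f"{var}__d{order}")


_DERIV_RE = re.compile(r"^(.*)__d(\d+)$")


def equation_order(expr: sp.Expr, var: str) -> int:
    """Highest derivative order of ``var`` appearing in ``expr``."""
    best = 0
    for s in expr.free_symbols:
        m = _DERIV_RE.match(s.name)
        if m and m.group(1) == var:
            best = max(best, int(m.group(2)))
    return best


@dataclass(frozen=True)
class EliminatedSystem:
    """Equivalent system produced by :func:`eliminate`.

    Attributes
    ----------
    equations : tuple of sympy expressions (implicitly ``= 0``)
        Ordered highest leader first, input-output equation last.
    leaders : tuple of str or None
        The residual unmeasured state of each equation (None for the
        input-output member).
    state_solutions : mapping state -> expression
        Resolution of every leader state in observed variables, their
        derivatives, and parameters.
    substitutions : mapping state -> expression
        Parameter-free conservation resolutions inlined during
        elimination (not counted as system members).
    max_derivative_order : mapping observed variable -> int
    """

    model_name: str
    observed: tuple[str, ...]
    ranking_used: tuple[str, ...]
    equations: tuple[sp.Expr, ...]
    leaders: tuple[str | None, ...]
    state_solutions: Mapping[str, sp.Expr]
    substitutions: Mapping[str, sp.Expr]
    max_derivative_order: Mapping[str, int]
    #: Lie-chain prolongation equations y__dk - L^k(y) (reduced states),
    #: one per prolongation-solved state, paired by `prolongation_leaders`.
    #: Each is an exact linear combination of the system members; the
    #: constraint penalty evaluates those members through this form,
    #: which is free of elimination determinants (see docs/methods.md).
    prolongations: tuple[sp.Expr, ...] = ()
    prolongation_leaders: tuple[str, ...] = ()

    @property
    def L(self) -> int:
        """Number of equations in the equivalent system."""
        return len(self.equations)

    @property
    def io_equation(self) -> sp.Expr:
        """The input-output member (no unmeasured states)."""
        for eq, lead in zip(self.equations, self.leaders):
            if lead is None:
                return eq
        raise ValueError("system has no input-output equation")

    def equation_orders(self) -> list[int]:
        """Max observed-derivative order used by each equation."""
        y = self.observed[0]
        return [equation_order(eq, y) for eq in self.equations]

    def member_constraint_expr(self, l: int) -> sp.Expr:
        """Expression through which member ``l`` enters the penalty C_DE.

        Members that resolve a prolongation-solved state are represented
        by their prolongation combination (smooth in the parameters);
        the input-output member is made monic in its highest derivative;
        conservation members are used as-is.  May be rational.
        """
        lead = self.leaders[l]
        if lead is not None and lead in self.prolongation_leaders:
            return self.prolongations[self.prolongation_leaders.index(lead)]
        eq = self.equations[l]
        c = leader_coefficient(eq, lead, self.observed[0])
        return eq / c if c != 1 else eq


def _normalize(expr: sp.Expr) -> sp.Expr:
    """Expand, strip rational content, and fix the overall sign."""
    expr = sp.expand(expr)
    syms = sorted(expr.free_symbols, key=lambda s: s.name)
    if not syms:
        return expr
    poly = sp.Poly(expr, *syms)
    _, prim = poly.primitive()
    out = prim.as_expr()
    lead = sp.Poly(out, *syms).coeffs()[0]
    if lead.is_number and lead < 0:
        out = sp.expand(-out)
    return out


def _exactify(value: float) -> sp.Expr:
    """Turn benign floats (initial conditions) into exact rationals."""
    return sp.nsimplify(value, rational=True)


def lie_exprs(
    model: ODEModel,
    variable: str,
    order: int,
    rhs_map: Mapping[str, sp.Expr] | None = None,
) -> list[sp.Expr]:
    """Symbolic Lie derivatives d^k(variable)/dt^k for k = 1..order.

    Each derivative is obtained by chained substitution of the right-hand
    sides: L^{k+1} = sum_s d(L^k)/ds * rhs(s).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    rhs = dict(rhs_map) if rhs_map is not None else model.rhs_exprs()
    out = []
    cur = sp.Symbol(variable)
    for _ in range(order):
        cur = sp.together(
            sum(sp.diff(cur, sp.Symbol(s)) * rhs[s] for s in rhs)
        )
        out.append(cur)
    return out


def lie_derivatives(
    model: ODEModel,
    variable: str,
    order: int,
    params=None,
    traj: Trajectory | None = None,
) -> dict[int, np.ndarray]:
    """Exact derivative vectors of ``variable`` along a simulated trajectory.

    The k-th derivative is the k-th Lie derivative evaluated at the
    trajectory's states — the oracle against which data-side numerical
    derivatives and eliminated equations are tested.
    """
    if traj is None:
        raise ValueError("a trajectory is required")
    p = model.param_vector(params)
    args = (*model.state_symbols, *model.param_symbols)
    key = ("lie", model.name, id(model._rhs_exprs), variable, order)
    fns = _LAMBDIFY_CACHE.get(key)
    if fns is None:
        exprs = lie_exprs(model, variable, order)
        fns = [sp.lambdify(args, expr, modules="numpy") for expr in exprs]
        _LAMBDIFY_CACHE[key] = fns
    state_arrays = [traj[s] for s in model.states]
    out = {}
    for k, fn in enumerate(fns, start=1):
        val = fn(*state_arrays, *p)
        out[k] = np.broadcast_to(np.asarray(val, dtype=float), traj.times.shape).copy()
    return out


def _linear_io_equation(
    rhs_map: Mapping[str, sp.Expr],
    states: list[str],
    yname: str,
    dsyms: list[sp.Symbol],
) -> sp.Expr | None:
    """Input-output equation for a linear homogeneous reduced system.

    When the reduced vector field is ``x' = J x`` with ``J`` free of the
    states, every trajectory of any state satisfies the system's
    characteristic ODE ``p(d/dt) x = 0``; applied to the observed
    variable this is the minimal input-output equation.  Returns None if
    the system is not linear homogeneous in its states.
    """
    syms = [sp.Symbol(s) for s in states]
    n = len(states)
    rows = []
    for s in states:
        expr = sp.expand(rhs_map[s])
        row = []
        for t in syms:
            c = sp.expand(expr.coeff(t, 1))
            if c.free_symbols & set(syms):
                return None
            row.append(c)
        rest = sp.expand(expr - sum(c * t for c, t in zip(row, syms)))
        if rest != 0:
            return None  # inhomogeneous or nonlinear
        rows.append(row)
    J = sp.Matrix(rows)
    lam = sp.Dummy("lambda")
    p = J.charpoly(lam)
    coeffs = p.all_coeffs()  # monic, degree n .. 0
    terms = []
    ysym = sp.Symbol(yname)
    for i, c in enumerate(coeffs):
        order = n - i
        var = ysym if order == 0 else dsyms[order - 1]
        terms.append(sp.expand(c) * var)
    return sp.expand(sum(terms))


def eliminate(
    model: ODEModel,
    *,
    known_ics: bool = True,
    size_budget: int = 200_000,
) -> EliminatedSystem:
    """Eliminate unmeasured states from ``model`` according to its ranking.

    Strategy: clear denominators to polynomial form; reduce dimension
    first with linear conservation laws (initial conditions of unmeasured
    states treated as known constants when ``known_ics``); prolong the
    observed variable by its Lie-derivative chain and solve the
    prolongation equations for the remaining unmeasured states; the next
    derivative with those resolutions substituted is the input-output
    equation.  Raises :class:`EliminationError` naming the blocking state
    if the resolution fails or expressions exceed ``size_budget`` ops.
    """
    if len(model.observed) != 1:
        raise EliminationError("only single-observed-variable models are supported")
    yname = model.observed[0]
    ysym = sp.Symbol(yname)
    ranking = list(model.ranking)
    unmeasured = [s for s in ranking if s not in model.observed]

    # -- conservation-law reduction --------------------------------------
    substitutions: dict[str, sp.Expr] = {}
    if known_ics:
        for law in conserved_quantities(model):
            law_red = sp.expand(law.subs({sp.Symbol(s): e for s, e in substitutions.items()}))
            const = _exactify(
                float(law.subs({sp.Symbol(s): model.init[s] for s in model.states}))
            )
            for s in ranking:  # highest first
                if s in model.observed or s in substitutions:
                    continue
                coeff = law_red.coeff(sp.Symbol(s))
                if coeff.is_number and coeff != 0:
                    rest = sp.expand(law_red - coeff * sp.Symbol(s))
                    substitutions[s] = sp.expand((const - rest) / coeff)
                    break
        # close substitutions over each other
        for _ in range(len(substitutions)):
            substitutions = {
                s: sp.expand(e.subs({sp.Symbol(k): v for k, v in substitutions.items() if k != s}))
                for s, e in substitutions.items()
            }

    sub_map = {sp.Symbol(s): e for s, e in substitutions.items()}
    remaining = [s for s in model.states if s not in substitutions]
    rhs_red = {s: sp.together(model.rhs_exprs()[s].subs(sub_map)) for s in remaining}
    solve_for = [s for s in ranking if s in remaining and s not in model.observed]
    m = len(solve_for)

    # -- prolongation by the Lie chain -----------------------------------
    lies = lie_exprs(model, yname, m + 1, rhs_map=rhs_red)
    dsyms = [deriv_symbol(yname, k) for k in range(1, m + 2)]
    prolongation = [sp.together(dsyms[k] - lies[k]) for k in range(m)]

    solutions: dict[str, sp.Expr] = {}
    io_char: sp.Expr | None = None
    if m:
        target = [sp.Symbol(s) for s in solve_for]
        numers = [
            sp.expand(sp.numer(sp.together(dsyms[k] - lies[k]))) for k in range(m)
        ]
        try:
            # the common case: prolongation equations linear in the
            # unmeasured states -> exact linear elimination (Cramer)
            A, b = sp.linear_eq_to_matrix(numers, target)
            det = A.det(method="berkowitz")
            if sp.expand(det) == 0:
                raise EliminationError(
                    "prolongation system is structurally singular",
                    blocking_state=solve_for[0],
                )
            sol_vec = A.adjugate() * b
            sol = {t: sp.cancel(v / det) for t, v in zip(target, sol_vec)}
        except (sp.polys.polyerrors.PolynomialError, ValueError):
            sols = sp.solve(numers, target, dict=True)
            if not sols:
                raise EliminationError(
                    f"could not resolve unmeasured states {solve_for} from the "
                    f"prolongation system",
                    blocking_state=solve_for[0],
                )
            sol = sols[0]
        for s in solve_for:
            if sp.Symbol(s) not in sol:
                raise EliminationError(
                    f"state {s!r} not resolvable from the prolongation system",
                    blocking_state=s,
                )
            solutions[s] = sp.together(sp.cancel(sol[sp.Symbol(s)]))
        io_char = _linear_io_equation(rhs_red, remaining, yname, dsyms)

    equations: list[sp.Expr] = []
    leaders: list[str | None] = []

    # one emitted member for the top-ranked conservation-eliminated state;
    # lower-ranked parameter-free resolutions stay inlined substitutions.
    cons_leader = next((s for s in ranking if s in substitutions), None)
    if cons_leader is not None:
        eq = _normalize(sp.numer(sp.together(sp.Symbol(cons_leader) - substitutions[cons_leader])))
        equations.append(eq)
        leaders.append(cons_leader)
        solutions = {cons_leader: substitutions[cons_leader], **solutions}

    for s in solve_for:
        eq = _normalize(sp.numer(sp.together(sp.Symbol(s) - solutions[s])))
        if sp.count_ops(eq) > size_budget:
            raise EliminationError(
                f"equation for state {s!r} exceeds the size budget", blocking_state=s
            )
        equations.append(eq)
        leaders.append(s)

    if io_char is not None:
        io = _normalize(io_char)
    else:
        io = sp.together(
            sp.cancel((dsyms[m] - lies[m]).subs({sp.Symbol(s): e for s, e in solutions.items()}))
        )
        io = _normalize(sp.numer(io))
    bad = {s.name for s in io.free_symbols} & set(unmeasured)
    if bad:
        raise EliminationError(
            f"input-output equation still contains unmeasured states {sorted(bad)}",
            blocking_state=sorted(bad)[0],
        )
    if sp.count_ops(io) > size_budget:
        raise EliminationError("input-output equation exceeds the size budget")
    equations.append(io)
    leaders.append(None)

    inlined = {s: e for s, e in substitutions.items() if s != cons_leader}
    max_order = {yname: max(equation_order(eq, yname) for eq in equations)}
    prolongs = tuple(sp.together(dsyms[k] - lies[k]) for k in range(m))
    return EliminatedSystem(
        model_name=model.name,
        observed=tuple(model.observed),
        ranking_used=tuple(ranking),
        equations=tuple(equations),
        leaders=tuple(leaders),
        state_solutions=dict(solutions),
        substitutions=inlined,
        max_derivative_order=max_order,
        prolongations=prolongs,
        prolongation_leaders=tuple(solve_for),
    )


# -- numeric evaluation ---------------------------------------------------


_LAMBDIFY_CACHE: dict = {}


def _cached_lambdify(syms, expr_key, builder):
    """Per-process cache for lambdified expressions (the Model 2 system's
    members are large; compiling them dominates repeated evaluations)."""
    key = (expr_key, tuple(s.name for s in syms))
    fn = _LAMBDIFY_CACHE.get(key)
    if fn is None:
        fn = builder()
        _LAMBDIFY_CACHE[key] = fn
    return fn


def _symbol_value(
    sym: sp.Symbol,
    params: Mapping[str, float],
    data: Mapping[str, np.ndarray],
    derivs: Mapping[tuple[str, int], np.ndarray],
    state_values: Mapping[str, np.ndarray],
):
    name = sym.name
    m = _DERIV_RE.match(name)
    if m:
        key = (m.group(1), int(m.group(2)))
        if key not in derivs:
            raise KeyError(f"missing derivative {name}")
        return derivs[key]
    if name in data:
        return data[name]
    if name in state_values:
        return state_values[name]
    if name in params:
        return params[name]
    raise KeyError(f"no value supplied for symbol {name}")


def solve_states(
    sys: EliminatedSystem,
    params: Mapping[str, float],
    data: Mapping[str, np.ndarray],
    derivs: Mapping[tuple[str, int], np.ndarray],
) -> dict[str, np.ndarray]:
    """Evaluate every recorded state resolution on data-side quantities.

    Returns leader states (and inlined substitutions) as arrays on the
    data grid, computed from the observed series, its supplied
    derivatives, and the candidate parameters.
    """
    out: dict[str, np.ndarray] = {}
    exprs = {**sys.substitutions, **sys.state_solutions}
    for s, expr in exprs.items():
        syms = sorted(expr.free_symbols, key=lambda x: x.name)
        vals = [_symbol_value(sym, params, data, derivs, out) for sym in syms]
        fn = _cached_lambdify(syms, ("sol", id(expr)), lambda: sp.lambdify(syms, expr, modules="numpy"))
        with np.errstate(all="ignore"):
            val = fn(*vals)
        shape = next(iter(data.values())).shape
        out[s] = np.broadcast_to(np.asarray(val, dtype=float), shape).copy()
    return out


def evaluate_equations(
    sys: EliminatedSystem,
    params: Mapping[str, float],
    data: Mapping[str, np.ndarray],
    derivs: Mapping[tuple[str, int], np.ndarray],
    state_values: Mapping[str, np.ndarray] | None = None,
    relative: bool = False,
) -> list[np.ndarray]:
    """Residual of every equation on the supplied series.

    ``state_values`` supplies leader-state series (e.g. from a candidate
    simulation or from :func:`solve_states`); when omitted they are
    resolved from the recorded expressions.  With ``relative=True`` each
    residual is divided by the sum of the magnitudes of the equation's
    monomials at the same point — the cancellation-aware notion of
    "vanishes" for polynomials whose terms reach far above unity.
    """
    if state_values is None:
        state_values = solve_states(sys, params, data, derivs)
    shape = next(iter(data.values())).shape
    out = []
    for eq in sys.equations:
        syms = sorted(eq.free_symbols, key=lambda x: x.name)
        vals = [_symbol_value(sym, params, data, derivs, state_values) for sym in syms]
        fn = _cached_lambdify(syms, ("eq", id(eq)), lambda: sp.lambdify(syms, eq, modules="numpy"))
        with np.errstate(all="ignore"):
            val = np.broadcast_to(np.asarray(fn(*vals), dtype=float), shape).copy()
        if relative:
            terms = eq.args if eq.is_Add else (eq,)
            tf = _cached_lambdify(
                syms,
                ("absterms", id(eq)),
                lambda: sp.lambdify(syms, [sp.Abs(t) for t in terms], modules="numpy"),
            )
            with np.errstate(all="ignore"):
                mags = tf(*vals)
            total = np.zeros(shape)
            for mm in mags:
                total += np.broadcast_to(np.asarray(mm, dtype=float), shape)
            val = val / np.maximum(total, 1.0)
        out.append(val)
    return out


_SYSTEM_CACHE: dict[str, EliminatedSystem] = {}


def get_system(model: ODEModel, **kwargs) -> EliminatedSystem:
    """Eliminated system for ``model``: shipped fixture if one exists,
    otherwise a fresh (cached) derivation."""
    if not kwargs and model.name in _SYSTEM_CACHE:
        return _SYSTEM_CACHE[model.name]
    try:
        sys = load_fixture(model.name) if not kwargs else eliminate(model, **kwargs)
    except FileNotFoundError:
        sys = eliminate(model, **kwargs)
    if not kwargs:
        _SYSTEM_CACHE[model.name] = sys
    return sys


def load_fixture(model_name: str) -> EliminatedSystem:
    """Load the versioned eliminated system shipped for a bundled model.

    The fixture is byte-identical to a fresh :func:`eliminate` run (the
    test suite asserts this); it lets the optimizers start without
    re-deriving Model 2's system (~30 s of symbolic work).
    """
    import importlib.resources

    ref = importlib.resources.files("defit") / "fixtures" / f"{model_name}.txt"
    if not ref.is_file():
        raise FileNotFoundError(f"no eliminated-system fixture for {model_name!r}")
    return parse_system(ref.read_text())


# -- canonical text form --------------------------------------------------


def serialize_system(sys: EliminatedSystem) -> str:
    """Deterministic canonical text form of an eliminated system."""
    lines = ["# defit eliminated system v1"]
    lines.append(f"model: {sys.model_name}")
    lines.append(f"observed: {','.join(sys.observed)}")
    lines.append(f"ranking: {','.join(sys.ranking_used)}")
    lines.append(
        "order: "
        + ",".join(f"{v}={k}" for v, k in sorted(sys.max_derivative_order.items()))
    )
    for s in sorted(sys.substitutions):
        lines.append(f"substitution: {s} = {sp.sstr(sys.substitutions[s], order='lex')}")
    for s, e in sys.state_solutions.items():
        lines.append(f"solution: {s} = {sp.sstr(e, order='lex')}")
    for s, e in zip(sys.prolongation_leaders, sys.prolongations):
        lines.append(f"prolongation {s}: {sp.sstr(e, order='lex')}")
    for eq, lead in zip(sys.equations, sys.leaders):
        lines.append(f"equation {lead or '-'}: {sp.sstr(eq, order='lex')}")
    return "\n".join(lines) + "\n"


def _parse_expr(text: str, allowed: dict[str, sp.Symbol]) -> sp.Expr:
    expr = sp.parse_expr(text, local_dict=allowed, evaluate=True)
    extra = expr.free_symbols - set(allowed.values())
    if extra:
        raise ValueError(f"expression references undeclared symbols: {sorted(map(str, extra))}")
    return expr


def parse_system(text: str) -> EliminatedSystem:
    """Parse the canonical text form back into an :class:`EliminatedSystem`."""
    model_name = None
    observed: tuple[str, ...] = ()
    ranking: tuple[str, ...] = ()
    orders: dict[str, int] = {}
    substitutions: dict[str, sp.Expr] = {}
    solutions: dict[str, sp.Expr] = {}
    equations: list[sp.Expr] = []
    leaders: list[str | None] = []
    prolongations: list[sp.Expr] = []
    prolongation_leaders: list[str] = []
    allowed: dict[str, sp.Symbol] = {}

    def ensure_allowed():
        if not allowed:
            if not ranking or not observed or not orders:
                raise ValueError("header (ranking/observed/order) must precede expressions")
            for s in ranking:
                allowed[s] = sp.Symbol(s)
            for v, k in orders.items():
                for i in range(1, k + 1):
                    allowed[f"{v}__d{i}"] = deriv_symbol(v, i)
        return allowed

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            key, _, rest = line.partition(":")
            key = key.strip()
            rest = rest.strip()
            if key == "model":
                model_name = rest
            elif key == "observed":
                observed = tuple(rest.split(","))
            elif key == "ranking":
                ranking = tuple(rest.split(","))
            elif key == "order":
                for item in rest.split(","):
                    v, k = item.split("=")
                    orders[v] = int(k)
            elif key in ("substitution", "solution"):
                name, _, body = rest.partition("=")
                # parameters may appear in solutions; allow any symbol here
                # and validate against ranking+derivs+params-by-usage later.
                expr = sp.parse_expr(body.strip())
                target = substitutions if key == "substitution" else solutions
                target[name.strip()] = expr
            elif key.startswith("equation") or key.startswith("prolongation"):
                lead = key.split(None, 1)[1] if len(key.split()) > 1 else "-"
                local = dict(ensure_allowed())
                # parameters are legal symbols in equations; add on sight
                expr = sp.parse_expr(rest)
                for s in expr.free_symbols:
                    mm = _DERIV_RE.match(s.name)
                    if mm:
                        v, k = mm.group(1), int(mm.group(2))
                        if v not in orders or k > orders[v]:
                            raise ValueError(f"derivative {s.name} above declared order")
                    elif s.name not in local and "__" in s.name:
                        raise ValueError(f"undeclared symbol {s.name}")
                if key.startswith("prolongation"):
                    prolongations.append(expr)
                    prolongation_leaders.append(lead)
                else:
                    equations.append(expr)
                    leaders.append(None if lead == "-" else lead)
            else:
                raise ValueError(f"unknown field {key!r}")
        except (ValueError, sp.SympifyError, SyntaxError) as exc:
            raise ValueError(f"line {lineno}: cannot parse {raw!r}: {exc}") from exc
    if model_name is None or not equations:
        raise ValueError("malformed system file: missing model or equations")
    lead_states = {l for l in leaders if l is not None}
    for l in lead_states:
        if l not in ranking:
            raise ValueError(f"equation leader {l!r} is not a ranked state")
    return EliminatedSystem(
        model_name=model_name,
        observed=observed,
        ranking_used=ranking,
        equations=tuple(equations),
        leaders=tuple(leaders),
        state_solutions=solutions,
        substitutions=substitutions,
        max_derivative_order=orders,
        prolongations=tuple(prolongations),
        prolongation_leaders=tuple(prolongation_leaders),
    )
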