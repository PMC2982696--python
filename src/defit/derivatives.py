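"""Numerical differentiation of sampled time courses.

The constraint equations are evaluated on measured data, which requires
estimates of the observed variable's time derivatives.  Two estimators
are provided: iterated second-order central differences (exact for
quadratics, the right choice for noiseless curves) and a generalized
cross-validated smoothing spline (the right choice once measurement
noise is present).  Orders above four are supported but emit a warning:
high-order derivatives estimated from sampled data carry little signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .trajectory import Trajectory

__all__ = ["DerivativeSettings", "estimate_derivatives", "HIGH_ORDER_WARNING"]

HIGH_ORDER_WARNING = (
    "derivative order %d exceeds the recommended cap of 4; high-order "
    "estimates from sampled data are dominated by discretisation/noise error"
)


@dataclass(frozen=True)
class DerivativeSettings:
    """How data-side derivatives of the observed series are estimated.

    method : "central_difference" or "smoothing_spline"
        Central differences for noiseless curves; a cubic smoothing
        spline with GCV-selected smoothing for noisy ones.
    spline_smoothing : float or None
        Smoothing parameter ``lam``; None selects it by generalized
        cross-validation.
    max_order : int
        Highest derivative order estimated (and the highest order of
        constraint equation evaluated on data).
    """

    method: str = "central_difference"
    spline_smoothing: float | None = None
    max_order: int = 4
    accuracy: int = 2

    def __post_init__(self):
        if self.method not in ("central_difference", "smoothing_spline"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")
        if self.accuracy < 2 or self.accuracy % 2:
            raise ValueError("accuracy must be an even integer >= 2")

    @classmethod
    def for_noise(cls, c: float, max_order: int = 4) -> "DerivativeSettings":
        """Default estimator choice given the data's noise scale."""
        method = "smoothing_spline" if c > 0 else "central_difference"
        return cls(method=method, max_order=max_order)


def _central(times: np.ndarray, y: np.ndarray, order: int) -> dict[int, np.ndarray]:
    steps = np.diff(times)
    if not np.allclose(steps, steps[0], rtol=1e-8):
        raise ValueError("central differences require a uniform grid")
    out = {}
    cur = y
    for k in range(1, order + 1):
        cur = np.gradient(cur, times, edge_order=2)
        out[k] = cur
    return out


def _fornberg_weights(x: np.ndarray, x0: float, k: int) -> np.ndarray:
    """Finite-difference weights for the k-th derivative at ``x0`` on
    arbitrary nodes ``x`` (Fornberg's recursion)."""
    n = len(x)
    C = np.zeros((n, k + 1))
    C[0, 0] = 1.0
    c1 = 1.0
    c4 = x[0] - x0
    for i in range(1, n):
        mn = min(i, k)
        c2 = 1.0
        c5 = c4
        c4 = x[i] - x0
        for j in range(i):
            c3 = x[i] - x[j]
            c2 *= c3
            if j == i - 1:
                for v in range(mn, 0, -1):
                    C[i, v] = c1 * (v * C[i - 1, v - 1] - c5 * C[i - 1, v]) / c2
                C[i, 0] = -c1 * c5 * C[i - 1, 0] / c2
            for v in range(mn, 0, -1):
                C[j, v] = (c4 * C[j, v] - v * C[j, v - 1]) / c3
            C[j, 0] = c4 * C[j, 0] / c3
        c1 = c2
    return C[:, k]


def _stencil(times: np.ndarray, y: np.ndarray, order: int, accuracy: int) -> dict[int, np.ndarray]:
    """Direct central stencils of the requested accuracy order.

    Each derivative order is estimated independently from the raw series
    with a sliding window of ``order + accuracy - 1`` (rounded up to odd)
    points, shifted one-sidedly near the boundary.
    """
    N = times.size
    out = {}
    for k in range(1, order + 1):
        w = k + accuracy - 1
        if w % 2 == 0:
            w += 1
        w = min(w, N)
        half = w // 2
        est = np.empty(N)
        for i in range(N):
            start = min(max(i - half, 0), N - w)
            idx = slice(start, start + w)
            wts = _fornberg_weights(times[idx], times[i], k)
            est[i] = float(np.dot(wts, y[idx]))
        out[k] = est
    return out


def _spline(times, y, order, lam) -> dict[int, np.ndarray]:
    out = {}
    spl = make_smoothing_spline(times, y, lam=lam)
    base = 0
    cur = spl
    for k in range(1, order + 1):
        if k - base > 3:
            # cubic pieces differentiate cleanly three times; re-smooth the
            # last series before going higher
            cur = make_smoothing_spline(times, out[k - 1], lam=lam)
            base = k - 1
        out[k] = cur.derivative(k - base)(times)
    return out


def estimate_derivatives(
    series: Trajectory,
    settings: DerivativeSettings | None = None,
    variables=None,
) -> dict[tuple[str, int], np.ndarray]:
    """Estimate d^k(var)/dt^k on the series' own grid for k = 1..max_order.

    Interior points use second-order central stencils (or the spline's
    analytic derivative); boundary points use one-sided second-order
    stencils.  Raises ValueError if the series is too short
    (fewer than ``2*max_order + 1`` points).
    """
    settings = settings or DerivativeSettings()
    if len(series) < 2 * settings.max_order + 1:
        raise ValueError(
            f"need at least {2 * settings.max_order + 1} points for order "
            f"{settings.max_order}, got {len(series)}"
        )
    if settings.max_order > 4:
        warnings.warn(HIGH_ORDER_WARNING % settings.max_order, stacklevel=2)
    variables = tuple(variables) if variables is not None else series.variables
    out: dict[tuple[str, int], np.ndarray] = {}
    for var in variables:
        y = series[var]
        if settings.method == "central_difference":
            if settings.accuracy == 2:
                per = _central(series.times, y, settings.max_order)
            else:
                per = _stencil(series.times, y, settings.max_order, settings.accuracy)
        else:
            per = _spline(series.times, y, settings.max_order, settings.spline_smoothing)
        for k, v in per.items():
            out[(var, k)] = v
    return out
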