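"""Scaling-law fits and blob-crossover detection.

The chain-size scaling laws fitted here are

* chain length:    <Rg^2> ~ N^(2 nu)      (2 nu = 3/2 dilute 2D good
  solvent, 1 in the melt / for ideal chains)
* concentration:   <Rg^2> ~ phi^((1 - 2 nu)/(d nu - 1))  in the
  concentrated regime; for nu = 3/4, d = 2 the exponent is -1
* structure factor: S(q) ~ q^(-1/nu) in the fractal window
  2 pi/Rg << q << 2 pi  (slope -4/3 dilute, -2 dense)

In the semidilute regime a chain is a self-avoiding walk below the
correlation (blob) length xi and ideal above it, so log S(q) vs log q
changes slope near q* = 2 pi/xi; :func:`detect_crossover` locates that
breakpoint with a two-segment piecewise-linear fit.

All exponent fits are ordinary least squares in log-log space with the
usual OLS standard error; Monte Carlo configurations are correlated, so
these errors are lower bounds unless inputs are pre-blocked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_FIT_KINDS = ("chain-length", "concentration", "structure-factor")


@dataclass
class ScalingFit:
    exponent: float
    stderr: float
    window: tuple[float, float]
    r_squared: float
    kind: str
    amplitude: float = np.nan  # prefactor exp(intercept)
    n_points: int = 0


@dataclass
class CrossoverEstimate:
    found: bool
    q_star: float
    xi: float
    low_q_slope: float
    high_q_slope: float


def fit_power_law(
    xs, ys, window: tuple[float, float] | None = None, kind: str = "chain-length"
) -> ScalingFit:
    """Least-squares slope of log y vs log x over ``window`` (inclusive)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if np.any(xs <= 0) or np.any(ys <= 0):
        raise ValueError("power-law fit needs strictly positive data")
    if window is None:
        window = (xs.min(), xs.max())
    mask = (xs >= window[0]) & (xs <= window[1])
    if mask.sum() < 3:
        raise ValueError("need at least 3 points inside the fit window")
    res = stats.linregress(np.log(xs[mask]), np.log(ys[mask]))
    return ScalingFit(
        exponent=float(res.slope),
        stderr=float(res.stderr),
        window=(float(window[0]), float(window[1])),
        r_squared=float(res.rvalue**2),
        kind=kind,
        amplitude=float(np.exp(res.intercept)),
        n_points=int(mask.sum()),
    )


def estimate_2nu(
    chain_lengths, rg2_means, window: tuple[float, float] | None = None
) -> ScalingFit:
    """Fit <Rg^2> ~ N^(2 nu) across chain lengths."""
    return fit_power_law(chain_lengths, rg2_means, window, kind="chain-length")


def concentration_exponent_reference(nu: float, d: int) -> float:
    """Analytic exponent (1 - 2 nu)/(d nu - 1) of <Rg^2> ~ phi^x."""
    return (1.0 - 2.0 * nu) / (d * nu - 1.0)


def estimate_concentration_exponent(
    phis, rg2_means, window: tuple[float, float] | None = None
) -> ScalingFit:
    """Fit <Rg^2> ~ phi^x at fixed N over the concentrated regime.

    The 2D athermal reference value is
    ``concentration_exponent_reference(3/4, 2) == -1``.
    """
    return fit_power_law(phis, rg2_means, window, kind="concentration")


def sq_slope(
    curve_or_q, s=None, window: tuple[float, float] | None = None
) -> ScalingFit:
    """Log-log slope of S(q) inside the fractal window.

    Accepts a :class:`~cmapoly.observables.StructureFactorCurve` or a
    pair of arrays.  The caller chooses the window; sensible defaults are
    ``(2*pi/Rg, pi)``.
    """
    if s is None:
        q, s = curve_or_q.q, curve_or_q.s
    else:
        q = curve_or_q
    return fit_power_law(q, s, window, kind="structure-factor")


def detect_crossover(
    curve_or_q,
    s=None,
    min_segment: int = 4,
    min_delta_slope: float = 0.2,
) -> CrossoverEstimate:
    """Two-segment piecewise-linear fit of log S vs log q.

    The breakpoint q* is the grid point minimising the total squared
    residual of independent fits to the two segments; xi = 2 pi/q*.  If
    the two slopes differ by less than ``min_delta_slope`` the result is
    flagged ``found=False`` ("no crossover"), which is the expected
    outcome for a pure power law.
    """
    if s is None:
        q, s = curve_or_q.q, curve_or_q.s
    else:
        q = curve_or_q
    q = np.asarray(q, dtype=float)
    s = np.asarray(s, dtype=float)
    if len(q) < 12:
        raise ValueError("crossover detection needs at least 12 points")
    lq, ls = np.log(q), np.log(s)
    best = None
    for brk in range(min_segment, len(q) - min_segment + 1):
        sse = 0.0
        slopes = []
        for seg in (slice(0, brk), slice(brk - 1, len(q))):
            # segments share the breakpoint sample so xi lies on the grid
            p, res = np.polyfit(lq[seg], ls[seg], 1, full=True)[:2]
            sse += float(res[0]) if len(res) else 0.0
            slopes.append(float(p[0]))
        if best is None or sse < best[0]:
            best = (sse, brk, slopes)
    _, brk, (low_slope, high_slope) = best
    q_star = float(q[brk - 1])
    found = abs(low_slope - high_slope) >= min_delta_slope
    return CrossoverEstimate(
        found=found,
        q_star=q_star,
        xi=2.0 * np.pi / q_star,
        low_q_slope=low_slope,
        high_q_slope=high_slope,
    )
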