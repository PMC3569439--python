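"""Observable decay patterns and the bona-fide convexity screen.

After a global transcription stop at steady state, the relative transcript
level at delay ``dt`` is the normalised tail integral of the lifetime
survival function,

    N_rel(dt) = (1 / <U>) * int_dt^inf survival(u) du,

while after a short transcriptional pulse the whole cohort shares one age
and the level is simply the survival function.  Steady-state patterns are
always non-increasing and convex; pulse patterns need not be.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .lifetime_models import LifetimeDistribution, _nonneg_times, _scalarize

__all__ = [
    "DecayPattern",
    "BonaFideStatus",
    "steady_state_pattern",
    "pulse_pattern",
    "pattern_half_life",
    "check_bona_fide",
    "tail_integral",
]

DEFAULT_NEAR_TOL = 0.05


@dataclass
class DecayPattern:
    """Relative transcript level as a function of the delay (minutes)."""

    value: Callable[[np.ndarray], np.ndarray]
    mode: str  # "steady_state" | "pulse"
    source: LifetimeDistribution

    def __call__(self, dt):
        return self.value(dt)


def tail_integral(lt: LifetimeDistribution, dt) -> np.ndarray | float:
    """``int_dt^inf survival(u) du``, analytic when the model provides it.

    The quadrature fallback integrates to a cutoff where survival has
    dropped below 1e-12 and completes the tail with an exponential bound
    from the local hazard.
    """
    if lt.survival_tail_integral is not None:
        return lt.survival_tail_integral(dt)
    ts = _nonneg_times(dt)
    out = np.empty_like(ts)
    # find cutoff T* with survival < 1e-12
    T = max(10.0 * lt.mean, 1.0)
    while float(lt.survival(T)) > 1e-12 and T < 1e9:
        T *= 2.0
    for i, t in enumerate(ts):
        val, _ = quad(lambda u: float(lt.survival(u)), t, T, limit=400)
        # exponential tail completion using the hazard at the cutoff
        s_T = float(lt.survival(T))
        if s_T > 0:
            h = float(lt.pdf(T)) / s_T
            if h > 0:
                val += s_T / h
        out[i] = val
    return _scalarize(out, dt)


def steady_state_pattern(lt: LifetimeDistribution) -> DecayPattern:
    """Decay pattern after a transcription stop at steady-state expression."""
    if not np.isfinite(lt.mean):
        raise ValueError("lifetime mean must be finite for a steady-state pattern")
    mean = lt.mean

    def value(dt):
        return tail_integral(lt, dt) / mean

    return DecayPattern(value=value, mode="steady_state", source=lt)


def pulse_pattern(lt: LifetimeDistribution) -> DecayPattern:
    """Decay pattern of a cohort born in a short transcriptional pulse."""
    return DecayPattern(value=lt.survival, mode="pulse", source=lt)


def pattern_half_life(p: DecayPattern, horizon: float = 1e7) -> float:
    """The delay at which the pattern crosses 1/2, by bracketing + brentq."""
    hi = min(max(getattr(p.source, "mean", 1.0), 1.0), horizon)
    while float(p.value(hi)) > 0.5:
        if hi >= horizon:
            raise ValueError(
                f"pattern does not reach 1/2 within search horizon {horizon} min"
            )
        hi = min(hi * 2.0, horizon)
    return float(brentq(lambda t: float(p.value(t)) - 0.5, 0.0, hi, xtol=1e-8))


class BonaFideStatus(str, Enum):
    STRICT_PASS = "strict_pass"
    NEAR_PASS = "near_pass"
    FAIL = "fail"


def check_bona_fide(table, levels=None, tol: float = DEFAULT_NEAR_TOL):
    """Screen a measured decay curve for monotone decrease and convexity.

    Accepts either a table object with ``times``/``levels`` attributes or
    two explicit arrays.  Works on the discrete grid: first differences
    must be <= +tol and second difference quotients (slope increments)
    >= -tol.  ``strict_pass`` means both hold with tol = 0; ``near_pass``
    with the given tolerance.

    Returns
    -------
    (status, diagnostics) : (BonaFideStatus, dict)
        ``diagnostics`` lists the offending intervals at tol = 0:
        ``monotonicity_violations`` as (t_left, t_right, level_increase) and
        ``convexity_violations`` as (t_left, t_mid, t_right, slope_drop).
    """
    if hasattr(table, "times") and hasattr(table, "levels"):
        times, levels = table.times, table.levels
    else:
        times = table
    times = np.asarray(times, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if times.shape != levels.shape or times.ndim != 1:
        raise ValueError("times and levels must be 1-d arrays of equal length")
    if times.size < 3:
        raise ValueError("need at least 3 time points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time points must be strictly increasing")

    diffs = np.diff(levels)
    slopes = diffs / np.diff(times)
    slope_steps = np.diff(slopes)

    mono_viol = [
        (float(times[j]), float(times[j + 1]), float(diffs[j]))
        for j in np.nonzero(diffs > 0)[0]
    ]
    convex_viol = [
        (float(times[j]), float(times[j + 1]), float(times[j + 2]), float(slope_steps[j]))
        for j in np.nonzero(slope_steps < 0)[0]
    ]
    diagnostics = {
        "monotonicity_violations": mono_viol,
        "convexity_violations": convex_viol,
        "max_level_increase": float(max(diffs.max(), 0.0)),
        "max_slope_drop": float(max(-slope_steps.min(), 0.0)) if slope_steps.size else 0.0,
    }

    if not mono_viol and not convex_viol:
        return BonaFideStatus.STRICT_PASS, diagnostics
    if np.all(diffs <= tol) and np.all(slope_steps >= -tol):
        return BonaFideStatus.NEAR_PASS, diagnostics
    return BonaFideStatus.FAIL, diagnostics
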