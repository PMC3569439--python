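"""Age-dependent degradation rates, residual lifetimes and synthesis capacity.

The hazard (age-dependent degradation rate) of a molecule of age ``a`` is
``pdf(a)/survival(a)``.  It can equivalently be read off a measured decay
pattern: for a steady-state pattern the ratio of the second to the negated
first derivative, for a pulse pattern the negative logarithmic derivative.
All three routes must agree — a consistency contract exercised heavily in
the tests.

Residual quantities describe the ageing of the surviving population after
the transcription stop: the density of the remaining lifetime ``R`` at
delay ``dt`` is ``survival(dt + r) / int_dt^inf survival``, and the residual
protein synthesis capacity is ``C(dt) ∝ N_rel(dt) * <R>(dt)``, normalised
to ``C(0) = 1``.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad

from .decay_patterns import DecayPattern, steady_state_pattern, tail_integral
from .lifetime_models import LifetimeDistribution

__all__ = [
    "hazard_rate",
    "hazard_from_pattern",
    "hazard_from_pulse",
    "residual_density",
    "residual_density_pulse",
    "mean_residual",
    "synthesis_capacity",
    "stationary_age_density",
]

_SUPPORT_FLOOR = 1e-300


def hazard_rate(lt: LifetimeDistribution, a):
    """Instantaneous degradation rate of a molecule of age ``a``.

    Raises outside the numerical support instead of extrapolating.
    """
    a_arr = np.atleast_1d(np.asarray(a, dtype=float))
    s = np.atleast_1d(lt.survival(a_arr))
    if np.any(s < _SUPPORT_FLOOR):
        raise ValueError("hazard undefined: survival underflows at requested age")
    out = np.atleast_1d(lt.pdf(a_arr)) / s
    return float(out[0]) if np.ndim(a) == 0 else out


def _derivatives(p: DecayPattern, t: np.ndarray, h: float):
    """Central finite differences of the pattern value."""
    t = np.asarray(t, dtype=float)
    f = lambda x: np.atleast_1d(p.value(np.maximum(x, 0.0)))
    # shift the stencil right at the boundary so we never evaluate t < 0
    lo = np.maximum(t - h, 0.0)
    hi = lo + 2 * h
    d1 = (f(hi) - f(lo)) / (2 * h)
    d2 = (f(hi) - 2 * f(lo + h) + f(lo)) / h**2
    return d1, d2


def hazard_from_pattern(p: DecayPattern, h: float = 0.05):
    """Recover the hazard from a steady-state decay pattern.

    Uses the identity hazard(a) = -d2 N_rel / d1 N_rel: the first derivative
    of the pattern is -survival/<U> and the second is pdf/<U>, so their
    ratio cancels the unknown normalisation.
    """
    if p.mode != "steady_state":
        raise ValueError("expected a steady-state pattern; use hazard_from_pulse")
    lt = p.source

    def hazard(a):
        a_arr = np.atleast_1d(np.asarray(a, dtype=float))
        if lt is not None and lt.survival_tail_integral is not None:
            # analytic derivatives available through the source model
            d1 = -np.atleast_1d(lt.survival(a_arr)) / lt.mean
            d2 = np.atleast_1d(lt.pdf(a_arr)) / lt.mean
        else:
            d1, d2 = _derivatives(p, a_arr, h)
        out = d2 / (-d1)
        return float(out[0]) if np.ndim(a) == 0 else out

    return hazard


def hazard_from_pulse(p: DecayPattern, h: float = 1e-4):
    """Recover the hazard from a pulse pattern: -d/dt log value(t)."""
    if p.mode != "pulse":
        raise ValueError("expected a pulse pattern; use hazard_from_pattern")
    lt = p.source

    def hazard(t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if lt is not None:
            out = np.atleast_1d(lt.pdf(t_arr)) / np.atleast_1d(lt.survival(t_arr))
        else:
            d1, _ = _derivatives(p, t_arr, h)
            out = -d1 / np.atleast_1d(p.value(t_arr))
        return float(out[0]) if np.ndim(t) == 0 else out

    return hazard


def residual_density(lt: LifetimeDistribution, dt: float):
    """Density of the residual lifetime at delay ``dt`` after the stop.

    phi(r; dt) = survival(dt + r) / int_dt^inf survival(u) du.  At dt = 0
    this is the stationary residual-lifetime law survival(r)/<U>.
    """
    dt = float(dt)
    denom = float(tail_integral(lt, dt))
    if denom <= 0:
        raise ValueError(f"no surviving mass beyond dt={dt}")

    def density(r):
        r_arr = np.atleast_1d(np.asarray(r, dtype=float))
        if np.any(r_arr < 0):
            raise ValueError("residual times must be non-negative")
        out = np.atleast_1d(lt.survival(dt + r_arr)) / denom
        return float(out[0]) if np.ndim(r) == 0 else out

    return density


def residual_density_pulse(lt: LifetimeDistribution, t: float):
    """Residual-lifetime density for a pulse cohort of common age ``t``."""
    t = float(t)
    s = float(lt.survival(t))
    if s < _SUPPORT_FLOOR:
        raise ValueError(f"no surviving mass at age t={t}")

    def density(r):
        r_arr = np.atleast_1d(np.asarray(r, dtype=float))
        if np.any(r_arr < 0):
            raise ValueError("residual times must be non-negative")
        out = np.atleast_1d(lt.pdf(t + r_arr)) / s
        return float(out[0]) if np.ndim(r) == 0 else out

    return density


def mean_residual(lt: LifetimeDistribution, dt: float) -> float:
    """Average residual lifetime <R>(dt) of survivors at delay ``dt``.

    Computed as int_dt^inf (u - dt) survival'(...)... equivalently
    int_0^inf r phi(r; dt) dr = int_dt^inf tail(u) du / tail(dt), where
    tail is the survival tail integral; we integrate the tail by parts:
    int_0^inf r S(dt+r) dr / tail(dt) with the double tail evaluated by
    quadrature over the (analytic) single tail.
    """
    denom = float(tail_integral(lt, dt))
    if denom <= 0:
        raise ValueError(f"no surviving mass beyond dt={dt}")
    if lt.chain is not None:
        # exact: int_dt^inf tail(u) du = alpha T^{-2} exp(T dt) 1
        from scipy.linalg import expm

        T_sub = lt.chain.subgenerator
        alpha = lt.chain.initial_state
        v = np.linalg.solve(T_sub, np.linalg.solve(T_sub, expm(T_sub * dt) @ np.ones(lt.chain.n)))
        return float(alpha @ v) / denom
    # int_0^inf r S(dt+r) dr = int_dt^inf tail(u) du  (Fubini)
    T = dt + 20.0 * lt.mean
    while float(lt.survival(T)) > 1e-14 and T < 1e9:
        T *= 2.0
    num, _ = quad(lambda u: float(tail_integral(lt, u)), dt, T, limit=400)
    # exponential completion of the doubly-integrated tail
    tail_T = float(tail_integral(lt, T))
    s_T = float(lt.survival(T))
    if tail_T > 0 and s_T > 0:
        num += tail_T**2 / s_T
    return num / denom


def synthesis_capacity(lt: LifetimeDistribution, dt: float) -> float:
    """Residual protein synthesis capacity C(dt) = N_rel(dt)*<R>(dt)/<R>(0)."""
    pattern = steady_state_pattern(lt)
    return float(pattern.value(dt)) * mean_residual(lt, dt) / mean_residual(lt, 0.0)


def stationary_age_density(lt: LifetimeDistribution):
    """Age density of molecules alive at steady state: survival(a)/<U>."""
    if not np.isfinite(lt.mean):
        raise ValueError("requires a finite mean lifetime")
    mean = lt.mean

    def density(a):
        a_arr = np.atleast_1d(np.asarray(a, dtype=float))
        out = np.atleast_1d(lt.survival(a_arr)) / mean
        return float(out[0]) if np.ndim(a) == 0 else out

    return density
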