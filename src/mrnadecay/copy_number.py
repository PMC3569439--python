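"""Poisson copy-number laws at steady state and after a transcription stop.

With Poissonian transcription at rate ``nu`` and i.i.d. lifetimes, the
copy number per cell is Poisson at steady state (mean ``nu * <U>``) and
stays Poisson after the stop, with mean ``mu(dt) = nu * int_dt^inf
survival``.  The ratio ``mu(dt)/mu(0)`` is exactly the steady-state decay
pattern, which is the bridge between single-molecule lifetimes and the
population-level measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from .decay_patterns import tail_integral
from .lifetime_models import LifetimeDistribution

__all__ = [
    "ExpressionModel",
    "stationary_pmf",
    "mean_after_stop",
    "pmf_after_stop",
    "survival_probability_window",
    "finite_window_pmf",
]


@dataclass(frozen=True)
class ExpressionModel:
    """Poisson transcription at rate ``nu`` (1/min) with lifetime ``lt``."""

    nu: float
    lt: LifetimeDistribution

    def __post_init__(self):
        if self.nu <= 0:
            raise ValueError("transcription rate nu must be positive")
        if not np.isfinite(self.nu * self.lt.mean):
            raise ValueError("steady-state mean nu*<U> must be finite")

    @property
    def stationary_mean(self) -> float:
        return self.nu * self.lt.mean


def stationary_pmf(em: ExpressionModel, k) -> np.ndarray | float:
    """P(copy number = k) at steady state: Poisson with mean nu*<U>."""
    k_arr = np.asarray(k)
    if np.any(k_arr < 0):
        raise ValueError("copy number must be non-negative")
    return poisson.pmf(k, em.stationary_mean)


def mean_after_stop(em: ExpressionModel, dt) -> np.ndarray | float:
    """Average copy number mu(dt) = nu * int_dt^inf survival(u) du."""
    return em.nu * tail_integral(em.lt, dt)


def pmf_after_stop(em: ExpressionModel, dt, k) -> np.ndarray | float:
    """P(copy number = k) at delay ``dt`` after the stop: Poisson(mu(dt))."""
    k_arr = np.asarray(k)
    if np.any(k_arr < 0):
        raise ValueError("copy number must be non-negative")
    return poisson.pmf(k, mean_after_stop(em, dt))


def survival_probability_window(lt: LifetimeDistribution, T: float, dt: float) -> float:
    """P(a molecule born uniformly on [0, T] is alive at T + dt).

    p = (1/T) int_0^T survival(s + dt) ds, evaluated through the tail
    integral as (tail(dt) - tail(T + dt)) / T.  As T grows, nu*T*p tends to
    mu(dt); this is the finite-window construction behind the post-stop
    Poisson law.
    """
    if T <= 0:
        raise ValueError("window length T must be positive")
    return float(tail_integral(lt, dt) - tail_integral(lt, T + dt)) / T


def finite_window_pmf(em: ExpressionModel, T: float, dt: float, k_max: int) -> np.ndarray:
    """Exact copy-number pmf for a finite transcription window of length T.

    Births on [0, T] are Poisson(nu*T); each survives to T + dt
    independently with probability ``survival_probability_window``, so the
    Poisson-binomial mixture collapses to Poisson(nu*T*p).  Exposed for
    convergence tests against :func:`pmf_after_stop` (the T -> inf limit),
    not as public pipeline API.
    """
    p = survival_probability_window(em.lt, T, dt)
    return poisson.pmf(np.arange(k_max + 1), em.nu * T * p)
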