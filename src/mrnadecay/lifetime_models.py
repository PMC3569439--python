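"""Lifetime distributions of multi-step degradation chains.

A transcript is modelled as a particle on a linear continuous-time Markov
chain with states ``1..n``: from state ``i`` it either matures to state
``i+1`` at rate ``omega[i]`` or is degraded (absorbed) at rate ``delta[i]``.
The molecule lifetime is the absorption time, i.e. a phase-type random
variable.  This module provides the generic matrix-exponential route
(:func:`lifetime_from_chain`) and numerically hardened closed forms for the
three restricted parameterisations used throughout the package:

* :func:`lifetime_exponential` -- every state has the same degradation rate;
* :func:`lifetime_first_step` -- the first state has its own rate, all later
  states share a second rate (fast-then-slow decay when ``delta1 > delta2``);
* :func:`lifetime_last_step` -- degradation is only efficient from the last
  state (slow-then-fast decay when ``delta_pre`` is small).

All rates are in 1/min and all times in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.special import gammaincc

__all__ = [
    "DecayChain",
    "LifetimeDistribution",
    "build_chain",
    "lifetime_from_chain",
    "lifetime_exponential",
    "lifetime_first_step",
    "lifetime_last_step",
    "phase_type_moment",
]

#: relative rate-difference below which degenerate-limit series are used
_DEGENERATE_RTOL = 1e-9


@dataclass(frozen=True)
class DecayChain:
    """A linear absorbing chain: states ``1..n`` plus the absorbing state 0.

    Parameters
    ----------
    n : int
        Number of transient states.
    omega : ndarray, shape (n-1,)
        Forward maturation rates, ``omega[i]`` taking state ``i+1`` to
        ``i+2`` (1-based states).
    delta : ndarray, shape (n,)
        Degradation rates into the absorbing state.
    initial_state : ndarray, shape (n,)
        Probability distribution of the birth state; defaults to mass 1 on
        state 1.
    """

    n: int
    omega: np.ndarray
    delta: np.ndarray
    initial_state: np.ndarray

    @property
    def subgenerator(self) -> np.ndarray:
        """The n-by-n sub-generator T over the transient states."""
        T = np.zeros((self.n, self.n))
        idx = np.arange(self.n)
        T[idx, idx] = -(np.append(self.omega, 0.0) + self.delta)
        if self.n > 1:
            T[idx[:-1], idx[:-1] + 1] = self.omega
        return T

    @property
    def exit_rates(self) -> np.ndarray:
        """Absorption-rate vector t0 (equals ``delta``)."""
        return self.delta

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "omega": self.omega.tolist(),
            "delta": self.delta.tolist(),
            "initial_state": self.initial_state.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecayChain":
        return build_chain(
            int(d["n"]),
            d["omega"],
            d["delta"],
            initial_state=d.get("initial_state"),
        )


def build_chain(
    n: int,
    omega: Sequence[float],
    delta: Sequence[float],
    initial_state: Sequence[float] | None = None,
) -> DecayChain:
    """Validate parameters and construct a :class:`DecayChain`.

    Raises
    ------
    ValueError
        On dimension mismatch, negative rates, an initial distribution that
        does not sum to one, or a chain from which absorption is impossible
        (zero degradation rate everywhere on the reachable suffix).
    """
    n = int(n)
    if n < 1:
        raise ValueError(f"chain length must be >= 1, got {n}")
    omega = np.asarray(omega, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if omega.shape != (n - 1,):
        raise ValueError(f"omega must have length n-1={n - 1}, got {omega.shape}")
    if delta.shape != (n,):
        raise ValueError(f"delta must have length n={n}, got {delta.shape}")
    if np.any(omega < 0) or np.any(delta < 0):
        raise ValueError("all rates must be non-negative")
    if initial_state is None:
        alpha = np.zeros(n)
        alpha[0] = 1.0
    else:
        alpha = np.asarray(initial_state, dtype=float)
        if alpha.shape != (n,):
            raise ValueError(f"initial_state must have length {n}")
        if np.any(alpha < 0) or abs(alpha.sum() - 1.0) > 1e-12:
            raise ValueError("initial_state must be a probability vector")

    # Absorption is certain iff, from every state with initial mass, some
    # delta_i > 0 is reachable before the particle gets stuck.  On a linear
    # chain the particle moves right, so walk each suffix.
    for start in np.nonzero(alpha > 0)[0]:
        i = start
        while True:
            if delta[i] > 0:
                break
            if i == n - 1 or omega[i] == 0:
                raise ValueError(
                    f"absorption impossible from state {start + 1}: no positive "
                    "degradation rate is reachable"
                )
            i += 1
    return DecayChain(n=n, omega=omega, delta=delta, initial_state=alpha)


@dataclass
class LifetimeDistribution:
    """Distribution of the molecule lifetime ``U`` (minutes).

    ``pdf``, ``cdf`` and ``survival`` accept scalars or arrays of times and
    are vectorised.  ``survival_tail_integral(t)`` returns
    ``int_t^inf survival(u) du`` and is used by the decay-pattern transform;
    it is analytic for every distribution built by this module.
    """

    pdf: Callable[[np.ndarray], np.ndarray]
    survival: Callable[[np.ndarray], np.ndarray]
    mean: float
    provenance: str
    survival_tail_integral: Callable[[np.ndarray], np.ndarray] | None = None
    chain: DecayChain | None = field(default=None, repr=False)

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        return 1.0 - self.survival(t)

    def moment(self, k: int) -> float:
        """k-th raw moment; exact if a chain representation is attached."""
        if self.chain is not None:
            return phase_type_moment(self.chain, k)
        from scipy.integrate import quad

        val, _ = quad(lambda u: u**k * float(self.pdf(u)), 0, np.inf, limit=400)
        return val


def phase_type_moment(chain: DecayChain, k: int) -> float:
    """E[U^k] = (-1)^k k! alpha T^{-k} 1 for the absorption time of a chain."""
    T = chain.subgenerator
    ones = np.ones(chain.n)
    v = ones
    for _ in range(k):
        v = np.linalg.solve(T, v)
    return float((-1) ** k * math.factorial(k) * chain.initial_state @ v)


def _nonneg_times(t) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return t


def _scalarize(out: np.ndarray, t) -> np.ndarray | float:
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def lifetime_from_chain(chain: DecayChain) -> LifetimeDistribution:
    """Phase-type lifetime of a chain via the matrix exponential.

    ``pdf(t) = alpha exp(T t) t0`` and ``survival(t) = alpha exp(T t) 1``;
    this is the brute-force reference against which all closed forms are
    checked.  Uses scaling-and-squaring (scipy ``expm``); chains are tiny so
    a per-time-point ``expm`` is cheap.
    """
    T = chain.subgenerator
    t0 = chain.exit_rates
    alpha = chain.initial_state
    ones = np.ones(chain.n)
    Tinv_ones = np.linalg.solve(T, ones)
    mean = float(-alpha @ Tinv_ones)

    def _front(t):
        ts = _nonneg_times(t)
        return np.stack([alpha @ expm(T * ti) for ti in ts])

    def pdf(t):
        return _scalarize(_front(t) @ t0, t)

    def survival(t):
        return _scalarize(_front(t) @ ones, t)

    def tail(t):
        # int_t^inf alpha exp(Tu) 1 du = -alpha T^{-1} exp(Tt) 1
        return _scalarize(-(_front(t) @ Tinv_ones), t)

    return LifetimeDistribution(
        pdf=pdf,
        survival=survival,
        mean=mean,
        provenance=f"phase_type(n={chain.n})",
        survival_tail_integral=tail,
        chain=chain,
    )


def lifetime_exponential(delta: float) -> LifetimeDistribution:
    """Exponential lifetime: every state degrades at the same rate.

    When all degradation rates coincide the absorption hazard is constant
    regardless of the maturation rates, so the lifetime is exponential with
    rate ``delta`` independently of the chain length.
    """
    delta = float(delta)
    if delta <= 0:
        raise ValueError("delta must be positive")
    chain = build_chain(1, [], [delta])

    def pdf(t):
        ts = _nonneg_times(t)
        return _scalarize(delta * np.exp(-delta * ts), t)

    def survival(t):
        ts = _nonneg_times(t)
        return _scalarize(np.exp(-delta * ts), t)

    def tail(t):
        ts = _nonneg_times(t)
        return _scalarize(np.exp(-delta * ts) / delta, t)

    return LifetimeDistribution(
        pdf=pdf,
        survival=survival,
        mean=1.0 / delta,
        provenance="exponential",
        survival_tail_integral=tail,
        chain=chain,
    )


def _phik(k: int, x: np.ndarray) -> np.ndarray:
    """phi_k(x) = (e^x - sum_{j<k} x^j/j!) / x^k = sum_m x^m/(m+k)!.

    Entire in x; evaluated by series near 0 to dodge cancellation.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < k + 1.0
    xs = x[small]
    acc = np.zeros_like(xs)
    term = np.full_like(xs, 1.0 / math.factorial(k))
    acc += term
    for m in range(1, 60):
        term = term * xs / (m + k)
        acc += term
    out[small] = acc
    xl = x[~small]
    if xl.size:
        s = np.zeros_like(xl)
        term = np.ones_like(xl)
        for j in range(k):
            if j > 0:
                term = term * xl / j
            s += term
        out[~small] = (np.exp(xl) - s) / xl**k
    return out


def lifetime_first_step(omega: float, delta1: float, delta2: float) -> LifetimeDistribution:
    """Lifetime with a distinct degradation rate in the birth state only.

    State 1 exits at total rate ``a = omega + delta1``; once past it the
    absorption hazard is ``delta2`` forever, so the distribution does not
    depend on the chain length (n >= 2).  The survival is the two-term
    mixture ``A e^{-a t} + B e^{-delta2 t}`` with ``B = omega/(a - delta2)``,
    evaluated through a series at the removable singularity
    ``a == delta2``.
    """
    omega, delta1, delta2 = float(omega), float(delta1), float(delta2)
    if min(omega, delta1, delta2) < 0:
        raise ValueError("rates must be non-negative")
    if delta1 <= 0 and delta2 <= 0:
        raise ValueError("at least one degradation rate must be positive")
    a = omega + delta1
    b = delta2
    c = a - b
    chain = build_chain(2, [omega], [delta1, delta2])
    degenerate = abs(c) < _DEGENERATE_RTOL * max(a, b, 1e-30)

    if degenerate:
        # a == b: survival = e^{-at}(1 + omega t)
        mean = 1.0 / a + omega / a**2

        def survival(t):
            ts = _nonneg_times(t)
            return _scalarize(np.exp(-a * ts) * (1.0 + omega * ts), t)

        def pdf(t):
            ts = _nonneg_times(t)
            return _scalarize(np.exp(-a * ts) * (delta1 + omega * b * ts), t)

        def tail(t):
            ts = _nonneg_times(t)
            val = np.exp(-a * ts) * ((1.0 + omega * ts) / a + omega / a**2)
            return _scalarize(val, t)

    else:
        if b == 0 and omega > 0:
            raise ValueError(
                "delta2 = 0 with omega > 0 leaves a non-degrading tail; "
                "absorption time has infinite mean"
            )
        B = omega / c  # 0 when omega == 0 (b == 0 then implies pure state-1 decay)
        A = 1.0 - B
        mean = 1.0 / a + (omega / a) / b if omega > 0 else 1.0 / a

        def survival(t):
            ts = _nonneg_times(t)
            return _scalarize(A * np.exp(-a * ts) + B * np.exp(-b * ts), t)

        def pdf(t):
            ts = _nonneg_times(t)
            # omega*b*(e^{-bt} - e^{-at})/c: stable for |c| away from 0
            val = delta1 * np.exp(-a * ts) + omega * b * (
                np.exp(-b * ts) - np.exp(-a * ts)
            ) / c
            return _scalarize(val, t)

        def tail(t):
            ts = _nonneg_times(t)
            out = A * np.exp(-a * ts) / a
            if B != 0.0:
                out = out + B * np.exp(-b * ts) / b
            return _scalarize(out, t)

    return LifetimeDistribution(
        pdf=pdf,
        survival=survival,
        mean=mean,
        provenance="first_step",
        survival_tail_integral=tail,
        chain=chain,
    )


def lifetime_last_step(
    omega: float, delta_pre: float, delta_last: float, n: int = 5
) -> LifetimeDistribution:
    """Lifetime with efficient degradation only from the terminal state.

    States ``1..n-1`` share degradation rate ``delta_pre`` (default use is
    0) and maturation rate ``omega``; state ``n`` degrades at ``delta_last``.
    With ``delta_pre = 0`` this is the convolution of an Erlang(n-1, omega)
    maturation time with an exponential(delta_last) terminal stage.
    """
    omega, delta_pre, delta_last = float(omega), float(delta_pre), float(delta_last)
    n = int(n)
    if n < 2:
        raise ValueError("last-step variant requires n >= 2")
    if min(omega, delta_pre, delta_last) < 0:
        raise ValueError("rates must be non-negative")
    if delta_last <= 0 and delta_pre <= 0:
        raise ValueError("at least one degradation rate must be positive")
    a = omega + delta_pre
    b = delta_last
    c = a - b
    chain = build_chain(n, [omega] * (n - 1), [delta_pre] * (n - 1) + [delta_last])
    if a == 0:
        raise ValueError("omega = delta_pre = 0: terminal state unreachable")

    k_pre = np.arange(n - 1)  # occupancy terms for states 1..n-1
    reach = (omega / a) ** (n - 1)  # probability of ever reaching state n
    if b == 0 and reach > 0:
        raise ValueError("delta_last = 0 traps reachable mass in the last state")
    # mean: time in pre-states + P(reach) * 1/b
    if delta_pre > 0:
        mean_pre = (1.0 - reach) / delta_pre
    else:
        mean_pre = (n - 1) / omega
    mean = mean_pre + (reach / b if reach > 0 else 0.0)

    def _occupancy_pre(ts):
        # P(alive in state k+1 at t) = (omega t)^k e^{-a t} / k!, per-term in
        # log space so extreme t cannot overflow the polynomial factor
        with np.errstate(divide="ignore"):
            logwt = np.where(ts > 0, np.log(np.maximum(omega * ts, 1e-300)), -np.inf)
        acc = np.exp(-a * ts)  # k = 0
        for k in k_pre[1:]:
            term = np.exp(k * logwt - math.lgamma(k + 1) - a * ts)
            acc += np.where(ts > 0, term, 0.0)
        return acc

    def _occupancy_last(ts):
        # P(alive in state n at t) = omega^{n-1} t^{n-1} e^{-at} phi_{n-1}(ct)
        # where phi_k(x) = (e^x - sum_{j<k} x^j/j!)/x^k.  Series for small
        # |ct|; for large |ct| the equivalent two-exponential form with every
        # term assembled in log space to dodge intermediate overflow.
        out = np.empty_like(ts)
        x = c * ts
        small = np.abs(x) < n  # series regime
        tss = ts[small]
        out[small] = (
            omega ** (n - 1) * tss ** (n - 1) * np.exp(-a * tss) * _phik(n - 1, x[small])
        )
        tsl = ts[~small]
        if tsl.size:
            log_pref = (n - 1) * (np.log(omega) - np.log(abs(c))) if omega > 0 else -np.inf
            sign_c = 1.0 if c > 0 else -1.0
            acc = np.exp(log_pref - b * tsl)
            logct = np.log(abs(c) * tsl)
            for j in range(n - 1):
                acc -= sign_c**j * np.exp(
                    log_pref - a * tsl + j * logct - math.lgamma(j + 1)
                )
            out[~small] = sign_c ** (n - 1) * acc
        return out

    def survival(t):
        ts = _nonneg_times(t)
        return _scalarize(_occupancy_pre(ts) + _occupancy_last(ts), t)

    def pdf(t):
        ts = _nonneg_times(t)
        return _scalarize(delta_pre * _occupancy_pre(ts) + b * _occupancy_last(ts), t)

    def tail(t):
        ts = _nonneg_times(t)
        # pre-state block: sum_k omega^k/a^{k+1} Q(k+1, a t)
        pre = sum(
            (omega**k / a ** (k + 1)) * gammaincc(k + 1, a * ts) for k in k_pre
        )
        # terminal block: omega^{n-1} sum_m c^m a^{-(n+m)} Q(n+m, a t),
        # the term-wise tail of the phi-series; geometric ratio c/a
        if abs(c) < 0.5 * a:
            last = np.zeros_like(ts)
            coeff = omega ** (n - 1) / a**n
            ratio = c / a
            term = np.full_like(ts, coeff)
            m = 0
            while True:
                last = last + term * gammaincc(n + m, a * ts)
                m += 1
                term = term * ratio
                if m > 200 or np.all(np.abs(term) < 1e-18 * coeff / (1 - abs(ratio))):
                    break
        else:
            # direct two-exponential form, safe when |a-b| is not small
            j_pre = np.arange(n - 1)
            s = sum(
                (c**j / a ** (j + 1)) * gammaincc(j + 1, a * ts) for j in j_pre
            )
            last = (omega / c) ** (n - 1) * (np.exp(-b * ts) / b - s)
        return _scalarize(pre + last, t)

    return LifetimeDistribution(
        pdf=pdf,
        survival=survival,
        mean=mean,
        provenance=f"last_step(n={n})",
        survival_tail_integral=tail,
        chain=chain,
    )
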