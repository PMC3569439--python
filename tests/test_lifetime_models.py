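"""Chain construction, the phase-type oracle, and the closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.linalg import expm

from mrnadecay.lifetime_models import (
    build_chain,
    lifetime_exponential,
    lifetime_first_step,
    lifetime_from_chain,
    lifetime_last_step,
    phase_type_moment,
)

from conftest import random_chain


def reference_pdf(chain, t):
    """Independent phase-type density: alpha e^{Tt} t0 assembled in-test."""
    n = chain.n
    T = np.zeros((n, n))
    for i in range(n):
        w = chain.omega[i] if i < n - 1 else 0.0
        T[i, i] = -(w + chain.delta[i])
        if i < n - 1:
            T[i, i + 1] = chain.omega[i]
    return float(chain.initial_state @ expm(T * t) @ chain.delta)


class TestBuildChain:
    def test_single_state_exponential_chain(self):
        c = build_chain(1, [], [0.1])
        assert c.n == 1
        assert np.allclose(c.subgenerator, [[-0.1]])

    def test_five_state_terminal_decay(self):
        c = build_chain(5, [0.5] * 4, [0, 0, 0, 0, 0.1])
        assert c.delta[-1] == 0.1
        assert np.allclose(np.diag(c.subgenerator), [-0.5] * 4 + [-0.1])

    def test_absorption_impossible_rejected(self):
        with pytest.raises(ValueError, match="absorption impossible"):
            build_chain(2, [0.5], [0, 0])

    def test_dead_end_before_exit_rejected(self):
        # omega chain broken before the only positive delta
        with pytest.raises(ValueError, match="absorption impossible"):
            build_chain(3, [0.5, 0.0], [0, 0, 0.1])

    @pytest.mark.parametrize(
        "n,omega,delta",
        [(2, [0.1, 0.2], [0.1, 0.1]), (2, [0.1], [0.1]), (1, [], [-0.1])],
    )
    def test_bad_dimensions_or_rates(self, n, omega, delta):
        with pytest.raises(ValueError):
            build_chain(n, omega, delta)

    def test_initial_state_must_be_distribution(self):
        with pytest.raises(ValueError, match="probability"):
            build_chain(2, [0.1], [0.1, 0.1], initial_state=[0.5, 0.4])

    def test_serialization_roundtrip(self):
        c = build_chain(3, [0.1, 0.2], [0.0, 0.1, 0.2])
        from mrnadecay.lifetime_models import DecayChain

        c2 = DecayChain.from_dict(c.to_dict())
        assert c2.n == c.n
        assert np.array_equal(c2.omega, c.omega)
        assert np.array_equal(c2.delta, c.delta)


class TestLifetimeFromChain:
    def test_single_state_is_exponential(self):
        lt = lifetime_from_chain(build_chain(1, [], [0.1]))
        assert lt.pdf(0.0) == pytest.approx(0.1)
        assert lt.survival(10.0) == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_two_state_mean_by_stage_decomposition(self):
        # state 1: mean sojourn 1/(omega+delta1); reach state 2 w.p.
        # omega/(omega+delta1), then exponential(delta2):
        # mean = 1/0.3 + (0.1/0.3)/0.02 = 20.0 min
        lt = lifetime_from_chain(build_chain(2, [0.1], [0.2, 0.02]))
        assert lt.mean == pytest.approx(20.0, rel=1e-12)

    def test_pdf_normalizes(self, rng):
        for _ in range(5):
            lt = lifetime_from_chain(random_chain(rng))
            total, _ = quad(lambda t: float(lt.pdf(t)), 0, np.inf, limit=300)
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_mean_equals_survival_integral(self, rng):
        for _ in range(5):
            lt = lifetime_from_chain(random_chain(rng))
            integral, _ = quad(lambda t: float(lt.survival(t)), 0, np.inf, limit=300)
            assert lt.mean == pytest.approx(integral, rel=1e-6)

    def test_cdf_properties(self, rng):
        lt = lifetime_from_chain(random_chain(rng))
        ts = np.linspace(0, 30 * lt.mean, 200)
        cdf = lt.cdf(ts)
        assert cdf[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(cdf) >= -1e-12)
        assert cdf[-1] == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(lt.survival(ts), 1 - cdf)


class TestExponential:
    def test_half_life_and_mean(self):
        lt = lifetime_exponential(math.log(2) / 10)
        assert lt.mean == pytest.approx(10 / math.log(2))
        assert lt.survival(10.0) == pytest.approx(0.5)
        assert lifetime_exponential(0.1).mean == pytest.approx(10.0)

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            lifetime_exponential(0.0)

    def test_equals_chain_with_equal_deltas_any_omega(self):
        # equal degradation rates in every state: maturation is irrelevant
        chain = build_chain(4, [0.7, 0.01, 2.3], [0.1] * 4)
        oracle = lifetime_from_chain(chain)
        lt = lifetime_exponential(0.1)
        ts = np.linspace(0, 100, 101)
        assert np.max(np.abs(oracle.pdf(ts) - lt.pdf(ts))) < 1e-8

    @given(
        n=st.integers(1, 8),
        delta=st.floats(0.01, 1.0),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=25, deadline=None)
    def test_n_independence_property(self, n, delta, seed):
        rng = np.random.default_rng(seed)
        omega = rng.uniform(0.0, 2.0, size=n - 1)
        chain = build_chain(n, omega, [delta] * n)
        ts = np.geomspace(0.01, 5 / delta, 20)
        expected = delta * np.exp(-delta * ts)
        got = np.array([reference_pdf(chain, t) for t in ts])
        assert np.max(np.abs(got - expected)) < 1e-8


class TestFirstStep:
    def test_pdf_at_zero_is_delta1(self):
        lt = lifetime_first_step(0.1, 0.2, 0.02)
        assert lt.pdf(0.0) == pytest.approx(0.2, rel=1e-12)

    def test_matches_phase_type_oracle(self):
        lt = lifetime_first_step(0.1, 0.2, 0.02)
        chain = build_chain(5, [0.1] * 4, [0.2, 0.02, 0.02, 0.02, 0.02])
        ts = np.concatenate([[0.0], np.geomspace(1e-3, 300, 60)])
        got = lt.pdf(ts)
        expected = np.array([reference_pdf(chain, t) for t in ts])
        assert np.max(np.abs(got - expected)) < 1e-8

    def test_reduces_to_exponential_when_rates_equal(self):
        lt = lifetime_first_step(0.3, 0.1, 0.1)
        exp = lifetime_exponential(0.1)
        ts = np.linspace(0, 80, 200)
        assert np.allclose(lt.pdf(ts), exp.pdf(ts), atol=1e-12)
        assert lt.mean == pytest.approx(exp.mean, rel=1e-12)

    @given(
        omega=st.floats(0.01, 1.0),
        delta1=st.floats(0.01, 1.0),
        delta2=st.floats(0.01, 1.0),
        n=st.integers(2, 8),
    )
    @settings(max_examples=25, deadline=None)
    def test_n_independence_property(self, omega, delta1, delta2, n):
        lt = lifetime_first_step(omega, delta1, delta2)
        chain = build_chain(n, [omega] * (n - 1), [delta1] + [delta2] * (n - 1))
        ts = np.geomspace(0.1, 5 * lt.mean, 15)
        got = np.atleast_1d(lt.pdf(ts))
        expected = np.array([reference_pdf(chain, t) for t in ts])
        assert np.max(np.abs(got - expected)) < 1e-8

    def test_degenerate_point_continuity(self):
        # omega + delta1 == delta2 is a removable singularity of the closed
        # form; it must agree with the oracle in a neighbourhood too
        omega, delta1 = 0.05, 0.05
        for eps in [0.0, 1e-12, -1e-12, 1e-7, -1e-7]:
            delta2 = omega + delta1 + eps
            lt = lifetime_first_step(omega, delta1, delta2)
            chain = build_chain(2, [omega], [delta1, delta2])
            for t in [0.5, 5.0, 50.0]:
                assert lt.pdf(t) == pytest.approx(reference_pdf(chain, t), abs=1e-6)

    def test_isolated_first_state_is_exponential(self):
        # omega = 0 (and delta2 irrelevant/zero): pure state-1 decay
        lt = lifetime_first_step(0.0, 0.25, 0.0)
        assert lt.mean == pytest.approx(4.0)
        assert lt.survival(4.0) == pytest.approx(math.exp(-1.0))
        assert lt.survival_tail_integral(0.0) == pytest.approx(4.0)

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError):
            lifetime_first_step(0.1, 0.0, 0.0)

    def test_trapped_mass_rejected(self):
        with pytest.raises(ValueError):
            lifetime_first_step(0.1, 0.2, 0.0)


class TestLastStep:
    def test_mean_is_sum_of_stage_means(self):
        lt = lifetime_last_step(0.5, 0.0, 0.1, n=5)
        assert lt.mean == pytest.approx(4 / 0.5 + 1 / 0.1, rel=1e-12)

    def test_pdf_zero_at_birth(self):
        # absorption requires reaching state n: zero density at t=0
        assert lifetime_last_step(0.5, 0.0, 0.1, n=5).pdf(0.0) == 0.0

    def test_matches_phase_type_oracle(self):
        lt = lifetime_last_step(0.5, 0.0, 0.1, n=5)
        chain = build_chain(5, [0.5] * 4, [0, 0, 0, 0, 0.1])
        ts = np.concatenate([[0.0], np.geomspace(1e-3, 10 * lt.mean, 60)])
        expected = np.array([reference_pdf(chain, t) for t in ts])
        assert np.max(np.abs(np.atleast_1d(lt.pdf(ts)) - expected)) < 1e-8

    def test_erlang_convolution_identity(self):
        # delta_pre=0: density is Erlang(n-1, omega) convolved with
        # exponential(delta_last); check against direct numeric convolution
        omega, b, n = 0.4, 0.08, 5
        lt = lifetime_last_step(omega, 0.0, b, n=n)
        for t in [1.0, 10.0, 40.0]:
            conv, _ = quad(
                lambda s: omega**4 * s**3 * np.exp(-omega * s) / 6 * b * np.exp(-b * (t - s)),
                0,
                t,
                limit=200,
            )
            assert lt.pdf(t) == pytest.approx(conv, rel=1e-9, abs=1e-12)

    def test_nonzero_delta_pre_matches_oracle(self):
        lt = lifetime_last_step(0.3, 0.01, 0.2, n=4)
        chain = build_chain(4, [0.3] * 3, [0.01, 0.01, 0.01, 0.2])
        ts = np.geomspace(0.01, 10 * lt.mean, 40)
        expected = np.array([reference_pdf(chain, t) for t in ts])
        assert np.max(np.abs(np.atleast_1d(lt.pdf(ts)) - expected)) < 1e-8

    def test_degenerate_rates_match_oracle(self):
        for eps in [0.0, 1e-12, 1e-7]:
            lt = lifetime_last_step(0.1, 0.0, 0.1 + eps, n=5)
            chain = build_chain(5, [0.1] * 4, [0, 0, 0, 0, 0.1 + eps])
            for t in [1.0, 20.0, 100.0]:
                assert lt.pdf(t) == pytest.approx(reference_pdf(chain, t), abs=1e-6)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            lifetime_last_step(0.5, 0.0, 0.1, n=1)


class TestMoments:
    def test_phase_type_moments_vs_quadrature(self):
        chain = build_chain(2, [0.1], [0.2, 0.02])
        lt = lifetime_from_chain(chain)
        for k in (1, 2, 3):
            mk, _ = quad(lambda t: t**k * float(lt.pdf(t)), 0, np.inf, limit=400)
            assert phase_type_moment(chain, k) == pytest.approx(mk, rel=1e-6)


def test_zoo_closed_forms_match_oracle(zoo_model, zoo_oracle):
    ts = np.concatenate([[0.0], np.geomspace(1e-3, 10 * zoo_model.mean, 50)])
    got = np.atleast_1d(zoo_model.pdf(ts))
    expected = np.atleast_1d(zoo_oracle.pdf(ts))
    assert np.max(np.abs(got - expected)) < 1e-8
    assert zoo_model.mean == pytest.approx(zoo_oracle.mean, rel=1e-10)
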