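import numpy as np
import pytest

from mrnadecay.lifetime_models import (
    build_chain,
    lifetime_exponential,
    lifetime_first_step,
    lifetime_from_chain,
    lifetime_last_step,
)

# representative parameter sets: an exponential decay, a fast-then-slow
# curve, and a slow-then-fast curve (rates in 1/min, as used throughout)
ZOO_PARAMS = {
    "exponential": dict(variant="exponential", delta=0.1),
    "fast_slow": dict(variant="first_step", omega=0.1, delta1=0.2, delta2=0.02),
    "slow_fast": dict(variant="last_step", omega=0.5, delta_pre=0.0, delta_last=0.1, n=5),
    "slow_fast_leaky": dict(variant="last_step", omega=0.3, delta_pre=0.01, delta_last=0.2, n=4),
    "near_degenerate": dict(variant="first_step", omega=0.05, delta1=0.05, delta2=0.1 - 1e-11),
}


def build_zoo_model(name):
    p = dict(ZOO_PARAMS[name])
    variant = p.pop("variant")
    if variant == "exponential":
        return lifetime_exponential(p["delta"])
    if variant == "first_step":
        return lifetime_first_step(p["omega"], p["delta1"], p["delta2"])
    return lifetime_last_step(p["omega"], p["delta_pre"], p["delta_last"], n=p["n"])


def matching_chain(name):
    """The explicit chain that generates each zoo model (oracle input)."""
    p = ZOO_PARAMS[name]
    if p["variant"] == "exponential":
        return build_chain(1, [], [p["delta"]])
    if p["variant"] == "first_step":
        n = 5  # any n >= 2 must give the same law
        return build_chain(n, [p["omega"]] * (n - 1), [p["delta1"]] + [p["delta2"]] * (n - 1))
    n = p["n"]
    return build_chain(n, [p["omega"]] * (n - 1), [p["delta_pre"]] * (n - 1) + [p["delta_last"]])


@pytest.fixture(params=list(ZOO_PARAMS), ids=list(ZOO_PARAMS))
def zoo_name(request):
    return request.param


@pytest.fixture
def zoo_model(zoo_name):
    return build_zoo_model(zoo_name)


@pytest.fixture
def zoo_oracle(zoo_name):
    """Matrix-exponential phase-type reference for the same parameters."""
    return lifetime_from_chain(matching_chain(zoo_name))


@pytest.fixture
def rng():
    return np.random.default_rng(20130211)


def random_chain(rng, n_max=8, allow_zero_delta=True):
    """A random valid linear chain for property-style sweeps."""
    n = int(rng.integers(1, n_max + 1))
    omega = rng.uniform(0.01, 1.0, size=n - 1)
    delta = rng.uniform(0.0, 0.5, size=n) if allow_zero_delta else rng.uniform(0.01, 0.5, size=n)
    delta[-1] = rng.uniform(0.01, 0.5)  # make absorption certain
    return build_chain(n, omega, delta)
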