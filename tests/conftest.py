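import numpy as np
import pytest

from mesord.network import (GridSpec, RateLaw, Reaction, ReactionNetwork,
                            SpeciesSpec, scale_network)
from mesord.ssa import compile_network


@pytest.fixture
def immigration_death():
    """0 -> A at rate a, A -> 0 at rate k; stationary law Poisson(a/k)."""
    a, k = 5.0, 0.5
    net = ReactionNetwork(
        species=[SpeciesSpec("A")],
        reactions=[
            Reaction({}, {"A": 1}, RateLaw("zeroth_order", a), "in"),
            Reaction({"A": 1}, {}, RateLaw("mass_action", k, 1), "out"),
        ],
        grid=GridSpec(1, 1))
    return net, a, k


@pytest.fixture
def compiled_immigration_death(immigration_death):
    net, a, k = immigration_death
    return compile_network(scale_network(net, 1.0)), a, k


@pytest.fixture
def diffusion_only_net():
    def make(D=1.0, nx=16, ny=16, lam=1.0, background=5.0):
        return ReactionNetwork(
            species=[SpeciesSpec("A", D, background)],
            reactions=[],
            grid=GridSpec(nx, ny, lam))
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
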