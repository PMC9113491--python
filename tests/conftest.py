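import numpy as np
import pytest

from phylosim import RateModel, build_model


def make_random_gtr(rng):
    """A randomly parameterized GTR model (exchangeabilities U(0.1, 5),
    Dirichlet(1,1,1,1) frequencies)."""
    exch = rng.uniform(0.1, 5.0, size=6)
    freqs = rng.dirichlet(np.ones(4))
    return build_model("GTR", params=exch, freqs=freqs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def jc():
    return build_model("JC")


@pytest.fixture
def gtr_factory():
    return make_random_gtr


@pytest.fixture
def moderate_gtr():
    """A fixed GTR instance without extreme parameters."""
    return build_model("GTR", params=(1.0, 2.0, 1.5, 0.8, 3.0, 1.0),
                       freqs=(0.3, 0.2, 0.2, 0.3))


@pytest.fixture(params=["none", "inv", "g4", "gc"])
def any_rate_model(request):
    return {
        "none": RateModel.constant(),
        "inv": RateModel.invariant(0.2),
        "g4": RateModel.discrete_gamma(0.5, 4),
        "gc": RateModel.continuous_gamma(0.5),
    }[request.param]
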