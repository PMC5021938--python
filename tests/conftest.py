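import numpy as np
import pytest

from tierscan.motif_models import (
    consensus_to_pssm,
    half_site_model,
    ideal_full_site_model,
    lenient_full_site_model,
)


@pytest.fixture(scope="session")
def ideal_model():
    return ideal_full_site_model()


@pytest.fixture(scope="session")
def lenient_model():
    return lenient_full_site_model()


@pytest.fixture(scope="session")
def hexamer_model():
    return half_site_model()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_model(rng, width, name="rand"):
    """A random strictly-positive probability model over a random background."""
    probs = rng.dirichlet(np.full(4, 0.5), size=width) + 1e-4
    probs /= probs.sum(axis=1, keepdims=True)
    bg = rng.dirichlet(np.full(4, 5.0)) + 0.05
    bg /= bg.sum()
    from tierscan.motif_models import MotifModel

    return MotifModel(name=name, probs=probs, background=bg)


@pytest.fixture
def make_random_model(rng):
    def _make(width, name="rand"):
        return random_model(rng, width, name)

    return _make


@pytest.fixture(scope="session")
def secondary_model():
    """A KLF-like GC-box secondary motif."""
    return consensus_to_pssm("GGGGCGGGG", 0.95, name="gcbox")
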