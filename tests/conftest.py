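import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def registry():
    from tcatrace.isotope import default_registry

    return default_registry()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_mid(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random valid MID of length n+1 (Dirichlet)."""
    return rng.dirichlet(np.ones(n + 1))
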