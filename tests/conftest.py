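import numpy as np
import pytest

from b3locus.synthetic import LocusSpec, generate_locus


@pytest.fixture(scope="session")
def default_locus():
    """The default synthetic locus at a fixed seed, shared across tests."""
    return generate_locus(LocusSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
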