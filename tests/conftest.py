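import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, max_examples=50)
settings.load_profile("repeatable")

from radiolysim import load_chemistry


@pytest.fixture(scope="session")
def chem():
    """The bundled pure-water 25 degC chemistry (9 reactions)."""
    return load_chemistry()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def e_aq_only():
    """Single-species pure-diffusion table (solvated electron)."""
    return load_chemistry(
        {
            "species": [{"name": "e_aq", "D": 4.9e-9, "charge": -1}],
            "reactions": [],
        }
    )


@pytest.fixture(scope="session")
def recombination_only():
    """All species, but only e_aq + e_aq -> 2 OH- + H2."""
    from radiolysim.benchmarks import electron_recombination_chemistry

    return electron_recombination_chemistry()
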