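import numpy as np
import pytest
from hypothesis import settings

from symscan import GeneratorSpec, ScanConfig, make_cyclic, make_helical, make_random_coil

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cfg():
    return ScanConfig()


@pytest.fixture(scope="session")
def c4_trace():
    """Noise-free closed ring with exact 4-fold symmetry, N = 80."""
    return make_cyclic(GeneratorSpec(kind="cyclic", n_units=4, unit_length=20))


@pytest.fixture(scope="session")
def c8_trace():
    return make_cyclic(GeneratorSpec(kind="cyclic", n_units=8, unit_length=12))


@pytest.fixture(scope="session")
def solenoid_trace():
    """Open 8-unit solenoid, rise 4.8 Å, twist 100° per unit."""
    return make_helical(
        GeneratorSpec(kind="helical", n_units=8, unit_length=20, rise=4.8, twist_deg=100.0)
    )


@pytest.fixture()
def coil_factory():
    def make(n_residues: int, seed: int):
        return make_random_coil(
            GeneratorSpec(kind="random_coil", n_units=1, unit_length=n_residues, seed=seed)
        )

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
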