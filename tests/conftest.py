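import numpy as np
import pytest

from vasodose import masses
from vasodose.lobule import LobuleSpec, build_hexagonal_lobule


@pytest.fixture(scope="session")
def male_masses() -> masses.MassTable:
    return masses.reference_mass_table("male")


@pytest.fixture(scope="session")
def female_masses() -> masses.MassTable:
    return masses.reference_mass_table("female")


@pytest.fixture(scope="session")
def small_lobule_spec() -> LobuleSpec:
    # reduced lobule: same targets, smaller prism -> fast builds in tests
    return LobuleSpec(side_um=150.0, height_um=150.0, layer_spacing_um=30.0, canaliculus_radius_um=4.5, seed=3)


@pytest.fixture(scope="session")
def small_lobule(small_lobule_spec):
    return build_hexagonal_lobule(small_lobule_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
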