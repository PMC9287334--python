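import numpy as np
import pytest

from orbinet.ct_io import CTVolume
from orbinet.phantom import PhantomParams, generate_phantom
from orbinet.preprocessing import preprocess_case


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    """Shrunken phantom geometry for fast unit tests (not the default world)."""
    return PhantomParams(
        grid_shape=(48, 48, 32),
        globe_radius_mm=6.0,
        eom_base_radius_mm=1.4,
        orbit_offset_mm=8.0,
        cavity_semiaxes_mm=(7.0, 10.0, 7.0),
        bone_thickness_mm=2.0,
        eom_offset_mm=3.5,
        proptosis_mm={"control": 0.0, "mild": 1.0, "moderate_severe": 3.0},
    )


@pytest.fixture(scope="session")
def small_volume(small_params) -> CTVolume:
    return generate_phantom("control", small_params, np.random.default_rng(0))


@pytest.fixture(scope="session")
def small_planeset(small_volume):
    return preprocess_case(small_volume, label="control")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
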