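import numpy as np
import pytest

from mpcalcium import mc_transport as mt


@pytest.fixture(scope="session")
def beam_1mm():
    return mt.BeamGeometry(z_focus_um=1000.0, fov_diameter_um=230.0)


@pytest.fixture(scope="session")
def geom_default():
    return mt.SimulationGeometry()


@pytest.fixture(scope="session")
def absorption_1320(beam_1mm, geom_default):
    """Shared 1320-nm transport run: 1 mm focus, 230 μm FOV."""
    return mt.simulate(
        beam_1mm, geom_default, mt.tissue_for_wavelength(1320),
        n_photons=150_000, seed=11,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
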