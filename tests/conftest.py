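import numpy as np
import pytest

from ntk.mechanics import INDENTER_CATALOG, MediumSpec
from ntk.stacks import AxialProfile, ZStack


@pytest.fixture
def si3n4():
    return INDENTER_CATALOG["si3n4_1_32"]


@pytest.fixture
def wc():
    return INDENTER_CATALOG["wc_1_8"]


@pytest.fixture
def water():
    return MediumSpec()


def make_boxcar_profile(
    n_slices: int = 150,
    lo: int = 20,
    hi: int = 120,
    intensity: float = 1000.0,
    step_um: float = 1.0,
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> AxialProfile:
    """Profile of a slab occupying slices lo..hi inclusive."""
    y = np.zeros(n_slices)
    y[lo : hi + 1] = intensity
    if noise_cv > 0:
        assert rng is not None
        y = y * (1.0 + noise_cv * rng.standard_normal(n_slices))
    return AxialProfile(
        z_positions=np.arange(n_slices) * step_um, mean_intensity=y, channel="green"
    )


def make_flat_bead_stack(
    nz: int = 100,
    ny: int = 32,
    nx: int = 32,
    surface_um: float = 120.0,
    z_step_um: float = 2.0,
    bead_intensity: float = 3000.0,
    sigma_um: float = 2.0,
) -> ZStack:
    """Stack with an empty green channel and a flat bead layer in red."""
    z = (np.arange(nz) * z_step_um)[:, None, None]
    red = bead_intensity * np.exp(-0.5 * ((z - surface_um) / sigma_um) ** 2)
    red = np.broadcast_to(red, (nz, ny, nx)).copy()
    green = np.zeros((nz, ny, nx))
    return ZStack(green=green, red=red, xy_pixel_size=16.0, z_step_nominal=z_step_um)
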