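import numpy as np
import pytest

from memfish import (
    LocalizationModel,
    NoiseModel,
    distance_field,
    generate_geometry,
)

ISO_VOXEL = (0.1, 0.1, 0.1)
ANISO_VOXEL = (0.2, 0.1, 0.1)


def snr_noise(amplitude: float, snr: float) -> NoiseModel:
    """Gaussian-only noise model with peak SNR = amplitude / sd."""
    return NoiseModel(poisson=False, gaussian_sd=amplitude / snr, baseline=100.0)


NOISELESS = NoiseModel(poisson=False, gaussian_sd=0.0, baseline=0.0)


@pytest.fixture(scope="session")
def sphere():
    """Single-cell digital sphere of radius 30 voxels, isotropic 0.1 µm."""
    geom = generate_geometry(1, (65, 65, 65), ISO_VOXEL, seed=7, semi_axes_um=(3.0, 3.0, 3.0))
    field = distance_field(geom.label_volume, geom.voxel_size)
    return geom, field


@pytest.fixture(scope="session")
def embryo4():
    """Four-cell embryo at realistic anisotropic spacing."""
    geom = generate_geometry(4, (32, 192, 192), ANISO_VOXEL, seed=11)
    field = distance_field(geom.label_volume, geom.voxel_size)
    return geom, field


@pytest.fixture(scope="session")
def box_cell():
    """Single large cell for detection benchmarks, kept clear of the stack
    borders (edge slices distort band-pass maxima, as on real stacks)."""
    geom = generate_geometry(
        1, (28, 160, 160), ANISO_VOXEL, seed=3, semi_axes_um=(2.2, 7.3, 7.3)
    )
    field = distance_field(geom.label_volume, geom.voxel_size)
    return geom, field


@pytest.fixture(scope="session")
def embryo4_full():
    """Full-size four-cell stack (the default simulated world)."""
    geom = generate_geometry(4, (40, 256, 256), ANISO_VOXEL, seed=21)
    field = distance_field(geom.label_volume, geom.voxel_size)
    return geom, field


@pytest.fixture
def uniform_model():
    return LocalizationModel(mode="uniform")
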