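import numpy as np
import pytest

from calvapit.phantom import PhantomSpec, PorosityFeature, generate_phantom
from calvapit.volio import BinaryMask, VoxelVolume

VOX = 7.5


def make_volume(data, voxel_size_um=VOX):
    return VoxelVolume(np.asarray(data), voxel_size_um)


def make_mask(data, voxel_size_um=VOX):
    return BinaryMask(np.asarray(data, dtype=bool), voxel_size_um)


def small_phantom(seed=1, noise_sd=10.0, blur_sigma_um=5.0, n_pits=2, n_channels=1):
    """A compact two-pit, one-channel phantom for unit tests (40x96x96)."""
    spec = PhantomSpec(
        shape=(40, 96, 96),
        plate_curvature=15.0,
        noise_sd=noise_sd,
        blur_sigma_um=blur_sigma_um,
        seed=seed,
    )
    pits = [(240.0, 240.0, 50.0, 50.0), (480.0, 480.0, 40.0, 40.0)][:n_pits]
    channels = [
        PorosityFeature(center_um=(0.0, 240.0, 540.0), channel_radius_um=15.0)
    ][:n_channels]
    return generate_phantom(spec, pits, channels)


@pytest.fixture(scope="session")
def small_phantom_noisy():
    return small_phantom()


@pytest.fixture(scope="session")
def small_phantom_clean():
    return small_phantom(noise_sd=0.0, blur_sigma_um=0.0)
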