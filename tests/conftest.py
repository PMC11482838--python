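import numpy as np
import pytest

from motorsym.models import default_protomer
from motorsym.phantom import (
    MotorPhantomSpec,
    RingComponent,
    RingLatticeSpec,
    make_standard_phantom,
)
from motorsym.cylinder import resample_cylindrical


def single_ring_phantom(
    n: int,
    radius: float = 44.0,
    box_size: int = 64,
    voxel_size: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    phase: float = 0.0,
    protomer_scale: float = 1.0,
):
    """Noise-controlled phantom with one protomer ring, for sweeps."""
    spec = MotorPhantomSpec(
        [
            RingComponent(
                RingLatticeSpec(n, radius, 0.0, phase=phase),
                default_protomer(scale=protomer_scale),
            )
        ],
        box_size=box_size,
        voxel_size=voxel_size,
        noise_sd=noise_sd,
        seed=seed,
    )
    from motorsym.phantom import make_motor_phantom

    return make_motor_phantom(spec)


@pytest.fixture(scope="session")
def c17_phantom():
    """Noise-free 64^3 C17 single-ring phantom."""
    return single_ring_phantom(17)


@pytest.fixture(scope="session")
def standard_phantom_cyl():
    """Standard multi-symmetry phantom (192^3, SNR 0.5, fixed seed) plus its
    cylindrical resampling and named annuli — shared by the acceptance
    checks to avoid regenerating a large volume per test."""
    vol, annuli = make_standard_phantom(seed=20231009, snr=0.5)
    cmap = resample_cylindrical(vol, 256)
    return vol, cmap, annuli


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
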