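import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import beamprobe as bp

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> bp.AcquisitionConfig:
    """Desk-scale acquisition: 64 elements, 1024 samples, 0.5 mm grid."""
    return bp.default_config(
        n_elements=64, n_samples=1024, grid_spacing=0.5e-3, z_min=5e-3, z_max=30e-3
    )


@pytest.fixture(scope="session")
def speckle_base(small_cfg):
    """Low-density speckle acquisition plus its DAS image (memorizer store)."""
    phantom = bp.make_speckle_phantom(
        region=(-5e-3, 5e-3, 12e-3, 20e-3), density=50e6, seed=7
    )
    data = bp.simulate_channel_data(
        phantom,
        small_cfg.geometry,
        small_cfg.sampling_rate,
        small_cfg.sound_speed,
        small_cfg.n_samples,
        seed=7,
    )
    stored = bp.beamform_das(data, small_cfg.geometry, small_cfg.grid)
    return data, stored


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
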