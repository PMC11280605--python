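from types import SimpleNamespace

import numpy as np
import pytest

from cestrecon import (
    FrequencyGrid,
    Pool,
    ZSpectrumParams,
    build_phantom,
    encode_kspace,
    grid_from_spec,
    phase_series,
    preset_spec,
    synthesize_series,
)

# Brain-like truth line parameters shared across tests: water dip depth
# 0.999 with Γ = 4e4 Hz² and one CEST pool at 450 Hz (b = 0.12, σ = 150 Hz).
WATER_A = 0.999 * 4.0e4
WATER_GAMMA = 4.0e4
POOL = Pool(450.0, 0.12, 150.0)


@pytest.fixture(scope="session")
def grid51() -> FrequencyGrid:
    """The 51-offset schedule: −1250..1250 Hz step 50, reference at −1250."""
    return FrequencyGrid(np.arange(-1250.0, 1251.0, 50.0), 0, 0.0, (450.0,))


@pytest.fixture(scope="session")
def truth_params() -> ZSpectrumParams:
    return ZSpectrumParams(WATER_A, WATER_GAMMA, (POOL,))


@pytest.fixture(scope="session")
def water_only_params() -> ZSpectrumParams:
    return ZSpectrumParams(WATER_A, WATER_GAMMA, ())


def _make_phantom(shape):
    spec = preset_spec("simulated_brain", shape)
    scene = build_phantom(spec)
    grid = grid_from_spec(spec)
    images = synthesize_series(scene, grid)
    phase = phase_series(scene, grid)
    ks = encode_kspace(images, phase)
    return SimpleNamespace(spec=spec, scene=scene, grid=grid, images=images,
                           phase=phase, ks=ks)


@pytest.fixture(scope="session")
def brain64():
    """Noiseless two-compartment 64×64 phantom acquisition."""
    return _make_phantom((64, 64))


@pytest.fixture(scope="session")
def brain128():
    """Noiseless two-compartment 128×128 phantom acquisition."""
    return _make_phantom((128, 128))
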