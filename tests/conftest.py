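"""Shared fixtures: small phantoms, scan patterns and volumes.

Everything is generated programmatically at session scope so the expensive
renders are shared across test modules.  Scan sizes are reduced relative to
the clinical defaults; the geometry (FOV, pitches, timing fractions) is
unchanged.
"""

import numpy as np
import pytest

from roboct.acquisition import NoiseConfig, acquire, make_scan_pattern
from roboct.phantom import build_phantom

SMALL_VOLUME_KW = dict(n_ascans_per_bscan=300, n_bscans=60)


@pytest.fixture(scope="session")
def healthy_phantom():
    return build_phantom(seed=1)


@pytest.fixture(scope="session")
def small_pattern():
    return make_scan_pattern("volume", **SMALL_VOLUME_KW)


@pytest.fixture(scope="session")
def still_noiseless_volume(healthy_phantom, small_pattern):
    return acquire(
        healthy_phantom, None, small_pattern,
        noise=NoiseConfig(speckle=False, noise_floor_sd=0.0),
        seed=0, n_depth=512,
    )


@pytest.fixture(scope="session")
def still_speckle_volume(healthy_phantom, small_pattern):
    return acquire(healthy_phantom, None, small_pattern, seed=0, n_depth=512)


@pytest.fixture(scope="session")
def clean_bscan(healthy_phantom):
    """Noiseless structured B-scan used as the registration test target."""
    pat = make_scan_pattern("repeated_bscan", n_ascans_per_bscan=200, n_bscans=1)
    vol = acquire(
        healthy_phantom, None, pat,
        noise=NoiseConfig(speckle=False, noise_floor_sd=0.0), n_depth=256,
    )
    img = vol.intensity[:, :, 0]
    return img / img.max()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
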