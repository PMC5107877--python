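"""Shared fixtures: phantoms are generated once per session and reused."""

import numpy as np
import pytest

import coroseg as cs


@pytest.fixture(scope="session")
def default_noiseless():
    """Default cardiac phantom without noise: (spec, volume, heart, vessel)."""
    spec = cs.default_phantom_spec(noise_sd_hu=0.0, rng_seed=0)
    vol, heart, vessel = cs.make_cardiac_phantom(spec)
    return spec, vol, heart, vessel


@pytest.fixture(scope="session")
def default_response(default_noiseless):
    """Multiscale vesselness response of the default noiseless phantom."""
    _, vol, heart, _ = default_noiseless
    return cs.multiscale_vesselness(vol, heart, cs.VesselnessParams())


@pytest.fixture(scope="session")
def default_seeds(default_noiseless, default_response):
    _, vol, _, _ = default_noiseless
    return cs.detect_seeds(vol, default_response, cs.SeedDetectionParams())


@pytest.fixture(scope="session")
def registration_spec():
    """Heart-sized registration phantom spec: 64^3 at 1 mm, textured tissue."""
    spec = cs.PhantomSpec(shape=(64, 64, 64), spacing=(1.0, 1.0, 1.0),
                          noise_sd_hu=5.0, rng_seed=3,
                          heart_semiaxes_mm=(22.0, 22.0, 20.0),
                          blood_pool_semiaxes_mm=(7.0, 7.0, 7.0),
                          texture_sd_hu=40.0,
                          vessel_centerlines=[], vessel_radius_mm=[])
    c = spec.center_mm()
    t = np.linspace(-1, 1, 31)
    curve = np.stack([c[0] + 14 * np.cos(t), c[1] + 14 * np.sin(t),
                      c[2] + 8 * t], axis=1)
    spec.vessel_centerlines = [curve]
    spec.vessel_radius_mm = [2.5]
    spec.stenoses = [[]]
    spec.__post_init__()
    return spec


@pytest.fixture(scope="session")
def registration_phantom(registration_spec):
    vol, heart, vessel = cs.make_cardiac_phantom(registration_spec)
    return vol, heart, vessel


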