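import numpy as np
import pytest

from ceboost.phantom import Box, PhantomSpec, VesselSpec


def compact_spec(**overrides) -> PhantomSpec:
    """Small, fast phantom for unit tests: one vessel, both compartments.

    36 x 36 mm in-plane so the 100 mm^2 fat/muscle ROIs fit with margin.
    """
    base = dict(
        shape=(16, 72, 72),
        spacing=(0.5, 0.5, 0.5),
        fat_region=Box((1.0, 2.0, 20.0), (15.0, 16.0, 34.0)),
        muscle_region=Box((1.0, 20.0, 20.0), (15.0, 34.0, 34.0)),
        vessels=[VesselSpec((-2.0, 10.0, 8.0), (10.0, 10.0, 8.0), 1.5, label="V1")],
        seed=0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, unblurred compact phantom (exact-value oracle)."""
    from ceboost.phantom import make_phantom

    spec = compact_spec(noise_sigma_hu=0.0, blur_sigma_mm=0.0)
    pre, enhanced, truth = make_phantom(spec)
    return spec, pre, enhanced, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Compact phantom with 10 HU noise, no blur (noise-statistics oracle)."""
    from ceboost.phantom import make_phantom

    spec = compact_spec(noise_sigma_hu=10.0, blur_sigma_mm=0.0, seed=7)
    pre, enhanced, truth = make_phantom(spec)
    return spec, pre, enhanced, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
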