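import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mpqmri.fitting import apply_signal_threshold
from mpqmri.phantom import (
    PhantomSpec,
    default_tumor_geometry,
    generate_phantom,
    synthesize_acquisitions,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small three-class digital tumor with noiseless series and a fit mask."""
    shape = (24, 24, 8)
    spec = PhantomSpec(
        grid_shape=shape,
        tumor_geometry=default_tumor_geometry(shape),
        noise_sigma=0.0,
        target_snr=None,
        seed=0,
    )
    vols = generate_phantom(spec)
    series = synthesize_acquisitions(vols)
    excluded = apply_signal_threshold(series["dwi_adc"], noise_sd=5.0, k=3.0)
    fit_mask = vols.tumor_mask & ~excluded
    return vols, series, fit_mask


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
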