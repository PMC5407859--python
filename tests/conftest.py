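import numpy as np
import pytest

from hairbundle.synthetic import (
    BundleSpec,
    NoiseSpec,
    TreatmentSpec,
    default_bundle_spec,
    generate_bundle,
    standard_views,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ohc_spec():
    return default_bundle_spec("OHC")


@pytest.fixture
def small_bundle(ohc_spec):
    """One seeded control OHC bundle (10 per ranked row plus supernumerary)."""
    return generate_bundle(ohc_spec, seed=7, bundle_id="b0")


@pytest.fixture
def noise_free():
    return NoiseSpec(projection_noise_cv=0.0, diameter_noise_sd=0.0, seed=0)


@pytest.fixture
def views(ohc_spec):
    return standard_views(ohc_spec.insertion_tilt_alpha)
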