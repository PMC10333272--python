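import numpy as np
import pytest

from slice3bc import PhantomSpec, CohortSpec, make_slice_phantom, make_cohort


@pytest.fixture(scope="session")
def clean_spec() -> PhantomSpec:
    """Noise-free elliptical phantom with a 20 mm fat ring."""
    return PhantomSpec()


@pytest.fixture(scope="session")
def clean_phantom(clean_spec):
    return make_slice_phantom(clean_spec, seed=0)


@pytest.fixture(scope="session")
def blob_spec() -> PhantomSpec:
    """Phantom with two visceral fat blobs and mild noise."""
    return PhantomSpec(noise_sd=40.0,
                       visceral_blobs=(((30.0, 10.0), 15.0),
                                       ((-40.0, -20.0), 12.0)))


@pytest.fixture(scope="session")
def default_cohort():
    """One reference-condition cohort draw (n = 310)."""
    return make_cohort(CohortSpec(), seed=0)
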