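import numpy as np
import pytest

from trajbench import cohort_simulator as cs
from trajbench import reference_profiles as rp


@pytest.fixture(scope="session")
def prepared_reference():
    """A prepared (complete, median-normalized) 16-point BMI-like reference."""
    return rp.generate_synthetic_references("bmi", n_refs=1, length=16, seed=42)[0].prepared()


@pytest.fixture(scope="session")
def poly_fit(prepared_reference):
    return cs.fit_poly10(prepared_reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
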