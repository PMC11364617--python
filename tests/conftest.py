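import numpy as np
import pytest

from kneemark.phantom import generate_cohort


@pytest.fixture(scope="session")
def small_axial_cohort():
    """Six trochlear-sulcus phantoms with their ground-truth index table."""
    return generate_cohort(6, seed=41, protocol="trochlear_sulcus")


@pytest.fixture(scope="session")
def small_knee_cohort():
    """Four full knees (three protocol slices each) with ground truth."""
    return generate_cohort(4, seed=42, protocol=None)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
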