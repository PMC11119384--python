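import numpy as np
import pytest

from wmhkit.segmentation import compute_brain_mask
from wmhkit.synthetic import CohortSpec, PhantomSpec, generate_brain_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom with its truth masks and derived brain mask."""
    flair, truth, icv, excl = generate_brain_phantom(PhantomSpec(seed=7))
    return {
        "flair": flair,
        "truth_wmh": truth,
        "truth_icv": icv,
        "exclusions": excl,
        "brain": compute_brain_mask(flair),
    }


@pytest.fixture(scope="session")
def small_cohort():
    from wmhkit.synthetic import generate_cohort

    return generate_cohort(CohortSpec(n_lis=200, n_dich=120, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
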