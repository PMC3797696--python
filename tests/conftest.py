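import numpy as np
import pytest

from chromolens.presets import REFERENCE_COHORT_ROWS
from chromolens.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def reference_cohort():
    """Synthetic cohort generated from the reference 13-diagnosis layout."""
    return generate_cohort(CohortConfig(seed=42, rows=list(REFERENCE_COHORT_ROWS)))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
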