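import numpy as np
import pytest

from pascl import synth


@pytest.fixture(scope="session")
def small_cohort() -> synth.Cohort:
    """A small two-system cohort under the default study conditions."""
    spec = synth.CohortSpec(n_patients_per_system=(8, 6), seed=7)
    return synth.generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort() -> synth.Cohort:
    """The full default cohort (12 + 10 patients)."""
    return synth.generate_cohort(synth.CohortSpec(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
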