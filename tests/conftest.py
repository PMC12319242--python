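import numpy as np
import pytest

from tacfis.io import pk_frame
from tacfis.pipeline import features_from_pk
from tacfis.synthetic import GeneratorConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-patient default-parameter cohort shared across tests."""
    return simulate_cohort(GeneratorConfig().scaled(200), seed=42)


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    pk = pk_frame(small_cohort.pk)
    cdr, weekly, quartiles = features_from_pk(pk)
    return pk, cdr, weekly, quartiles


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
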