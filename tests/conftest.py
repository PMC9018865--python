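import numpy as np
import pytest

from combinet.measures import DoseResponseSeries
from combinet.synthetic import CohortSpec, generate_annotations, generate_responses

HALF_LOG_DOSES = 10.0 * 10.0 ** (0.5 * np.arange(7))


def make_series(responses, doses=None, drug="D", sample="S"):
    responses = np.asarray(responses, dtype=float)
    if doses is None:
        doses = 10.0 * 10.0 ** (0.5 * np.arange(len(responses)))
    return DoseResponseSeries(drug_id=drug, sample_id=sample,
                              doses=np.asarray(doses, float), responses=responses)


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(seed=11, n_drugs=12, n_samples=12)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    responses, truth = generate_responses(small_spec)
    return responses, truth


@pytest.fixture(scope="session")
def small_annotations(small_spec):
    return generate_annotations(small_spec)
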