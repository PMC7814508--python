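import numpy as np
import pytest

from ecgmotif import CohortSpec, Heartbeat, make_cohort, prepare_cohort_beats


def make_beats(vectors, labels=None, patient_id="p"):
    """Build Heartbeat objects from an array of vectors for unit tests."""
    vectors = np.asarray(vectors, dtype=float)
    if labels is None:
        labels = ["N"] * len(vectors)
    W = vectors.shape[1]
    return [
        Heartbeat(patient_id=patient_id, window_index=i, vector=v, label=lab,
                  start_sample=i * W)
        for i, (v, lab) in enumerate(zip(vectors, labels))
    ]


@pytest.fixture(scope="session")
def default_cohort_beats():
    """The default heterogeneous 8-patient synthetic cohort, segmented and labeled."""
    return prepare_cohort_beats(make_cohort(CohortSpec()))


@pytest.fixture(scope="session")
def small_cohort_beats():
    """A quick 3-patient cohort for pipeline-level tests."""
    spec = CohortSpec(n_patients=3, duration_min=2.0, seed=7)
    return prepare_cohort_beats(make_cohort(spec))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
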