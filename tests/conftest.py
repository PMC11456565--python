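import numpy as np
import pytest

from turnload import pipeline, screening
from turnload.models import TrainConfig
from turnload.synthetic import make_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """Six simulated subjects flying the default plan (shared across tests)."""
    return make_dataset(6, seed=11)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """Pooled labeled feature table + segmentation check for the small cohort."""
    features, seg_check = pipeline.process_subjects(small_cohort)
    return features, seg_check


@pytest.fixture(scope="session")
def screened(small_features):
    features, _ = small_features
    results = screening.screen_features(features)
    return results, screening.select_features(results)
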