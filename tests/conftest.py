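import dataclasses

import numpy as np
import pytest

from gliograd.hog import HogConfig, extract_subject
from gliograd.preprocess import zscore_normalize
from gliograd.synthetic import CohortSpec, PhantomSpec, generate_cohort


@pytest.fixture(scope="session")
def detection_cohort():
    """Small lesioned-vs-control cohort shared by the slower tests."""
    base = PhantomSpec(lesion_present=True)
    cohort = CohortSpec(n_per_class=6, task="detection", base_spec=base, seed=11)
    volumes, specs = generate_cohort(cohort)
    return volumes, specs, cohort


@pytest.fixture(scope="session")
def detection_descriptors(detection_cohort):
    volumes, specs, _ = detection_cohort
    config = HogConfig(cell_size=10)
    descs = [extract_subject(zscore_normalize(v), config) for v in volumes]
    labels = np.array([v.label for v in volumes])
    return descs, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
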