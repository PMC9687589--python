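"""Shared fixtures: one synthetic subject and its extracted feature vector."""

import numpy as np
import pytest

from epicon.config import PipelineConfig
from epicon.montage import MontageLayout
from epicon.pipeline import extract_subject_features
from epicon.synthetic import CohortSpec, generate_subject_eeg


@pytest.fixture(scope="session")
def layout() -> MontageLayout:
    return MontageLayout()


@pytest.fixture(scope="session")
def subject_spec() -> CohortSpec:
    return CohortSpec(n_subjects=2, duration_s=120.0, effect_size=2.0, seed=1)


@pytest.fixture(scope="session")
def synthetic_subject(subject_spec):
    """One positive-class 120 s recording, fixed seed."""
    return generate_subject_eeg(subject_spec, "focal_lesional", seed=42)


@pytest.fixture(scope="session")
def subject_features(synthetic_subject):
    """The full 784-entry feature vector of the fixture subject."""
    return extract_subject_features(synthetic_subject.recording,
                                    PipelineConfig(), seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
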