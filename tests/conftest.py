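"""Shared fixtures.

The expensive fixtures (feature matrices of full-length synthetic cohorts)
are session-scoped: EMD of a 30-minute 20 Hz record takes under a second,
but a 100-record cohort adds up, and several end-to-end tests share the
same cohorts.
"""

import numpy as np
import pytest

from ehgemd.entropy_features import build_feature_matrix
from ehgemd.signal_io import EHGRecord
from ehgemd.synth_data import SynthConfig, generate_cohort, generate_record


@pytest.fixture(scope="session")
def strong_cohort_matrix():
    """Channel-3 feature matrix of a (50, 50) cohort with a strong class effect."""
    cfg = SynthConfig(seed=7, class_effect="strong")
    return build_feature_matrix(generate_cohort(cfg, 50, 50), channel_index=3)


@pytest.fixture(scope="session")
def null_cohort_matrix():
    """Feature matrix of a (50, 50) cohort with no class effect."""
    cfg = SynthConfig(seed=11, class_effect="none")
    return build_feature_matrix(generate_cohort(cfg, 50, 50), channel_index=3)


@pytest.fixture(scope="session")
def default_record():
    """One default-scale (30-min, 3-channel) synthetic term record."""
    return generate_record(SynthConfig(seed=3), "term")


@pytest.fixture()
def small_record():
    """A short 3-channel record for cheap I/O and plumbing tests."""
    rng = np.random.default_rng(0)
    return EHGRecord(
        samples=rng.standard_normal((3, 5000)),
        fs=20.0,
        gestation_at_delivery=40.0,
        record_id="small",
    )
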