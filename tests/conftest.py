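import numpy as np
import pytest

from neuroictal import (DEFAULT_MASTER_SEED, Recording, SessionSpec,
                        extract_cohort_features, make_cohort)
from neuroictal.eeg_data import AnnotationInterval


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_recording(rng):
    """60 s, 4-channel, 100 Hz recording with one 20 s seizure interval."""
    fs = 100.0
    n = int(60 * fs)
    sig = rng.normal(size=(4, n))
    return Recording(
        subject_id="T01", session_id="T01-a", signal=sig, fs=fs,
        channel_names=["c1", "c2", "c3", "c4"],
        annotations=[AnnotationInterval(30.0, 50.0, "seizure")],
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The shipped default synthetic cohort: 5 subjects x 3 sessions."""
    return make_cohort(5, 3, DEFAULT_MASTER_SEED)


@pytest.fixture(scope="session")
def default_cohort_features(default_cohort):
    """Features of the default cohort (expensive; shared session-wide).

    Uses the shipped default pairing: 5 s epochs, the 10-feature RCE-RFE
    set (CD, SampEn, RMS D2/D1, AM D6..D1), per-channel for 21 channels.
    """
    return extract_cohort_features(default_cohort, epoch_duration_s=5.0,
                                   feature_set="rce-rfe")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Fast 3-subject cohort with short sessions for protocol tests."""
    return make_cohort(3, 3, DEFAULT_MASTER_SEED, SessionSpec(
        normal_duration_s=100.0, seizure_duration_s=30.0,
        seizure_onset_s=50.0))


@pytest.fixture(scope="session")
def tiny_cohort_features(tiny_cohort):
    # DWD-statistics-only set: fast to extract, still class-separable
    # (ictal discharges carry elevated mid-band energy)
    return extract_cohort_features(tiny_cohort, epoch_duration_s=5.0,
                                   feature_set="chi-squared")
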