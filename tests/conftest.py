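import numpy as np
import pytest
from dataclasses import replace

from ppglucose import (
    SimulationSchedule,
    SubjectProfile,
    default_profiles,
    gen_recording,
    preprocess,
)


@pytest.fixture(scope="session")
def clean_profile():
    """Noise-free subject: every generated cycle is identical."""
    return SubjectProfile(
        subject_id="CLEAN",
        phenotype="non_diabetic",
        fasting_bgl=90.0,
        postprandial_peak_bgl=142.0,
        bgl_noise_sd=0.0,
        hr_jitter_frac=0.0,
        baseline_wander_amplitude=0.0,
        noise_sd=0.0,
        artifact_rate=0.0,
        corrupt_frac_range=(0.0, 0.0),
        heart_rate=60.0,
    )


@pytest.fixture(scope="session")
def short_schedule():
    return SimulationSchedule(
        n_days=1,
        recordings_per_timepoint=1,
        recording_duration=120.0,
        timepoints=(-10.0, 30.0),
        sampling_rate=100.0,
        seed=7,
        glucometer_cv=0.0,
    )


@pytest.fixture(scope="session")
def clean_recording(clean_profile, short_schedule):
    """120 s, 60 bpm, perfectly periodic recording (exactly 120 cycles)."""
    return gen_recording(clean_profile, short_schedule, day=1, timepoint=-10.0)


@pytest.fixture(scope="session")
def clean_processed(clean_recording):
    return preprocess(clean_recording)


@pytest.fixture(scope="session")
def noisy_profile():
    """Default-noise subject used for realistic single-recording tests."""
    return default_profiles()[0]
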