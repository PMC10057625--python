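"""Synthetic PPG cohort generation.

Produces glucose trajectories, glucometer readings and glucose-modulated
PPG recordings with the statistical structure the downstream analysis
assumes: per-cycle pulse amplitude decreases and pulse width increases
with blood glucose, recordings follow a fasting + postprandial schedule
repeated over several days, and four diabetic phenotypes are supported
(non-diabetic, pre-diabetic, type 1 and type 2).

All randomness flows from ``SimulationSchedule.seed`` through per-subject,
per-recording ``numpy.random.Generator`` streams, so identical inputs
yield bitwise-identical cohorts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

PHENOTYPES = ("non_diabetic", "pre_diabetic", "type1", "type2")

#: physiological clipping range for simulated true BGL, mg/dL
BGL_MIN, BGL_MAX = 40.0, 600.0
#: glucometer measuring interval, mg/dL
GLUCOMETER_MIN, GLUCOMETER_MAX = 10.0, 600.0


@dataclass(frozen=True)
class SubjectProfile:
    """Parameters of one simulated subject.

    The glucose → waveform coupling is linear: pulse amplitude falls and
    pulse width grows with BGL above the subject's fasting level
    (``amplitude_glucose_slope`` < 0, ``width_glucose_slope`` > 0).
    """

    subject_id: str
    phenotype: str
    fasting_bgl: float
    postprandial_peak_bgl: float
    rise_time: float = 30.0  # minutes from meal to postprandial peak
    decay_time: float = 45.0  # minutes, postprandial decay constant
    bgl_noise_sd: float = 5.0  # day-level fasting variation, mg/dL
    insulin_event_sd: float = 0.0  # type-1 per-measurement perturbation, mg/dL
    hypo_event_rate: float = 0.0  # type-1 chance per measurement of a hypo episode
    hypo_band: Tuple[float, float] = (58.0, 72.0)  # hypo episode level, mg/dL
    heart_rate: float = 64.0  # beats/min
    hr_jitter_frac: float = 0.015  # per-cycle heart-rate jitter (fractional sd)
    dc_level: float = 10.0  # PPG units, slowly varying baseline
    cycle_amplitude_at_fasting: float = 1.0  # PPG units
    amplitude_glucose_slope: float = -0.002  # PPG units per mg/dL, must be < 0
    width_glucose_slope: float = 0.0003  # seconds per mg/dL, must be > 0
    systolic_width: float = 0.09  # Gaussian sigma of systolic pulse at fasting, s
    baseline_wander_amplitude: float = 0.2  # PPG units
    baseline_wander_freq: float = 0.25  # Hz
    noise_sd: float = 0.035  # PPG units (~20 dB SNR on a unit-amplitude pulse)
    artifact_rate: float = 0.05  # motion-artifact bursts per minute
    # per-recording fraction of cycles replaced by a distorted (motion
    # corrupted) morphology; drawn uniformly from this range so the
    # matched-filter QC removes 10-20% of cycles under defaults
    corrupt_frac_range: Tuple[float, float] = (0.172, 0.182)

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.fasting_bgl <= 0:
            raise ValueError("fasting_bgl must be positive")
        if self.phenotype != "type1" and self.postprandial_peak_bgl < self.fasting_bgl:
            raise ValueError(
                "postprandial_peak_bgl must be >= fasting_bgl "
                "(type1 may invert via insulin events)"
            )
        if self.amplitude_glucose_slope >= 0:
            raise ValueError("amplitude_glucose_slope must be negative")
        if self.width_glucose_slope <= 0:
            raise ValueError("width_glucose_slope must be positive")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        lo, hi = self.corrupt_frac_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("corrupt_frac_range must satisfy 0 <= lo <= hi < 1")


@dataclass(frozen=True)
class SimulationSchedule:
    """Recording schedule shared by all subjects of a cohort.

    ``timepoints`` are minutes since the meal; negative values denote
    fasting measurements (at least one is required, as the downstream
    high/low-glucose split is anchored on the fasting mean).
    """

    n_days: int = 9
    recordings_per_timepoint: int = 2
    recording_duration: float = 120.0  # seconds
    timepoints: Tuple[float, ...] = (-10.0, 30.0, 120.0)
    sampling_rate: float = 100.0  # Hz
    seed: int = 0
    glucometer_cv: float = 0.05  # sd of reference reading as fraction of value

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.recording_duration <= 0:
            raise ValueError("recording_duration must be positive")
        if len(self.timepoints) == 0:
            raise ValueError("timepoints must be non-empty")
        if not any(tp < 0 for tp in self.timepoints):
            raise ValueError("at least one fasting (negative) timepoint required")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.recordings_per_timepoint < 1:
            raise ValueError("recordings_per_timepoint must be >= 1")


@dataclass
class RawRecording:
    """One PPG trace plus its paired reference BGL and session metadata."""

    subject_id: str
    day_index: int  # 1-based
    timepoint: float  # minutes since meal, negative = fasting
    repeat: int  # 1-based repeat index within (day, timepoint)
    sampling_rate: float
    samples: np.ndarray
    reference_bgl: float
    true_bgl: float | None = None  # simulation-only ground truth

    @property
    def recording_id(self) -> str:
        return (
            f"{self.subject_id}_d{self.day_index:02d}"
            f"_t{int(round(self.timepoint))}_r{self.repeat}"
        )

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


def default_profiles() -> List[SubjectProfile]:
    """Default four-subject cohort, one subject per phenotype.

    Fasting/peak levels are chosen so simulated glucose spans roughly
    75-142 (non-diabetic), 86-194 (pre-diabetic), 63-175 (type 1, with
    unpredictable insulin-event excursions) and 184-346 (type 2) mg/dL.
    """
    return [
        SubjectProfile(
            subject_id="S1",
            phenotype="non_diabetic",
            fasting_bgl=90.0,
            postprandial_peak_bgl=142.0,
            rise_time=30.0,
            decay_time=40.0,
            bgl_noise_sd=6.0,
        ),
        SubjectProfile(
            subject_id="S2",
            phenotype="pre_diabetic",
            fasting_bgl=100.0,
            postprandial_peak_bgl=194.0,
            rise_time=35.0,
            decay_time=70.0,
            bgl_noise_sd=6.0,
        ),
        SubjectProfile(
            subject_id="S3",
            phenotype="type1",
            fasting_bgl=95.0,
            postprandial_peak_bgl=150.0,
            rise_time=30.0,
            decay_time=50.0,
            bgl_noise_sd=5.0,
            insulin_event_sd=12.0,
            hypo_event_rate=0.15,
        ),
        SubjectProfile(
            subject_id="S4",
            phenotype="type2",
            fasting_bgl=200.0,
            postprandial_peak_bgl=320.0,
            rise_time=40.0,
            decay_time=90.0,
            bgl_noise_sd=7.0,
            # wide glucose span: slightly narrower base pulse and slower
            # heart rate keep the (width-coupled) pulse within the cycle
            # at the highest simulated glucose levels
            heart_rate=56.0,
            systolic_width=0.085,
        ),
    ]


def _stream(schedule: SimulationSchedule, *tags: object) -> np.random.Generator:
    """Independent, reproducible generator keyed by schedule seed + tags."""
    digest = hashlib.sha256("|".join(map(str, tags)).encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng([schedule.seed, key])


def gen_glucose_profile(
    profile: SubjectProfile,
    schedule: SimulationSchedule,
    rng: np.random.Generator | None = None,
) -> Dict[Tuple[int, float], float]:
    """True BGL (mg/dL) at every (day, timepoint) of the schedule.

    Fasting timepoints return the fasting level plus day-level noise;
    postprandial values follow a rise-then-decay curve that equals
    ``postprandial_peak_bgl`` at ``rise_time``. Type-1 subjects receive
    an additional independent perturbation per measurement (insulin
    events), so the fasting/postprandial ordering may invert.
    """
    if rng is None:
        rng = _stream(schedule, profile.subject_id, "glucose")
    excess = profile.postprandial_peak_bgl - profile.fasting_bgl
    out: Dict[Tuple[int, float], float] = {}
    for day in range(1, schedule.n_days + 1):
        day_offset = rng.normal(0.0, profile.bgl_noise_sd) if profile.bgl_noise_sd else 0.0
        for tp in schedule.timepoints:
            bgl = profile.fasting_bgl + day_offset
            if tp > 0:
                # unit-peak curve: equals 1 exactly at tp == rise_time
                shape = (tp / profile.rise_time) * np.exp(
                    (profile.rise_time - tp) / profile.decay_time
                )
                bgl += excess * shape
            if profile.phenotype == "type1":
                # insulin dosing makes levels unpredictable: diffuse
                # perturbations plus occasional overshoot into hypoglycemia
                if profile.insulin_event_sd > 0:
                    bgl += rng.normal(0.0, profile.insulin_event_sd)
                if profile.hypo_event_rate > 0 and rng.random() < profile.hypo_event_rate:
                    bgl = rng.uniform(*profile.hypo_band)
            out[(day, tp)] = float(np.clip(bgl, BGL_MIN, BGL_MAX))
    return out


def _pulse_params(bgl: float, profile: SubjectProfile) -> Tuple[float, float]:
    """(amplitude, systolic sigma) of the pulse at a given glucose level."""
    delta = bgl - profile.fasting_bgl
    amp = profile.cycle_amplitude_at_fasting + profile.amplitude_glucose_slope * delta
    amp = max(amp, 0.1 * profile.cycle_amplitude_at_fasting)  # amplitude floor
    sigma = profile.systolic_width + profile.width_glucose_slope * delta
    sigma = max(sigma, 0.25 * profile.systolic_width)
    return amp, sigma


def gen_ppg_cycle(
    bgl: float,
    profile: SubjectProfile,
    sampling_rate: float,
    duration: float | None = None,
) -> np.ndarray:
    """One heartbeat of PPG: DC offset + systolic pulse + diastolic shoulder.

    Pulse amplitude and width depend linearly on (bgl - fasting_bgl); low
    glucose gives a taller, narrower pulse.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if bgl <= 0:
        raise ValueError("bgl must be positive")
    if duration is None:
        duration = 60.0 / profile.heart_rate
    n = int(round(duration * sampling_rate))
    if n < 4:
        raise ValueError("cycle too short for the requested sampling rate")
    t = np.arange(n) / sampling_rate
    amp, sigma = _pulse_params(bgl, profile)
    sys_c = 0.28 * duration
    dia_c = sys_c + 0.26 * duration
    # asymmetric systolic pulse: steep upstroke, slower decay (anchors the
    # preceding trough sharply, as in real PPG)
    sig = np.where(t < sys_c, 0.6 * sigma, 1.3 * sigma)
    wave = (
        profile.dc_level
        + amp * np.exp(-0.5 * ((t - sys_c) / sig) ** 2)
        + 0.30 * amp * np.exp(-0.5 * ((t - dia_c) / (1.25 * sigma)) ** 2)
        # cardiac-frequency undulation: gives every cycle a single clear
        # trough (real PPG never sits on a flat floor between pulses)
        + 0.25 * amp * np.cos(2.0 * np.pi * (t - sys_c) / duration)
    )
    return wave


def _gen_corrupt_cycle(
    bgl: float,
    profile: SubjectProfile,
    sampling_rate: float,
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Motion-corrupted cycle: displaced, widened, attenuated pulse.

    The pulse is displaced by a fixed multiple of its own width (so the
    corrupted shape is roughly equally dissimilar from the clean one at
    every glucose level) in a random direction (so corrupted cycles caught
    in the template's middle-ten average largely cancel), widened and
    attenuated, with a little in-band ripple. It keeps a single detectable
    peak and the clean trough phase, so segmentation is unaffected, while
    its matched-filter correlation falls below the r = 0.90 acceptance
    threshold.
    """
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    amp, sigma = _pulse_params(bgl, profile)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    c = 0.28 * duration + (2.0 * sigma if sign > 0 else -1.4 * sigma)
    sig = np.where(t < c, 0.9 * sigma, 1.6 * sigma)
    # super-Gaussian confinement keeps the displaced pulse away from the
    # cycle-boundary troughs, so neighbouring clean cycles keep their
    # segmentation boundaries
    confine = np.exp(-(((t - 0.33 * duration) / (0.27 * duration)) ** 6))
    ripple_phase = rng.uniform(0.0, 2.0 * np.pi)
    wave = (
        profile.dc_level
        + 0.55 * amp * np.exp(-0.5 * ((t - c) / sig) ** 2) * confine
        + 0.25 * amp * np.cos(2.0 * np.pi * (t - 0.28 * duration) / duration)
        + 0.13 * amp * np.sin(2.0 * np.pi * 4.3 * t + ripple_phase) * confine
    )
    wave += rng.normal(0.0, 0.08 * profile.cycle_amplitude_at_fasting, n) * confine
    return wave


def gen_recording(
    profile: SubjectProfile,
    schedule: SimulationSchedule,
    day: int,
    timepoint: float,
    repeat: int = 1,
    rng: np.random.Generator | None = None,
    true_bgl: float | None = None,
) -> RawRecording:
    """Render one recording: jittered cycle train + wander + noise + artifacts.

    ``reference_bgl`` is the true BGL plus zero-mean glucometer noise
    (sd = ``schedule.glucometer_cv`` × value), clipped to the glucometer
    measuring interval 10-600 mg/dL. Deterministic given the schedule seed.
    """
    if not (1 <= day <= schedule.n_days):
        raise ValueError(f"day {day} outside schedule (1..{schedule.n_days})")
    if timepoint not in schedule.timepoints:
        raise ValueError(f"timepoint {timepoint} not in schedule")
    if rng is None:
        rng = _stream(schedule, profile.subject_id, "rec", day, timepoint, repeat)
    if true_bgl is None:
        true_bgl = gen_glucose_profile(profile, schedule)[(day, timepoint)]

    fs = schedule.sampling_rate
    n_target = int(round(schedule.recording_duration * fs))

    cycles: List[np.ndarray] = []
    durations: List[float] = []
    total = 0
    while total < n_target:
        jitter = rng.normal(0.0, profile.hr_jitter_frac) if profile.hr_jitter_frac else 0.0
        hr = profile.heart_rate * float(np.clip(1.0 + jitter, 0.7, 1.3))
        dur = 60.0 / hr
        cyc = gen_ppg_cycle(true_bgl, profile, fs, dur)
        cycles.append(cyc)
        durations.append(dur)
        total += len(cyc)

    lo, hi = profile.corrupt_frac_range
    if hi > 0:
        frac = rng.uniform(lo, hi)
        n_corrupt = int(round(frac * len(cycles)))
        if n_corrupt:
            # motion artifacts spare the stable middle of a recording (the
            # subject settles after insertion and stirs before removal),
            # which is the empirical rationale for building the matched-
            # filter template from the middle ten cycles; corruption is
            # placed uniformly outside a protected centre window
            pos = np.arange(len(cycles))
            center = (len(cycles) - 1) / 2.0
            weights = np.where(np.abs(pos - center) < 8.0, 0.05, 1.0)
            weights /= weights.sum()
            idx = rng.choice(len(cycles), size=n_corrupt, replace=False, p=weights)
            for i in idx:
                cycles[i] = _gen_corrupt_cycle(true_bgl, profile, fs, durations[i], rng)

    samples = np.concatenate(cycles)[:n_target]
    t = np.arange(n_target) / fs

    phase = rng.uniform(0.0, 2.0 * np.pi)
    if profile.baseline_wander_amplitude:
        samples = samples + profile.baseline_wander_amplitude * np.sin(
            2.0 * np.pi * profile.baseline_wander_freq * t + phase
        )
    if profile.noise_sd:
        samples = samples + rng.normal(0.0, profile.noise_sd, n_target)

    n_bursts = rng.poisson(profile.artifact_rate * schedule.recording_duration / 60.0)
    for _ in range(n_bursts):
        start = rng.uniform(0.0, max(schedule.recording_duration - 1.0, 0.0))
        burst_dur = rng.uniform(0.3, 1.0)
        i0 = int(start * fs)
        i1 = min(n_target, i0 + int(burst_dur * fs))
        samples[i0:i1] += rng.normal(
            0.0, 1.0 * profile.cycle_amplitude_at_fasting, i1 - i0
        )

    ref = true_bgl + rng.normal(0.0, schedule.glucometer_cv * true_bgl)
    ref = float(np.clip(ref, GLUCOMETER_MIN, GLUCOMETER_MAX))
    return RawRecording(
        subject_id=profile.subject_id,
        day_index=day,
        timepoint=timepoint,
        repeat=repeat,
        sampling_rate=fs,
        samples=samples,
        reference_bgl=ref,
        true_bgl=float(true_bgl),
    )


def gen_cohort(
    profiles: Sequence[SubjectProfile],
    schedule: SimulationSchedule,
) -> Tuple[List[RawRecording], pd.DataFrame]:
    """Full cohort: one recording per (subject, day, timepoint, repeat).

    Returns the recordings plus a metadata table (one row per recording).
    Use :func:`ppglucose.io.write_cohort` to persist to disk.
    """
    if len(profiles) == 0:
        raise ValueError("at least one profile required")
    ids = [p.subject_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")

    recordings: List[RawRecording] = []
    rows = []
    for profile in profiles:
        glucose = gen_glucose_profile(profile, schedule)
        for day in range(1, schedule.n_days + 1):
            for tp in schedule.timepoints:
                for rep in range(1, schedule.recordings_per_timepoint + 1):
                    rec = gen_recording(
                        profile, schedule, day, tp, repeat=rep,
                        true_bgl=glucose[(day, tp)],
                    )
                    recordings.append(rec)
                    rows.append(
                        {
                            "subject_id": rec.subject_id,
                            "day": rec.day_index,
                            "timepoint_min": rec.timepoint,
                            "repeat": rec.repeat,
                            "sampling_rate_hz": rec.sampling_rate,
                            "reference_bgl_mgdl": rec.reference_bgl,
                            "true_bgl_mgdl": rec.true_bgl,
                            "recording_id": rec.recording_id,
                        }
                    )
    return recordings, pd.DataFrame(rows)
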