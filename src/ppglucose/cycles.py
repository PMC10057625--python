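"""Cycle segmentation, matched-filter quality control and feature extraction.

Each heartbeat is windowed trough-to-trough around its systolic peak,
correlated against a template (mean of the middle ten cycles of the
recording) and rejected when r < 0.90. Eighteen morphological and
Teager-Kaiser-energy features are computed per retained cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats

from ppglucose.preprocessing import ProcessedRecording

#: canonical ordering of the 18 per-cycle features
FEATURE_NAMES: Tuple[str, ...] = (
    "dc_value",
    "peak_value",
    "delta_ac",
    "rise_slope",
    "rise_time",
    "fall_level",
    "fall_slope",
    "fall_time",
    "width_quarter",
    "width_three_quarter",
    "base_width",
    "area",
    "optical_density",
    "tkeo_mean",
    "tkeo_variance",
    "tkeo_std",
    "tkeo_skewness",
    "tkeo_kurtosis",
)

DEFAULT_TEMPLATE_LENGTH = 100
DEFAULT_R_MIN = 0.90


@dataclass
class PpgCycle:
    """One segmented heartbeat, spanning left trough to right trough."""

    samples: np.ndarray
    peak_offset: int  # index of the systolic peak within samples
    dc_value: float
    sampling_rate: float
    recording_ref: str = ""
    bgl_label: float = float("nan")  # reference glucometer BGL of the recording

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        n = len(self.samples)
        if n < 3:
            raise ValueError("cycle needs at least 3 samples")
        if not (0 < self.peak_offset < n - 1):
            raise ValueError("peak_offset must be interior to the cycle")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def left_trough_value(self) -> float:
        return float(self.samples[0])

    @property
    def peak_value(self) -> float:
        return float(self.samples[self.peak_offset])

    @property
    def right_trough_value(self) -> float:
        return float(self.samples[-1])

    @property
    def duration(self) -> float:
        return (len(self.samples) - 1) / self.sampling_rate


@dataclass
class CycleTemplate:
    """Fixed-length mean cycle used as the matched filter."""

    waveform: np.ndarray
    n_source_cycles: int


@dataclass
class FeatureVector:
    """The 18 per-cycle features (times in s, slopes in PPG units/s)."""

    dc_value: float
    peak_value: float
    delta_ac: float
    rise_slope: float
    rise_time: float
    fall_level: float
    fall_slope: float
    fall_time: float
    width_quarter: float
    width_three_quarter: float
    base_width: float
    area: float
    optical_density: float
    tkeo_mean: float
    tkeo_variance: float
    tkeo_std: float
    tkeo_skewness: float
    tkeo_kurtosis: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def segment_cycles(
    processed: ProcessedRecording,
    bgl_label: float | None = None,
    recording_ref: str | None = None,
) -> List[PpgCycle]:
    """One cycle per interior peak, spanning left to right trough inclusive.

    Adjacent cycles share their boundary trough. Cycles inherit the
    recording's DC value and its reference glucometer BGL as label.
    """
    src = processed.source
    if bgl_label is None:
        bgl_label = src.reference_bgl if src is not None else float("nan")
    if recording_ref is None:
        recording_ref = src.recording_id if src is not None else ""
    x = processed.ac_series
    troughs = np.asarray(processed.trough_indices)
    cycles: List[PpgCycle] = []
    for p in processed.peak_indices:
        left_candidates = troughs[troughs < p]
        right_candidates = troughs[troughs > p]
        if len(left_candidates) == 0 or len(right_candidates) == 0:
            continue
        left, right = int(left_candidates[-1]), int(right_candidates[0])
        cycles.append(
            PpgCycle(
                samples=x[left : right + 1],
                peak_offset=int(p - left),
                dc_value=processed.dc_value,
                sampling_rate=processed.upsampled_rate,
                recording_ref=recording_ref,
                bgl_label=float(bgl_label),
            )
        )
    if not cycles:
        warnings.warn("no valid interior peak: recording yields zero cycles")
    return cycles


def resample_cycle(samples: np.ndarray, length: int) -> np.ndarray:
    """Linear-interpolation resampling of one cycle to a fixed length."""
    x = np.asarray(samples, dtype=float)
    if len(x) == length:
        return x.copy()
    old = np.linspace(0.0, 1.0, len(x))
    new = np.linspace(0.0, 1.0, length)
    return np.interp(new, old, x)


def middle_ten_indices(n: int) -> np.ndarray:
    """Indices of the ten cycles centred at n // 2 (all when n < 10)."""
    if n < 10:
        return np.arange(n)
    start = n // 2 - 5
    return np.arange(start, start + 10)


def build_template(
    cycles: Sequence[PpgCycle], length: int = DEFAULT_TEMPLATE_LENGTH
) -> CycleTemplate:
    """Matched-filter template: pointwise mean of the middle ten cycles.

    When fewer than ten cycles exist, all of them are used (logged via
    warning). Each contributing cycle is resampled to ``length`` first.
    """
    if len(cycles) == 0:
        raise ValueError("cannot build a template from zero cycles")
    idx = middle_ten_indices(len(cycles))
    if len(idx) < 10:
        warnings.warn(f"only {len(idx)} cycles available for template (< 10)")
    stack = np.stack([resample_cycle(cycles[i].samples, length) for i in idx])
    return CycleTemplate(waveform=stack.mean(axis=0), n_source_cycles=len(idx))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; 0 by convention when either input has zero variance."""
    sa, sb = np.std(a), np.std(b)
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def filter_cycles(
    cycles: Sequence[PpgCycle],
    template: CycleTemplate,
    r_min: float = DEFAULT_R_MIN,
) -> Tuple[List[PpgCycle], List[PpgCycle], np.ndarray]:
    """Matched-filter QC: keep cycles whose correlation with the template
    satisfies r >= r_min (the boundary is kept; rejection is r < r_min).

    Returns (valid, rejected, correlations). Zero-variance cycles get
    r = 0 and are rejected.
    """
    length = len(template.waveform)
    correlations = np.array(
        [_pearson(resample_cycle(c.samples, length), template.waveform) for c in cycles]
    )
    valid = [c for c, r in zip(cycles, correlations) if r >= r_min]
    rejected = [c for c, r in zip(cycles, correlations) if r < r_min]
    return valid, rejected, correlations


def tkeo(samples: np.ndarray) -> np.ndarray:
    """Teager-Kaiser energy: x[n]^2 - x[n+1] x[n-1], interior points only."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 3:
        raise ValueError("TKEO requires at least 3 samples")
    return x[1:-1] ** 2 - x[2:] * x[:-2]


def _width_at_height(
    samples: np.ndarray, threshold: float, rate: float
) -> float:
    """Time span (s) between the outermost crossings of ``threshold``.

    Crossing positions are linearly interpolated between samples; returns 0
    when the cycle never reaches the threshold.
    """
    s = samples - threshold
    above = np.flatnonzero(s >= 0)
    if len(above) == 0:
        return 0.0
    i = above[0]
    if i == 0:
        left = 0.0
    else:
        left = i - s[i] / (s[i] - s[i - 1])
    j = above[-1]
    if j == len(s) - 1:
        right = float(j)
    else:
        right = j + s[j] / (s[j] - s[j + 1])
    return (right - left) / rate


def extract_features(
    cycle: PpgCycle,
    sampling_rate: float | None = None,
    od_log_base: float = 10.0,
) -> FeatureVector:
    """Compute the 18 features of one valid cycle.

    Conventions (where the feature definitions leave freedom): fall slope
    is stored negative (downhill); widths at 1/4 and 3/4 height are
    durations above ``left_trough + h * delta_ac``; optical density uses
    log base 10; TKEO variance is the population variance and kurtosis is
    raw (normal => 3).
    """
    rate = sampling_rate if sampling_rate is not None else cycle.sampling_rate
    x = cycle.samples
    n = len(x)
    delta_ac = cycle.peak_value - cycle.left_trough_value
    fall_level = cycle.peak_value - cycle.right_trough_value
    rise_time = cycle.peak_offset / rate
    fall_time = (n - 1 - cycle.peak_offset) / rate
    if rise_time <= 0 or fall_time <= 0:
        raise ValueError("degenerate cycle: zero rise or fall time")
    if cycle.dc_value <= 0:
        raise ValueError("optical density undefined for non-positive DC value")

    width_quarter = _width_at_height(
        x, cycle.left_trough_value + 0.25 * delta_ac, rate
    )
    width_three_quarter = _width_at_height(
        x, cycle.left_trough_value + 0.75 * delta_ac, rate
    )
    area = float(np.trapezoid(x - cycle.left_trough_value, dx=1.0 / rate))
    od = float(np.log(1.0 + delta_ac / cycle.dc_value) / np.log(od_log_base))

    e = tkeo(x)
    t_mean = float(np.mean(e))
    t_var = float(np.var(e))  # population variance
    t_std = float(np.sqrt(t_var))
    if t_var > 0:
        t_skew = float(sstats.skew(e, bias=True))
        t_kurt = float(sstats.kurtosis(e, fisher=False, bias=True))
    else:  # degenerate flat energy profile: normal-reference convention
        t_skew, t_kurt = 0.0, 3.0

    return FeatureVector(
        dc_value=float(cycle.dc_value),
        peak_value=float(cycle.peak_value),
        delta_ac=float(delta_ac),
        rise_slope=float(delta_ac / rise_time),
        rise_time=float(rise_time),
        fall_level=float(fall_level),
        fall_slope=float(-fall_level / fall_time),
        fall_time=float(fall_time),
        width_quarter=float(width_quarter),
        width_three_quarter=float(width_three_quarter),
        base_width=float(rise_time + fall_time),
        area=area,
        optical_density=od,
        tkeo_mean=t_mean,
        tkeo_variance=t_var,
        tkeo_std=t_std,
        tkeo_skewness=t_skew,
        tkeo_kurtosis=t_kurt,
    )


def features_frame(
    cycles: Iterable[PpgCycle],
    correlations: Sequence[float] | None = None,
    od_log_base: float = 10.0,
    **metadata,
) -> pd.DataFrame:
    """Feature table: one row per cycle, 18 feature columns + metadata.

    Cycles with non-positive DC value (optical density undefined) are
    dropped with a warning.
    """
    rows = []
    for k, cycle in enumerate(cycles):
        try:
            fv = extract_features(cycle, od_log_base=od_log_base)
        except ValueError as exc:
            warnings.warn(f"dropping cycle {k} of {cycle.recording_ref}: {exc}")
            continue
        row = dict(metadata)
        row["recording_id"] = cycle.recording_ref
        row["bgl_label"] = cycle.bgl_label
        if correlations is not None:
            row["correlation_r"] = float(correlations[k])
        row.update(fv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
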