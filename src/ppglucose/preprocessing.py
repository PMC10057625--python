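"""PPG pre-processing: DC/AC filtering, upsampling, baseline removal, peaks.

Pipeline order: band-pass -> upsample -> lower-envelope subtraction ->
peak/trough detection. All filters are zero-phase (forward-backward), so
cycle landmarks used later for timing features are not phase-shifted; the
effective magnitude response is therefore the squared single-pass
Butterworth magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d

from ppglucose.synthetic import RawRecording

#: minimum samples accepted by the filters (warm-up handled by reflect-style
#: odd padding of up to len-1 samples on each side)
MIN_FILTER_LEN = 64


@dataclass
class ProcessedRecording:
    """Filtered recording with detected cycle landmarks.

    ``ac_series`` is band-passed, upsampled and lower-envelope subtracted;
    ``peak_indices``/``trough_indices`` index into it and strictly
    alternate, every peak flanked by a trough on each side.
    """

    source: RawRecording
    dc_series: np.ndarray
    dc_value: float
    ac_series: np.ndarray
    upsampled_rate: float
    peak_indices: np.ndarray
    trough_indices: np.ndarray


def _check_input(samples: np.ndarray) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    if len(x) < MIN_FILTER_LEN:
        raise ValueError(
            f"signal too short for zero-phase filtering: {len(x)} samples, "
            f"need at least {MIN_FILTER_LEN}"
        )
    return x


def extract_dc(
    samples: np.ndarray, sampling_rate: float, order: int = 10, cutoff_hz: float = 0.01
) -> np.ndarray:
    """Slow (DC) component: zero-phase low-pass Butterworth, 10th order, 0.01 Hz."""
    x = _check_input(samples)
    if sampling_rate <= 2 * cutoff_hz:
        raise ValueError("sampling_rate must exceed twice the cutoff")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=sampling_rate, output="sos")
    padlen = min(len(x) - 1, int(round(3 * sampling_rate / cutoff_hz)))
    return signal.sosfiltfilt(sos, x, padtype="odd", padlen=padlen)


def extract_ac(
    samples: np.ndarray,
    sampling_rate: float,
    order: int = 8,
    band_hz: Tuple[float, float] = (0.3, 10.0),
) -> np.ndarray:
    """Pulsatile (AC) component: zero-phase band-pass Butterworth, 8th order.

    ``order`` is the overall band-pass order (poles), i.e. the analog
    prototype has order/2 poles before the low-pass -> band-pass transform.
    """
    x = _check_input(samples)
    if sampling_rate <= 2 * band_hz[1]:
        raise ValueError(
            f"sampling_rate {sampling_rate} Hz too low for band edge {band_hz[1]} Hz"
        )
    if order % 2:
        raise ValueError("band-pass order must be even")
    sos = signal.butter(
        order // 2, band_hz, btype="bandpass", fs=sampling_rate, output="sos"
    )
    padlen = min(len(x) - 1, int(round(10 * sampling_rate / band_hz[0])))
    return signal.sosfiltfilt(sos, x, padtype="odd", padlen=padlen)


def upsample(series: np.ndarray, factor: int) -> np.ndarray:
    """Linear-interpolation upsampling; original samples kept at stride factor."""
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    x = np.asarray(series, dtype=float)
    if factor == 1:
        return x.copy()
    n = len(x)
    old = np.arange(n)
    new = np.arange((n - 1) * factor + 1) / factor
    return np.interp(new, old, x)


def remove_baseline(
    series: np.ndarray,
    rate: float,
    min_distance_s: float = 0.3,
    prominence_frac: float = 0.3,
) -> Tuple[np.ndarray, np.ndarray]:
    """Subtract the lower envelope (natural cubic spline through local minima).

    Only prominent minima become spline knots (prominence >= 0.3 x the
    75th-percentile minima prominence), so shallow mid-cycle dips such as
    the diastolic notch do not pull the envelope up between true cycle
    troughs. The envelope is held constant beyond the terminal minima and
    the corrected series is exactly zero at every knot. Requires at least
    4 qualifying local minima (cubic spline support).
    """
    x = np.asarray(series, dtype=float)
    distance = max(1, int(round(min_distance_s * rate)))
    minima, _ = signal.find_peaks(-x, distance=distance)
    if len(minima) >= 4 and prominence_frac > 0:
        prom = signal.peak_prominences(-x, minima)[0]
        threshold = prominence_frac * float(np.quantile(prom, 0.75))
        kept = minima[prom >= threshold]
        if len(kept) >= 4:
            minima = kept
    if len(minima) < 4:
        raise ValueError(
            f"only {len(minima)} local minima found; need >= 4 for the "
            "lower-envelope spline (recording unusable)"
        )
    spline = CubicSpline(minima, x[minima], bc_type="natural")
    knots_x = np.clip(np.arange(len(x)), minima[0], minima[-1])
    envelope = spline(knots_x)
    envelope[minima] = x[minima]  # exact zeros at knots, no rounding residue
    return x - envelope, envelope


def detect_peaks_troughs(
    series: np.ndarray,
    rate: float,
    min_separation_s: float = 0.3,
    prominence_frac: float = 0.3,
) -> Tuple[np.ndarray, np.ndarray]:
    """Systolic peaks and inter-peak troughs on a baseline-corrected series.

    Peaks: local maxima with a refractory separation (default 0.3 s, i.e.
    at most 200 bpm) and minimum prominence 0.3 x the typical systolic
    peak-to-trough span, estimated as the 75th-percentile prominence of a
    first distance-only pass (an upper quantile, not the median, so noise
    bumps admitted by the rough pass cannot drag the reference down).
    Troughs: the minimum between consecutive peaks plus the
    leading/trailing minima, located on a lightly smoothed copy (40 ms
    moving average) so sample noise in a shallow trough basin does not
    jitter the cycle boundaries; peaks without a trough on both sides are
    dropped, so peaks and troughs strictly alternate.
    """
    x = np.asarray(series, dtype=float)
    distance = max(1, int(round(min_separation_s * rate)))
    rough, _ = signal.find_peaks(x, distance=distance)
    if len(rough) == 0:
        raise ValueError("no peaks found in recording")
    prominences = signal.peak_prominences(x, rough)[0]
    threshold = prominence_frac * float(np.quantile(prominences, 0.75))
    peaks, _ = signal.find_peaks(x, distance=distance, prominence=threshold)
    # drop peaks that touch the ends: no flanking trough exists there
    peaks = peaks[(peaks > 0) & (peaks < len(x) - 1)]
    if len(peaks) == 0:
        raise ValueError("no interior peaks found in recording")

    win = max(1, int(round(0.04 * rate)))
    xs = uniform_filter1d(x, size=win) if win > 1 else x

    troughs = []
    lead = np.argmin(xs[: peaks[0]]) if peaks[0] > 0 else None
    if lead is not None:
        troughs.append(int(lead))
    for left, right in zip(peaks[:-1], peaks[1:]):
        troughs.append(int(left + 1 + np.argmin(xs[left + 1 : right])))
    tail_seg = xs[peaks[-1] + 1 :]
    if len(tail_seg):
        troughs.append(int(peaks[-1] + 1 + np.argmin(tail_seg)))

    troughs_arr = np.asarray(troughs, dtype=int)
    # the recording usually starts/ends mid-cycle: an edge "trough" that
    # sits well above the true trough level is a cut artefact, not a cycle
    # boundary - prune it (the edge peak it flanked is dropped with it)
    if len(troughs_arr) > 4:
        interior = x[troughs_arr[1:-1]]
        level = float(np.median(interior))
        span = float(np.median(x[peaks])) - level
        if x[troughs_arr[0]] > level + 0.15 * span:
            troughs_arr = troughs_arr[1:]
        if x[troughs_arr[-1]] > level + 0.15 * span:
            troughs_arr = troughs_arr[:-1]
    # keep only peaks with a trough strictly on each side
    keep = [p for p in peaks if troughs_arr[0] < p < troughs_arr[-1]]
    peaks = np.asarray(keep, dtype=int)
    if len(peaks) == 0:
        raise ValueError("no peaks flanked by troughs")
    return peaks, troughs_arr


def preprocess(
    recording: RawRecording,
    dc_order: int = 10,
    dc_cutoff_hz: float = 0.01,
    ac_order: int = 8,
    ac_band_hz: Tuple[float, float] = (0.3, 10.0),
    upsample_factor: int = 4,
    min_peak_separation_s: float = 0.3,
    peak_prominence_frac: float = 0.3,
) -> ProcessedRecording:
    """Full pre-processing of one recording; see module docstring for order."""
    fs = recording.sampling_rate
    dc_series = extract_dc(recording.samples, fs, dc_order, dc_cutoff_hz)
    ac = extract_ac(recording.samples, fs, ac_order, ac_band_hz)
    up = upsample(ac, upsample_factor)
    up_rate = fs * upsample_factor
    corrected, _ = remove_baseline(up, up_rate, min_peak_separation_s)
    peaks, troughs = detect_peaks_troughs(
        corrected, up_rate, min_peak_separation_s, peak_prominence_frac
    )
    return ProcessedRecording(
        source=recording,
        dc_series=dc_series,
        dc_value=float(np.mean(dc_series)),
        ac_series=corrected,
        upsampled_rate=up_rate,
        peak_indices=peaks,
        trough_indices=troughs,
    )
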