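"""High/low-glucose cycle statistics.

Cycles are split at the subject's mean fasting glucose, ensemble-averaged
and compared pointwise with two-sample t-tests; per-feature percentage
differences between the groups provide a feature-importance ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats

from ppglucose.cycles import FEATURE_NAMES, PpgCycle, resample_cycle


@dataclass
class GlucoseSplit:
    """Cycles (or feature rows) partitioned at the fasting-mean threshold."""

    threshold: float
    low: object  # list of PpgCycle or DataFrame of feature rows
    high: object


@dataclass
class CycleComparison:
    """Pointwise ensemble comparison of low- vs high-glucose cycles."""

    mean_low: np.ndarray
    mean_high: np.ndarray
    ci_low: np.ndarray  # pointwise 95% confidence half-widths
    ci_high: np.ndarray
    p_values: np.ndarray
    reject_mask: np.ndarray  # True where pointwise p < alpha


def _labels(collection) -> np.ndarray:
    if isinstance(collection, pd.DataFrame):
        return collection["bgl_label"].to_numpy(dtype=float)
    return np.array([c.bgl_label for c in collection], dtype=float)


def split_by_fasting_mean(
    cycles, fasting_bgls: Sequence[float]
) -> GlucoseSplit:
    """Split cycles at the mean fasting reference BGL.

    Low group: bgl_label strictly below the threshold; the boundary goes
    to the high group (the low group is defined as "below" the threshold).
    Accepts a list of cycles or a feature DataFrame with a ``bgl_label``
    column.
    """
    fasting = np.asarray(fasting_bgls, dtype=float)
    if len(fasting) == 0:
        raise ValueError("at least one fasting measurement required")
    threshold = float(np.mean(fasting))
    labels = _labels(cycles)
    low_mask = labels < threshold
    if isinstance(cycles, pd.DataFrame):
        low = cycles.loc[low_mask]
        high = cycles.loc[~low_mask]
    else:
        low = [c for c, m in zip(cycles, low_mask) if m]
        high = [c for c, m in zip(cycles, low_mask) if not m]
    if len(low) == 0 or len(high) == 0:
        warnings.warn(
            "all cycles fall on one side of the fasting threshold; "
            "high/low comparison will be skipped"
        )
    return GlucoseSplit(threshold=threshold, low=low, high=high)


def _welch_matrix(
    a: np.ndarray, b: np.ndarray, equal_var: bool
) -> np.ndarray:
    """Columnwise two-sample t-test p-values; identical columns give p = 1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sstats.ttest_ind(a, b, axis=0, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups with equal means -> nan -> no difference
    return np.where(np.isnan(p), 1.0, p)


def compare_cycles(
    split: GlucoseSplit,
    template_length: int = 100,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> CycleComparison:
    """Ensemble means with 95% CIs and a pointwise two-sample t-test.

    Welch (unequal variance) by default; set ``equal_var=True`` for the
    pooled-variance variant. No multiple-testing correction is applied.
    """
    low_cycles: List[PpgCycle] = list(split.low)
    high_cycles: List[PpgCycle] = list(split.high)
    if len(low_cycles) < 2 or len(high_cycles) < 2:
        raise ValueError("each glucose group needs at least 2 cycles")
    lo = np.stack([resample_cycle(c.samples, template_length) for c in low_cycles])
    hi = np.stack([resample_cycle(c.samples, template_length) for c in high_cycles])

    def ci_half_width(m: np.ndarray) -> np.ndarray:
        n = m.shape[0]
        crit = sstats.t.ppf(0.975, n - 1)
        return crit * m.std(axis=0, ddof=1) / np.sqrt(n)

    p = _welch_matrix(lo, hi, equal_var)
    return CycleComparison(
        mean_low=lo.mean(axis=0),
        mean_high=hi.mean(axis=0),
        ci_low=ci_half_width(lo),
        ci_high=ci_half_width(hi),
        p_values=p,
        reject_mask=p < alpha,
    )


def rank_features(
    split: GlucoseSplit,
    feature_names: Sequence[str] = FEATURE_NAMES,
    top_k: int | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Percentage difference of each feature between high and low groups.

    percent_difference = 100 * |mean_high - mean_low| / |mean_low|, with a
    Welch two-sample p-value per feature; sorted descending. Features whose
    low-group mean is zero are flagged (NaN percent difference) and placed
    last. ``top_k`` trims the ranking (e.g. 10 for the headline figure).
    """
    low, high = split.low, split.high
    if not isinstance(low, pd.DataFrame) or not isinstance(high, pd.DataFrame):
        raise TypeError("rank_features expects a split of feature DataFrames")
    if len(low) == 0 or len(high) == 0:
        raise ValueError("both glucose groups must be non-empty")
    rows = []
    for name in feature_names:
        a = low[name].to_numpy(dtype=float)
        b = high[name].to_numpy(dtype=float)
        mean_low, mean_high = float(a.mean()), float(b.mean())
        p = float(_welch_matrix(a[:, None], b[:, None], equal_var)[0])
        if mean_low == 0.0:
            pct = float("nan")
        else:
            pct = 100.0 * abs(mean_high - mean_low) / abs(mean_low)
        rows.append(
            {
                "feature": name,
                "mean_low": mean_low,
                "mean_high": mean_high,
                "percent_difference": pct,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "percent_difference", ascending=False, na_position="last"
    )
    table = table.reset_index(drop=True)
    if top_k is not None:
        table = table.head(top_k)
    return table
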