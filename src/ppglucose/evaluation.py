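"""Clinical-accuracy metrics: Clarke error grid, MARD, RMSE, OLS report, ISO.

The Clarke error grid regions follow the canonical 1987 inequality set:

  A: |pred - ref| <= 20% of ref, or both values below 70 mg/dL
     (clinically accurate);
  E: ref <= 70 with pred >= 180, or ref >= 180 with pred <= 70
     (opposite-corner misclassification);
  C: 70 <= ref <= 290 with pred >= ref + 110, or
     130 <= ref <= 180 with pred <= (7/5) ref - 182 (overcorrection);
  D: ref >= 240 with 70 <= pred <= 180, or
     ref <= 175/3 with 70 <= pred <= 180, or
     175/3 <= ref <= 70 with pred >= (6/5) ref (dangerous failure to detect);
  B: everything else (benign error).

Regions are evaluated in the order A, E, C, D, B, so labels are exhaustive
and exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy import stats as sstats

CEG_REGIONS = ("A", "B", "C", "D", "E")


@dataclass
class CegResult:
    """Clarke-error-grid classification of a set of prediction pairs."""

    labels: np.ndarray  # per-point region letters
    percentages: Dict[str, float]  # region -> percent of points
    counts: Dict[str, int]
    n_points: int


@dataclass
class EvaluationReport:
    """Full clinical evaluation of (reference, predicted) BGL pairs."""

    rmse: float  # mg/dL
    mard: float  # percent
    pearson_r: float
    slope: float
    slope_ci: Tuple[float, float]
    intercept: float  # mg/dL
    intercept_ci: Tuple[float, float]
    standard_error: float  # residual standard error, mg/dL
    r_squared: float
    iso_within_tolerance: float  # percent
    ceg: CegResult

    def as_dict(self) -> dict:
        return {
            "rmse_mgdl": self.rmse,
            "mard_percent": self.mard,
            "pearson_r": self.pearson_r,
            "slope": self.slope,
            "slope_ci95": list(self.slope_ci),
            "intercept_mgdl": self.intercept,
            "intercept_ci95": list(self.intercept_ci),
            "standard_error_mgdl": self.standard_error,
            "r_squared": self.r_squared,
            "iso_within_tolerance_percent": self.iso_within_tolerance,
            "ceg_percentages": dict(self.ceg.percentages),
            "n_points": self.ceg.n_points,
        }


def _validate_pairs(reference, predicted) -> Tuple[np.ndarray, np.ndarray]:
    ref = np.atleast_1d(np.asarray(reference, dtype=float))
    pred = np.atleast_1d(np.asarray(predicted, dtype=float))
    if ref.shape != pred.shape:
        raise ValueError("reference and predicted must have equal length")
    if len(ref) == 0:
        raise ValueError("at least one pair required")
    return ref, pred


def ceg_labels(reference, predicted) -> np.ndarray:
    """Vectorized Clarke-error-grid region labels for each pair."""
    ref, pred = _validate_pairs(reference, predicted)
    if np.any(ref <= 0) or np.any(pred <= 0):
        raise ValueError("BGL values must be positive")

    in_a = ((pred <= 70) & (ref <= 70)) | (
        (pred <= 1.2 * ref) & (pred >= 0.8 * ref)
    )
    in_e = ((ref >= 180) & (pred <= 70)) | ((ref <= 70) & (pred >= 180))
    in_c = ((ref >= 70) & (ref <= 290) & (pred >= ref + 110)) | (
        (ref >= 130) & (ref <= 180) & (pred <= (7.0 / 5.0) * ref - 182)
    )
    in_d = (
        ((ref >= 240) & (pred >= 70) & (pred <= 180))
        | ((ref <= 175.0 / 3.0) & (pred >= 70) & (pred <= 180))
        | ((ref >= 175.0 / 3.0) & (ref <= 70) & (pred >= (6.0 / 5.0) * ref))
    )
    return np.select(
        [in_a, in_e, in_c, in_d],
        ["A", "E", "C", "D"],
        default="B",
    ).astype("<U1")


def ceg_classify(reference: float, predicted: float) -> str:
    """Clarke-error-grid region of one (reference, predicted) pair."""
    return str(ceg_labels([reference], [predicted])[0])


def ceg_summary(reference, predicted) -> CegResult:
    """Label every pair and report per-region counts and percentages."""
    labels = ceg_labels(reference, predicted)
    n = len(labels)
    counts = {region: int(np.sum(labels == region)) for region in CEG_REGIONS}
    percentages = {region: 100.0 * counts[region] / n for region in CEG_REGIONS}
    return CegResult(labels=labels, percentages=percentages, counts=counts, n_points=n)


def mard(reference, predicted) -> float:
    """Mean absolute relative difference, percent."""
    ref, pred = _validate_pairs(reference, predicted)
    if np.any(ref <= 0):
        raise ValueError("reference values must be positive for MARD")
    return float(100.0 * np.mean(np.abs(pred - ref) / ref))


def rmse(reference, predicted) -> float:
    """Root mean squared error, mg/dL."""
    ref, pred = _validate_pairs(reference, predicted)
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def regression_report(
    reference, predicted, confidence: float = 0.95
) -> Dict[str, float | Tuple[float, float]]:
    """OLS of predicted on reference: slope/intercept with CIs, SE, R^2, r.

    SE is the residual standard error sqrt(SSR / (n - 2)); R^2 equals the
    squared Pearson correlation for this simple regression.
    """
    ref, pred = _validate_pairs(reference, predicted)
    n = len(ref)
    if n < 3:
        raise ValueError("regression needs at least 3 pairs")
    if np.ptp(ref) == 0:
        raise ValueError("degenerate reference variance")
    fit = sstats.linregress(ref, pred)
    resid = pred - (fit.intercept + fit.slope * ref)
    se = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    crit = sstats.t.ppf(0.5 + confidence / 2.0, n - 2)
    r = float(fit.rvalue)
    if np.isnan(r):  # constant predictions: zero correlation by convention
        r = 0.0
    return {
        "slope": float(fit.slope),
        "slope_ci": (
            float(fit.slope - crit * fit.stderr),
            float(fit.slope + crit * fit.stderr),
        ),
        "intercept": float(fit.intercept),
        "intercept_ci": (
            float(fit.intercept - crit * fit.intercept_stderr),
            float(fit.intercept + crit * fit.intercept_stderr),
        ),
        "standard_error": se,
        "r_squared": r * r,
        "pearson_r": r,
    }


def iso_tolerance_rate(
    reference,
    predicted,
    low_band: float = 15.0,
    high_band: float = 20.0,
    cutoff: float = 100.0,
) -> float:
    """Percent of pairs within the glucometer tolerance bands.

    A pair is compliant when |predicted - reference| <= 15 mg/dL for
    reference < 100 mg/dL, or <= 20 mg/dL for reference >= 100 mg/dL
    (bands and cutoff configurable).
    """
    ref, pred = _validate_pairs(reference, predicted)
    band = np.where(ref < cutoff, low_band, high_band)
    ok = np.abs(pred - ref) <= band
    return float(100.0 * np.mean(ok))


def evaluate(reference, predicted) -> EvaluationReport:
    """All clinical metrics for one set of (reference, predicted) pairs."""
    ref, pred = _validate_pairs(reference, predicted)
    reg = regression_report(ref, pred)
    return EvaluationReport(
        rmse=rmse(ref, pred),
        mard=mard(ref, pred),
        pearson_r=reg["pearson_r"],
        slope=reg["slope"],
        slope_ci=reg["slope_ci"],
        intercept=reg["intercept"],
        intercept_ci=reg["intercept_ci"],
        standard_error=reg["standard_error"],
        r_squared=reg["r_squared"],
        iso_within_tolerance=iso_tolerance_rate(ref, pred),
        ceg=ceg_summary(ref, pred),
    )
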