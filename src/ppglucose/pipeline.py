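"""End-to-end driver: simulate/load -> preprocess -> QC -> features ->
high/low statistics -> day-wise split -> train -> predict -> aggregate ->
clinical evaluation, one model and report per subject.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from ppglucose.config import PipelineConfig
from ppglucose.cycles import (
    FEATURE_NAMES,
    build_template,
    features_frame,
    filter_cycles,
    segment_cycles,
)
from ppglucose.evaluation import EvaluationReport, evaluate
from ppglucose.modelling import (
    SplitSpec,
    TrainedModel,
    aggregate_predictions,
    predict,
    split_by_day,
    tune_and_train,
)
from ppglucose.preprocessing import preprocess
from ppglucose.stats import rank_features, split_by_fasting_mean
from ppglucose.synthetic import (
    RawRecording,
    SimulationSchedule,
    SubjectProfile,
    default_profiles,
    gen_cohort,
)

log = logging.getLogger("ppglucose")


@dataclass
class SubjectResult:
    """Everything produced for one subject."""

    subject_id: str
    features: pd.DataFrame  # per-valid-cycle feature table
    qc: pd.DataFrame  # per-recording cycle bookkeeping
    fasting_threshold: float
    feature_ranking: pd.DataFrame | None
    model: TrainedModel
    predictions: pd.DataFrame  # evaluated pairs (+ metadata)
    report: EvaluationReport


@dataclass
class PipelineResult:
    subjects: Dict[str, SubjectResult]
    config: PipelineConfig

    @property
    def qc_table(self) -> pd.DataFrame:
        return pd.concat([s.qc for s in self.subjects.values()], ignore_index=True)


def extract_recording_features(
    recording: RawRecording, config: PipelineConfig
) -> Tuple[pd.DataFrame, dict]:
    """Preprocess + segment + QC + features for one recording.

    Returns the per-cycle feature rows and a QC bookkeeping dict
    (total / valid cycle counts and the retained fraction).
    """
    processed = preprocess(
        recording,
        dc_order=config.dc_filter_order,
        dc_cutoff_hz=config.dc_cutoff_hz,
        ac_order=config.ac_filter_order,
        ac_band_hz=config.ac_band_hz,
        upsample_factor=config.upsample_factor,
        min_peak_separation_s=config.min_peak_separation_s,
        peak_prominence_frac=config.peak_prominence_frac,
    )
    cycles = segment_cycles(processed)
    template = build_template(cycles, config.template_length)
    valid, rejected, correlations = filter_cycles(cycles, template, config.r_min)
    valid_r = [r for r in correlations if r >= config.r_min]
    frame = features_frame(
        valid,
        correlations=valid_r,
        od_log_base=config.od_log_base,
        subject_id=recording.subject_id,
        day=recording.day_index,
        timepoint_min=recording.timepoint,
        repeat=recording.repeat,
    )
    qc = {
        "subject_id": recording.subject_id,
        "recording_id": recording.recording_id,
        "day": recording.day_index,
        "timepoint_min": recording.timepoint,
        "repeat": recording.repeat,
        "n_cycles": len(cycles),
        "n_valid": len(valid),
        "retained_fraction": len(valid) / len(cycles) if cycles else float("nan"),
    }
    return frame, qc


def run_pipeline(
    config: PipelineConfig | None = None,
    recordings: Sequence[RawRecording] | None = None,
    profiles: Sequence[SubjectProfile] | None = None,
    schedule: SimulationSchedule | None = None,
) -> PipelineResult:
    """Run the full analysis; simulates the default cohort when no
    recordings are given. Fully seeded and deterministic."""
    if config is None:
        config = PipelineConfig()
    if recordings is None:
        if profiles is None:
            profiles = default_profiles()
        if schedule is None:
            schedule = SimulationSchedule(seed=config.seed)
        log.info("simulating cohort: %d subjects, seed %d", len(profiles), schedule.seed)
        recordings, _ = gen_cohort(profiles, schedule)

    by_subject: Dict[str, List[RawRecording]] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject_id, []).append(rec)

    spec = SplitSpec(
        train_days=config.train_days,
        test_days=config.test_days,
        cv_folds=config.cv_folds,
    )

    subjects: Dict[str, SubjectResult] = {}
    for subject_id, recs in by_subject.items():
        frames, qc_rows = [], []
        for rec in recs:
            frame, qc = extract_recording_features(rec, config)
            frames.append(frame)
            qc_rows.append(qc)
            log.info(
                "%s: %d/%d cycles retained (%.1f%%)",
                qc["recording_id"], qc["n_valid"], qc["n_cycles"],
                100.0 * qc["retained_fraction"],
            )
        features = pd.concat(frames, ignore_index=True)
        qc_table = pd.DataFrame(qc_rows)

        fasting_bgls = [r.reference_bgl for r in recs if r.timepoint < 0]
        split = split_by_fasting_mean(features, fasting_bgls)
        ranking = None
        if len(split.low) and len(split.high):
            ranking = rank_features(
                split, FEATURE_NAMES, equal_var=config.equal_var_ttest
            )

        train, test = split_by_day(features, spec)
        log.info(
            "%s: %d cycles total, %d train / %d test",
            subject_id, len(features), len(train), len(test),
        )
        model = tune_and_train(
            train,
            subject_id=subject_id,
            folds=config.cv_folds,
            seed=config.seed,
            n_draws=config.n_search_draws,
            tuning_subsample=config.tuning_subsample,
        )
        log.info(
            "%s: chose %s %s (CV RMSE %.2f mg/dL)",
            subject_id, model.method, model.hyperparameters, model.cv_rmse,
        )
        preds = predict(model, test)
        if config.eval_level == "recording":
            pairs = aggregate_predictions(test, preds, stat=config.aggregate_stat)
        else:
            pairs = test[["recording_id", "bgl_label"]].copy()
            pairs = pairs.rename(columns={"bgl_label": "reference_bgl"})
            pairs["predicted_bgl"] = preds
        report = evaluate(
            pairs["reference_bgl"].to_numpy(), pairs["predicted_bgl"].to_numpy()
        )
        subjects[subject_id] = SubjectResult(
            subject_id=subject_id,
            features=features,
            qc=qc_table,
            fasting_threshold=split.threshold,
            feature_ranking=ranking,
            model=model,
            predictions=pairs,
            report=report,
        )
    return PipelineResult(subjects=subjects, config=config)
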