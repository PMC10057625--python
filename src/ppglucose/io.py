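"""On-disk cohort format: per-recording DSV traces, metadata table, manifest.

Layout of a cohort directory:

  manifest.json             schema version, seed, generator config hash
  metadata.csv              one row per recording (subject, day, timepoint,
                            repeat, sampling rate, reference BGL, file name)
  <SUBJECT>_dDD_tTTT_rR.csv columns time_s, ppg
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from ppglucose.synthetic import RawRecording

SCHEMA_VERSION = 1

METADATA_COLUMNS = [
    "subject_id",
    "day",
    "timepoint_min",
    "repeat",
    "sampling_rate_hz",
    "reference_bgl_mgdl",
    "file",
]


def _recording_filename(rec: RawRecording) -> str:
    return rec.recording_id + ".csv"


def write_cohort(
    recordings: Sequence[RawRecording],
    out_dir: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
) -> Path:
    """Write recordings, metadata.csv and manifest.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = _recording_filename(rec)
        t = np.arange(len(rec.samples)) / rec.sampling_rate
        pd.DataFrame({"time_s": t, "ppg": rec.samples}).to_csv(
            out / fname, index=False, float_format="%.8g"
        )
        row = {
            "subject_id": rec.subject_id,
            "day": rec.day_index,
            "timepoint_min": rec.timepoint,
            "repeat": rec.repeat,
            "sampling_rate_hz": rec.sampling_rate,
            "reference_bgl_mgdl": rec.reference_bgl,
            "file": fname,
        }
        if rec.true_bgl is not None:
            row["true_bgl_mgdl"] = rec.true_bgl
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "metadata.csv", index=False)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "config_hash": config_hash,
        "n_recordings": len(recordings),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def read_cohort(path: str | Path) -> Tuple[List[RawRecording], pd.DataFrame]:
    """Read a cohort directory back into RawRecording objects + metadata.

    Raises with an explicit diagnostic (row number, file name) on a missing
    trace file, malformed number or unsupported schema version.
    """
    root = Path(path)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {root}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported cohort schema version {version!r} "
            f"(expected {SCHEMA_VERSION})"
        )
    meta_path = root / "metadata.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.csv in {root}")
    meta = pd.read_csv(meta_path)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata.csv missing columns: {missing_cols}")

    recordings: List[RawRecording] = []
    for i, row in meta.iterrows():
        fpath = root / str(row["file"])
        if not fpath.exists():
            raise FileNotFoundError(
                f"metadata row {i} ({row['subject_id']}): missing file {fpath.name}"
            )
        trace = pd.read_csv(fpath)
        if "ppg" not in trace.columns:
            raise ValueError(f"metadata row {i}: {fpath.name} lacks a 'ppg' column")
        rate = float(row["sampling_rate_hz"])
        if not np.isfinite(rate) or rate <= 0:
            raise ValueError(f"metadata row {i}: invalid sampling rate {rate!r}")
        true_bgl = (
            float(row["true_bgl_mgdl"])
            if "true_bgl_mgdl" in meta.columns and pd.notna(row.get("true_bgl_mgdl"))
            else None
        )
        recordings.append(
            RawRecording(
                subject_id=str(row["subject_id"]),
                day_index=int(row["day"]),
                timepoint=float(row["timepoint_min"]),
                repeat=int(row["repeat"]),
                sampling_rate=rate,
                samples=trace["ppg"].to_numpy(dtype=float),
                reference_bgl=float(row["reference_bgl_mgdl"]),
                true_bgl=true_bgl,
            )
        )
    return recordings, meta
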