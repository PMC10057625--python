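"""Pipeline configuration: every tunable of every stage, with defaults."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import yaml


@dataclass
class PipelineConfig:
    # pre-processing
    dc_filter_order: int = 10
    dc_cutoff_hz: float = 0.01
    ac_filter_order: int = 8
    ac_band_hz: Tuple[float, float] = (0.3, 10.0)
    upsample_factor: int = 4
    min_peak_separation_s: float = 0.3
    peak_prominence_frac: float = 0.3
    # cycle QC / features
    template_length: int = 100
    r_min: float = 0.90
    od_log_base: float = 10.0
    # statistics
    alpha: float = 0.05
    equal_var_ttest: bool = False
    top_k_features: int = 10
    # modelling
    train_days: Tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    test_days: Tuple[int, ...] = (8, 9)
    cv_folds: int = 5
    n_search_draws: int = 6
    tuning_subsample: int = 1500
    # evaluation
    eval_level: str = "recording"  # or "cycle"
    aggregate_stat: str = "mean"  # or "median"
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        if self.upsample_factor < 1:
            raise ValueError("upsample_factor must be >= 1")
        if not (0.0 < self.r_min <= 1.0):
            raise ValueError("r_min must be in (0, 1]")
        if set(self.train_days) & set(self.test_days):
            raise ValueError("train_days and test_days must be disjoint")
        if self.eval_level not in ("recording", "cycle"):
            raise ValueError("eval_level must be 'recording' or 'cycle'")
        if self.aggregate_stat not in ("mean", "median"):
            raise ValueError("aggregate_stat must be 'mean' or 'median'")
        if self.ac_band_hz[0] >= self.ac_band_hz[1]:
            raise ValueError("ac_band_hz must be (low, high) with low < high")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ac_band_hz"] = list(self.ac_band_hz)
        d["train_days"] = list(self.train_days)
        d["test_days"] = list(self.test_days)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        clean = dict(data)
        for key in ("ac_band_hz", "train_days", "test_days"):
            if key in clean and isinstance(clean[key], list):
                clean[key] = tuple(clean[key])
        return cls(**clean)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)
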