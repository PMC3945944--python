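"""Pipeline configuration.

Every threshold of the analysis lives here with its field-standard default:
3-m dive definition, 15-m deep-dive threshold, 0.4 m/s vertical-rate
threshold, 8-s step cap, 3-s wiggle gap, 60 % depth fraction for transit
steps, 85 % deep-dive-cycle coverage for aggregate windows, 0.95
cumulative-Akaike-weight candidate set, 3-Hz high-pass cutoff and
1.5 s / 5 s moving-variance windows for mouth-opening detection.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: temporal scales at which predictive models are built
SCALES = ("dive", "bout", "win30", "win60", "win120", "night")

#: window length in seconds for the fixed-duration scales
WINDOW_SECONDS = {"win30": 1800, "win60": 3600, "win120": 7200}


@dataclass
class SegmentationConfig:
    """Dive detection and phase segmentation thresholds."""

    dive_threshold_m: float = 3.0      # a dive exceeds this depth
    deep_threshold_m: float = 15.0     # dives entering the models exceed this
    rate_threshold_ms: float = 0.4     # vertical speed delimiting descent/ascent
    step_max_s: float = 8.0            # a step lasts strictly less than this
    step_depth_fraction: float = 0.6   # transit steps occur before this fraction of max depth
    surface_eps_m: float = 0.5         # depth at which a dive is considered to reach surface
    min_surface_records: int = 10      # below this, offset trend is linear not spline


@dataclass
class FeatureConfig:
    wiggle_gap_s: float = 3.0          # max gap between ascending and descending bottom step
    wiggle_either_order: bool = False  # strict ascending-then-descending by default


@dataclass
class BoutConfig:
    criterion_variable: str = "diffs"  # "diffs" (abs successive differences) | "raw_intervals"
    min_intervals: int = 20
    min_bout_dives: int = 3


@dataclass
class PcaConfig:
    sensor_kind: str = "accelerometer"  # or "hall"
    highpass_cutoff_hz: float = 3.0
    variance_window_s: float = 1.5      # accelerometer window
    hall_window_s: float = 5.0          # Hall-sensor window (slower return to baseline)
    threshold_rule: str = "robust"      # "robust" (median + k*MADn) | "moment" (mean + k*sd) | "absolute"
    threshold_k: float = 6.0
    threshold_abs: float | None = None
    merge_gap_s: float = 0.5


@dataclass
class AggregateConfig:
    coverage_min: float = 0.85          # deep-dive-cycle coverage for bout/window rows


@dataclass
class ModelConfig:
    weight_threshold: float = 0.95
    n_quad: int = 15                    # adaptive Gauss-Hermite nodes
    rows_per_variable: int = 10
    # per-scale caps on the number of predictors tested jointly
    max_vars: dict = field(default_factory=lambda: {
        "dive": 11, "bout": 7, "win30": 13, "win60": 13, "win120": 4, "night": 2,
    })
    # the night scale uses a plain Poisson GLM (too few rows for a random effect)
    random_intercept: dict = field(default_factory=lambda: {
        "dive": True, "bout": True, "win30": True, "win60": True,
        "win120": True, "night": False,
    })


@dataclass
class PipelineConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    seed: int = 0
    scales: tuple = SCALES
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    bouts: BoutConfig = field(default_factory=BoutConfig)
    pca: PcaConfig = field(default_factory=PcaConfig)
    aggregate: AggregateConfig = field(default_factory=AggregateConfig)
    models: ModelConfig = field(default_factory=ModelConfig)
    write_raw_accel: bool = False      # raw 16-Hz streams are regenerable from the manifest
    run_loocv: bool = True

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scales"] = list(self.scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("segmentation", SegmentationConfig), ("features", FeatureConfig),
            ("bouts", BoutConfig), ("pca", PcaConfig),
            ("aggregate", AggregateConfig), ("models", ModelConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "scales" in d:
            d["scales"] = tuple(d["scales"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
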