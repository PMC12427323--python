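"""Pipeline configuration: flat key-value config with presets.

A config round-trips through a single flat JSON file; unknown keys are
rejected by name. The ``desk`` preset is the default development scale
(6x6-frame slides, 512 px frames, 2000 common events); ``full`` reproduces the
production scan geometry (48x48 = 2304 frame positions, 761 features, ~3M
cells per slide) and is config-reachable but never the default; ``mini`` is a
fast scale for smoke runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

ALL_STAGES = ("simulate", "segment", "ocular", "train", "classify",
              "enumerate", "compare")


@dataclass
class PipelineConfig:
    preset: str = "desk"
    seed: int = 0
    out_root: str = "rarecell_run"
    stages: tuple[str, ...] = ALL_STAGES
    write_frames: bool = False  # TIFF export of simulated frames (large)

    # synthetic-slide geometry
    grid_rows: int = 6
    grid_cols: int = 6
    frame_px: int = 512
    n_common_events: int = 2000

    # spiking of the training and evaluation slides
    train_rare_mean_per_type: float = 5.0
    eval_rare_mean_per_type: float = 4.0
    bubble_rate: float = 4.0
    flare_rate: float = 4.0

    # smaller additional cohort slides (2 samples per cohort minimum)
    cohort_grid_rows: int = 3
    cohort_grid_cols: int = 3
    cohort_n_common_events: int = 450
    n_samples_per_cohort: int = 2

    # feature schema / OCULAR / classification
    n_features: int = 761
    n_components: int = 350
    cluster_size_max: int = 10
    distance_quantile: float = 0.999
    cut_height_quantile: float = 0.99
    cv_k: int = 5
    cv_iterations: int = 50
    confidence_threshold: float = 0.5
    n_background_negatives: int = 200

    # enumeration
    nominal_volume_ml: float = 0.5
    alpha: float = 0.05

    def validate(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}")
        if not 0 < self.confidence_threshold < 1:
            raise ValueError("confidence_threshold must be in (0, 1)")


PRESETS: dict[str, dict] = {
    "desk": {},
    "mini": {
        "grid_rows": 2, "grid_cols": 2, "frame_px": 256,
        "n_common_events": 150, "train_rare_mean_per_type": 2.0,
        "eval_rare_mean_per_type": 2.0, "bubble_rate": 1.0, "flare_rate": 1.0,
        "cohort_grid_rows": 2, "cohort_grid_cols": 2,
        "cohort_n_common_events": 80, "cv_iterations": 5,
        "n_components": 50,
    },
    "full": {
        "grid_rows": 48, "grid_cols": 48, "frame_px": 1024,
        "n_common_events": 3_000_000, "train_rare_mean_per_type": 50.0,
        "eval_rare_mean_per_type": 50.0, "bubble_rate": 40.0, "flare_rate": 40.0,
        "cv_iterations": 1000,
    },
}


def make_config(preset: str = "desk", **overrides) -> PipelineConfig:
    """Build a config from a preset plus explicit overrides (unknown keys rejected)."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    merged = {"preset": preset, **PRESETS[preset], **overrides}
    unknown = set(merged) - valid
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "stages" in merged and not isinstance(merged["stages"], tuple):
        merged["stages"] = tuple(merged["stages"])
    cfg = PipelineConfig(**merged)
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    d = dataclasses.asdict(cfg)
    d["stages"] = list(cfg.stages)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a flat JSON config; any unrecognized key raises with its name."""
    with open(path) as fh:
        d = json.load(fh)
    preset = d.pop("preset", "desk")
    # preset defaults are baked into the saved file; apply overrides verbatim
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "stages" in d:
        d["stages"] = tuple(d["stages"])
    cfg = PipelineConfig(preset=preset, **d)
    cfg.validate()
    return cfg
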