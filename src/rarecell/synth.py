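"""Synthetic fluorescent whole-slide image generator with ground truth.

Emulates the statistical structure of a liquid-biopsy slide: a monolayer of
nucleated cells dominated by leukocyte-like common events (DAPI+/CD+), a handful
of spiked rare cells drawn from the 8 channel phenotypes, and non-biological
artifacts (bubbles, fluorescent flares). Cells are rendered as isotropic 2-D
Gaussian intensity profiles truncated at 3 sigma; bubbles as annular discs 5-20x
the cell radius; flares as near-saturated streaks spanning at least a quarter of
the frame width. Background is Gaussian read noise per channel. No optical PSF,
autofluorescence spectrum or stain chemistry is modelled.

Rare cells are rendered larger (default 1.8x radius) and brighter (default 2x
marker amplitude) than the leukocyte background — circulating tumor and
endothelial cells are typically larger than white blood cells, and this is what
makes a D|CD rare event morphometrically separable from the D|CD leukocyte bulk.

A fixed seed reproduces the slide bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .frames import CHANNELS, FrameGrid, FrameStack
from .phenotypes import CELL_TYPES, positivity_of

MAX_COUNT = 65535  # 16-bit saturation

ARTIFACT_CLASSES = ("artifact-bubble", "artifact-flare")


class PlacementError(RuntimeError):
    """Raised when an event cannot be placed without excessive overlap."""


@dataclass(frozen=True)
class ChannelIntensity:
    """Foreground/background intensity model of one channel (16-bit counts)."""

    bg_mean: float = 300.0
    bg_sd: float = 30.0
    fg_mean: float = 3000.0
    fg_sd: float = 300.0

    def validate(self, name: str) -> None:
        if self.fg_mean <= self.bg_mean:
            raise ValueError(f"channel {name}: foreground mean must exceed background mean")
        if self.bg_sd < 0 or self.fg_sd < 0:
            raise ValueError(f"channel {name}: negative intensity sd")


def _default_rare_prevalence() -> dict[str, float]:
    return {t: 0.0 for t in CELL_TYPES}


def _default_intensity_model() -> dict[str, ChannelIntensity]:
    return {ch: ChannelIntensity() for ch in CHANNELS}


def _default_artifact_rates() -> dict[str, float]:
    return {"bubble": 0.0, "flare": 0.0}


@dataclass
class SyntheticSlideSpec:
    """Parameters of one synthetic slide.

    ``n_common_events`` common (leukocyte-like, D+/CD+) cells are placed exactly;
    rare-cell and artifact counts are drawn Poisson with the given expected
    counts per slide. Placement is uniform per frame with rejection resampling
    so that no two cells overlap by more than ~50%.
    """

    grid_rows: int = 6
    grid_cols: int = 6
    frame_height_px: int = 512
    frame_width_px: int = 512
    n_common_events: int = 2000
    rare_prevalence: dict[str, float] = field(default_factory=_default_rare_prevalence)
    artifact_rates: dict[str, float] = field(default_factory=_default_artifact_rates)
    intensity_model: dict[str, ChannelIntensity] = field(default_factory=_default_intensity_model)
    cell_radius_mean_px: float = 6.0
    cell_radius_sd_px: float = 1.0
    rare_radius_scale: float = 1.8
    rare_intensity_scale: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_common_events < 0:
            raise ValueError("n_common_events must be >= 0")
        if set(self.rare_prevalence) != set(CELL_TYPES):
            raise ValueError(
                "rare_prevalence must have exactly the 8 phenotype keys "
                f"{sorted(CELL_TYPES)}; got {sorted(self.rare_prevalence)}"
            )
        if any(v < 0 for v in self.rare_prevalence.values()):
            raise ValueError("rare prevalence values must be >= 0")
        if set(self.artifact_rates) - {"bubble", "flare"}:
            raise ValueError("artifact_rates keys must be within {bubble, flare}")
        if any(v < 0 for v in self.artifact_rates.values()):
            raise ValueError("artifact rates must be >= 0")
        if set(self.intensity_model) != set(CHANNELS):
            raise ValueError(f"intensity_model must cover channels {CHANNELS}")
        for name, model in self.intensity_model.items():
            model.validate(name)
        if self.cell_radius_mean_px <= 0:
            raise ValueError("cell radius must be positive")

    @property
    def grid(self) -> FrameGrid:
        return FrameGrid(self.grid_rows, self.grid_cols)


@dataclass
class GroundTruthEvent:
    """True identity of one rendered object, for spike-recovery evaluation."""

    event_id: int
    frame_row: int
    frame_col: int
    centroid_row: float
    centroid_col: float
    radius_px: float
    true_class: str  # "common", a rare phenotype, or artifact-bubble/-flare
    ck_positive: bool
    v_positive: bool
    cd_positive: bool
    d_positive: bool

    @property
    def is_rare(self) -> bool:
        return self.true_class in CELL_TYPES

    @property
    def is_artifact(self) -> bool:
        return self.true_class in ARTIFACT_CLASSES


def _render_gaussian(frame: np.ndarray, r: float, c: float, radius: float, amp: float) -> None:
    """Add an isotropic Gaussian blob (sigma = radius/2, truncated at 3 sigma)."""
    sigma = radius / 2.0
    t = int(np.ceil(3 * sigma))
    h, w = frame.shape
    r0, r1 = max(0, int(r) - t), min(h, int(r) + t + 1)
    c0, c1 = max(0, int(c) - t), min(w, int(c) + t + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = (rr - r) ** 2 + (cc - c) ** 2
    blob = amp * np.exp(-d2 / (2 * sigma**2))
    blob[d2 > (3 * sigma) ** 2] = 0.0
    frame[r0:r1, c0:c1] += blob


def _render_ring(frame: np.ndarray, r: float, c: float, radius: float, thick: float, amp: float) -> None:
    h, w = frame.shape
    t = int(np.ceil(radius + thick))
    r0, r1 = max(0, int(r) - t), min(h, int(r) + t + 1)
    c0, c1 = max(0, int(c) - t), min(w, int(c) + t + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.sqrt((rr - r) ** 2 + (cc - c) ** 2)
    ring = amp * np.exp(-((d - radius) ** 2) / (2 * (thick / 2.0) ** 2))
    frame[r0:r1, c0:c1] += ring


class _Placer:
    """Uniform placement with rejection of >50% pairwise overlap, per frame."""

    def __init__(self, spec: SyntheticSlideSpec, rng: np.random.Generator, max_tries: int = 100):
        self.spec = spec
        self.rng = rng
        self.max_tries = max_tries
        self.placed: dict[int, list[tuple[float, float, float]]] = {}

    def place(self, radius: float) -> tuple[int, float, float]:
        spec = self.spec
        h, w = spec.frame_height_px, spec.frame_width_px
        margin = np.ceil(1.5 * radius)  # 3 sigma: keep the blob fully inside
        if 2 * margin >= h or 2 * margin >= w:
            raise PlacementError(
                f"frame {h}x{w} too small for an event of radius {radius:.1f} px"
            )
        n_pos = spec.grid.n_positions
        for _ in range(self.max_tries):
            pos = int(self.rng.integers(n_pos))
            r = self.rng.uniform(margin, h - 1 - margin)
            c = self.rng.uniform(margin, w - 1 - margin)
            ok = True
            for pr, pc, prad in self.placed.get(pos, ()):
                # centre distance below ~70% of the summed radii ~ >50% overlap
                if (pr - r) ** 2 + (pc - c) ** 2 < (0.7 * (prad + radius)) ** 2:
                    ok = False
                    break
            if ok:
                self.placed.setdefault(pos, []).append((r, c, radius))
                return pos, r, c
        raise PlacementError(
            f"could not place event of radius {radius:.1f} px after "
            f"{self.max_tries} tries; slide too crowded"
        )


def generate_slide(
    spec: SyntheticSlideSpec, slide_id: str = "slide"
) -> tuple[FrameStack, list[GroundTruthEvent]]:
    """Render one synthetic slide and return its frames plus ground truth.

    Deterministic for a fixed ``spec.seed`` (bitwise-identical frames).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    h, w = spec.frame_height_px, spec.frame_width_px

    # background read noise, per channel
    frames = np.empty((grid.n_positions, len(CHANNELS), h, w), dtype=np.float64)
    for ci, ch in enumerate(CHANNELS):
        m = spec.intensity_model[ch]
        frames[:, ci] = rng.normal(m.bg_mean, m.bg_sd, size=(grid.n_positions, h, w))

    placer = _Placer(spec, rng)
    truth: list[GroundTruthEvent] = []
    eid = 0

    def draw_radius(scale: float = 1.0) -> float:
        r = rng.normal(scale * spec.cell_radius_mean_px, spec.cell_radius_sd_px)
        return float(np.clip(r, 2.0, None))

    def render_cell(true_class: str, ck: bool, v: bool, cd: bool, rare: bool) -> None:
        nonlocal eid
        radius = draw_radius(spec.rare_radius_scale if rare else 1.0)
        pos, r, c = placer.place(radius)
        boost = spec.rare_intensity_scale if rare else 1.0
        for ci, ch in enumerate(CHANNELS):
            positive = {"D": True, "CK": ck, "V": v, "CD": cd}[ch]
            if not positive:
                continue
            m = spec.intensity_model[ch]
            amp = max(rng.normal(boost * m.fg_mean, m.fg_sd), m.bg_mean + 5 * m.bg_sd)
            _render_gaussian(frames[pos, ci], r, c, radius, amp)
        fr, fc = grid.position_rc(pos)
        truth.append(
            GroundTruthEvent(eid, fr, fc, r, c, radius, true_class, ck, v, cd, True)
        )
        eid += 1

    for _ in range(spec.n_common_events):
        render_cell("common", ck=False, v=False, cd=True, rare=False)

    for ptype in CELL_TYPES:  # fixed order keeps the stream deterministic
        n = int(rng.poisson(spec.rare_prevalence[ptype]))
        ck, v, cd = positivity_of(ptype)
        for _ in range(n):
            render_cell(ptype, ck, v, cd, rare=True)

    # artifacts: fluoresce across channels but are biologically negative
    mean_fg = float(np.mean([spec.intensity_model[ch].fg_mean for ch in CHANNELS]))
    n_bubbles = int(rng.poisson(spec.artifact_rates.get("bubble", 0.0)))
    for _ in range(n_bubbles):
        radius = rng.uniform(5, 20) * spec.cell_radius_mean_px
        pos = int(rng.integers(grid.n_positions))
        r = rng.uniform(0, h - 1)
        c = rng.uniform(0, w - 1)
        thick = max(radius / 8.0, 2.0)
        for ci in range(len(CHANNELS)):
            _render_ring(frames[pos, ci], r, c, radius, thick, 0.6 * mean_fg)
        fr, fc = grid.position_rc(pos)
        truth.append(
            GroundTruthEvent(eid, fr, fc, r, c, radius, "artifact-bubble",
                             False, False, False, False)
        )
        eid += 1

    n_flares = int(rng.poisson(spec.artifact_rates.get("flare", 0.0)))
    for _ in range(n_flares):
        pos = int(rng.integers(grid.n_positions))
        length = int(rng.uniform(0.25, 0.6) * w)
        height = int(rng.uniform(3, 8))
        r = int(rng.uniform(0, h - height))
        c = int(rng.uniform(0, w - length))
        frames[pos, :, r : r + height, c : c + length] = MAX_COUNT
        fr, fc = grid.position_rc(pos)
        truth.append(
            GroundTruthEvent(eid, fr, fc, r + height / 2.0, c + length / 2.0,
                             length / 2.0, "artifact-flare", False, False, False, False)
        )
        eid += 1

    data = np.clip(frames, 0, MAX_COUNT).astype(np.uint16)
    return FrameStack(grid, data, slide_id=slide_id), truth


# ---------------------------------------------------------------------------
# on-disk layout


def truth_to_table(truth: list[GroundTruthEvent]) -> pd.DataFrame:
    cols = [
        "event_id", "frame_row", "frame_col", "centroid_row", "centroid_col",
        "radius_px", "true_class", "ck_positive", "v_positive", "cd_positive",
        "d_positive",
    ]
    rows = [[getattr(t, c) for c in cols] for t in truth]
    return pd.DataFrame(rows, columns=cols)


def write_slide(
    stack: FrameStack,
    truth: list[GroundTruthEvent],
    out_dir: str | Path,
    overwrite: bool = False,
) -> dict:
    """Write one TIFF per (frame, channel), the ground-truth TSV and a manifest.

    Refuses an existing non-empty directory unless ``overwrite`` is set.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty; pass overwrite=True to replace")
    out.mkdir(parents=True, exist_ok=True)

    grid = stack.grid
    tiffs = []
    for pos in range(grid.n_positions):
        fr, fc = grid.position_rc(pos)
        for ch in grid.channels:
            name = f"{stack.slide_id}_r{fr:03d}_c{fc:03d}_{ch}.tif"
            tifffile.imwrite(out / name, stack.frame(pos, ch))
            tiffs.append(name)

    truth_name = f"{stack.slide_id}_truth.tsv"
    truth_to_table(truth).to_csv(out / truth_name, sep="\t", index=False)

    manifest = {
        "slide_id": stack.slide_id,
        "grid_rows": grid.rows,
        "grid_cols": grid.cols,
        "channels": list(grid.channels),
        "frame_height_px": stack.frame_shape[0],
        "frame_width_px": stack.frame_shape[1],
        "n_frames": grid.n_frames,
        "frames": tiffs,
        "truth": truth_name,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_slide(slide_dir: str | Path) -> tuple[FrameStack, pd.DataFrame]:
    """Round-trip reader for :func:`write_slide` output."""
    slide_dir = Path(slide_dir)
    with open(slide_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    grid = FrameGrid(manifest["grid_rows"], manifest["grid_cols"],
                     tuple(manifest["channels"]))
    h, w = manifest["frame_height_px"], manifest["frame_width_px"]
    data = np.empty((grid.n_positions, len(grid.channels), h, w), dtype=np.uint16)
    it = iter(manifest["frames"])
    for pos in range(grid.n_positions):
        for ci in range(len(grid.channels)):
            data[pos, ci] = tifffile.imread(slide_dir / next(it))
    truth = pd.read_csv(slide_dir / manifest["truth"], sep="\t")
    return FrameStack(grid, data, slide_id=manifest["slide_id"]), truth
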