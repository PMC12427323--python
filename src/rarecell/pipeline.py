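"""End-to-end orchestration: simulate -> segment -> OCULAR -> train -> classify
-> enumerate -> compare.

Each stage writes its tabular outputs (tab-separated) and appends an entry to
the run manifest (parameters, seed, outputs, event counts), so the event
funnel — total nucleated events, OCULAR candidates, interesting events, typed
rare cells — is recorded at every filtering step. Rerunning with an identical
config reproduces identical tabular outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import classify as clf
from .cohort import compare_cohorts, plot_cohort_counts, plot_embedding, umap_embed
from .config import ALL_STAGES, PipelineConfig
from .enumeration import census_from_typed_events, cohort_table, normalize_counts
from .features import FeatureSchema, SchemaParams, build_feature_schema, segment_slide
from .ocular import OcularParams, run_ocular
from .phenotypes import CELL_TYPES
from .synth import SyntheticSlideSpec, generate_slide, truth_to_table, write_slide

log = logging.getLogger(__name__)

#: Relative spiked-cell abundance per phenotype (x eval_rare_mean_per_type).
#: The "early" profile is enriched for epithelial-involved phenotypes; "nd"
#: (normal donor) carries only a sparse rare-cell background.
COHORT_PROFILES: dict[str, dict[str, float]] = {
    "early": {"D": 0.5, "D|CK": 1.5, "D|V": 1.0, "D|CD": 0.5, "D|CK|V": 0.5,
              "D|CK|CD": 1.0, "D|V|CD": 1.0, "D|CK|V|CD": 1.5},
    "nd": {"D": 0.5, "D|CK": 0.1, "D|V": 0.5, "D|CD": 0.25, "D|CK|V": 0.1,
           "D|CK|CD": 0.1, "D|V|CD": 0.5, "D|CK|V|CD": 0.1},
}

TRAIN_SLIDE = "train"
SPIKE_SLIDE = "E1"


class StageError(RuntimeError):
    """A pipeline stage failed; the partial manifest is preserved on disk."""


def _sub_seed(seed: int, i: int) -> int:
    return int((seed * 9973 + 7919 * i + 1) % (2**31))


@dataclass
class RunState:
    """In-memory hand-off between stages."""

    schema: FeatureSchema | None = None
    stacks: dict = field(default_factory=dict)          # sample_id -> FrameStack
    truths: dict = field(default_factory=dict)          # sample_id -> list[GroundTruthEvent]
    cohorts: dict = field(default_factory=dict)         # sample_id -> cohort label
    events: dict = field(default_factory=dict)          # sample_id -> event table
    candidates: dict = field(default_factory=dict)      # sample_id -> ocular-augmented table
    interesting_model: object = None
    channel_trio: object = None
    typed: dict = field(default_factory=dict)           # sample_id -> typed candidate table
    censuses: dict = field(default_factory=dict)
    cohort_counts: pd.DataFrame | None = None
    sweep: pd.DataFrame | None = None
    spike_recovery: dict | None = None


def slide_plan(cfg: PipelineConfig) -> list[tuple[str, str, SyntheticSlideSpec]]:
    """The slides one run simulates: a labeled training slide, a desk-scale
    spike-evaluation slide, and smaller per-cohort samples."""
    plan: list[tuple[str, str, SyntheticSlideSpec]] = []

    def spec(rows, cols, n_common, rare, bubbles, flares, i):
        return SyntheticSlideSpec(
            grid_rows=rows, grid_cols=cols,
            frame_height_px=cfg.frame_px, frame_width_px=cfg.frame_px,
            n_common_events=n_common,
            rare_prevalence=rare,
            artifact_rates={"bubble": bubbles, "flare": flares},
            seed=_sub_seed(cfg.seed, i),
        )

    train_rare = {t: cfg.train_rare_mean_per_type for t in CELL_TYPES}
    plan.append((TRAIN_SLIDE, TRAIN_SLIDE,
                 spec(cfg.grid_rows, cfg.grid_cols, cfg.n_common_events,
                      train_rare, cfg.bubble_rate, cfg.flare_rate, 0)))

    i = 1
    for cohort in ("early", "nd"):
        profile = {t: cfg.eval_rare_mean_per_type * COHORT_PROFILES[cohort][t]
                   for t in CELL_TYPES}
        for j in range(cfg.n_samples_per_cohort):
            sid = f"{cohort[0].upper()}{j + 1}"
            if cohort == "early" and j == 0:
                # the spike-evaluation slide runs at full desk scale
                plan.append((sid, cohort,
                             spec(cfg.grid_rows, cfg.grid_cols,
                                  cfg.n_common_events, profile,
                                  cfg.bubble_rate / 2, cfg.flare_rate / 2, i)))
            else:
                plan.append((sid, cohort,
                             spec(cfg.cohort_grid_rows, cfg.cohort_grid_cols,
                                  cfg.cohort_n_common_events, profile,
                                  1.0, 1.0, i)))
            i += 1
    return plan


def match_truth_to_events(
    truth_df: pd.DataFrame, events: pd.DataFrame, tol_scale: float = 1.5
) -> pd.Series:
    """For each ground-truth object, the index of the nearest detected event
    on the same frame within ``tol_scale x radius`` (min 5 px), else -1."""
    match = pd.Series(-1, index=truth_df.index, dtype=int)
    for (fr, fc), tgrp in truth_df.groupby(["frame_row", "frame_col"]):
        egrp = events[(events["frame_row"] == fr) & (events["frame_col"] == fc)]
        if egrp.empty:
            continue
        tree = cKDTree(egrp[["centroid_row", "centroid_col"]].to_numpy())
        pts = tgrp[["centroid_row", "centroid_col"]].to_numpy()
        dist, idx = tree.query(pts)
        tol = np.maximum(tol_scale * tgrp["radius_px"].to_numpy(), 5.0)
        ok = dist <= tol
        match.loc[tgrp.index[ok]] = egrp.index.to_numpy()[idx[ok]]
    return match


def evaluate_spike_recovery(
    truth_df: pd.DataFrame, typed_candidates: pd.DataFrame, events: pd.DataFrame,
    threshold: float,
) -> dict:
    """Fraction of planted rare cells that survive detection, OCULAR, the
    interesting filter at the given confidence threshold, and receive their
    true phenotype."""
    rare = truth_df[truth_df["true_class"].isin(CELL_TYPES)]
    match = match_truth_to_events(rare, events)
    n_planted = len(rare)
    n_detected = int((match >= 0).sum())
    n_recovered = 0
    n_flagged = 0
    for tidx, eidx in match.items():
        if eidx < 0:
            continue
        row = typed_candidates[typed_candidates["event_index"] == eidx]
        if row.empty or not bool(row["is_candidate"].iloc[0]):
            continue
        n_flagged += 1
        if float(row["confidence"].iloc[0]) < threshold:
            continue
        if row["cell_type"].iloc[0] == rare.loc[tidx, "true_class"]:
            n_recovered += 1
    return {
        "n_planted": n_planted,
        "n_detected": n_detected,
        "n_candidates": n_flagged,
        "n_recovered": n_recovered,
        "recovery_pct": 100.0 * n_recovered / n_planted if n_planted else float("nan"),
    }


def _write(df: pd.DataFrame, path: Path) -> str:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return str(path)


def run_pipeline(cfg: PipelineConfig, out_root: str | Path | None = None) -> dict:
    """Run the enabled stage prefix; returns the run manifest.

    Stages run in their canonical order and stop at the first disabled stage;
    a stage failure aborts with the stage name while preserving the partial
    manifest on disk.
    """
    cfg.validate()
    out = Path(out_root if out_root is not None else cfg.out_root)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {**cfg.__dict__, "stages": list(cfg.stages)},
                      "stages": []}
    state = RunState()
    schema_params = SchemaParams(expected_length=cfg.n_features)
    state.schema = build_feature_schema(schema_params)

    def flush() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    stage_fns = {
        "simulate": _stage_simulate,
        "segment": _stage_segment,
        "ocular": _stage_ocular,
        "train": _stage_train,
        "classify": _stage_classify,
        "enumerate": _stage_enumerate,
        "compare": _stage_compare,
    }
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            log.info("stage %s disabled; stopping", stage)
            break
        log.info("running stage %s", stage)
        try:
            entry = stage_fns[stage](cfg, state, out)
        except Exception as exc:  # preserve partial manifest, name the stage
            manifest["failed_stage"] = stage
            flush()
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        entry["stage"] = stage
        manifest["stages"].append(entry)
        flush()
    if state.spike_recovery is not None:
        manifest["spike_recovery"] = state.spike_recovery
    flush()
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: PipelineConfig, state: RunState, out: Path) -> dict:
    outputs, counts = [], {}
    for sid, cohort, spec in slide_plan(cfg):
        stack, truth = generate_slide(spec, slide_id=sid)
        state.stacks[sid] = stack
        state.truths[sid] = truth
        state.cohorts[sid] = cohort
        outputs.append(_write(truth_to_table(truth), out / "simulate" / f"{sid}_truth.tsv"))
        if cfg.write_frames:
            man = write_slide(stack, truth, out / "simulate" / sid, overwrite=True)
            outputs.extend(str(out / "simulate" / sid / f) for f in man["frames"])
        counts[sid] = len(truth)
    return {"seed": cfg.seed, "outputs": outputs, "counts": counts}


def _stage_segment(cfg: PipelineConfig, state: RunState, out: Path) -> dict:
    outputs, counts = [], {}
    for sid, stack in state.stacks.items():
        table = segment_slide(stack, state.schema)
        state.events[sid] = table
        outputs.append(_write(table, out / "segment" / f"{sid}_events.tsv"))
        counts[sid] = len(table)
        log.info("slide %s: %d nucleated events", sid, len(table))
    return {"outputs": outputs, "counts": counts,
            "params": {"n_features": len(state.schema)}}


def _stage_ocular(cfg: PipelineConfig, state: RunState, out: Path) -> dict:
    params = OcularParams(cfg.cluster_size_max, cfg.distance_quantile,
                          cfg.cut_height_quantile)
    outputs, counts = [], {}
    for sid, table in state.events.items():
        aug, model = run_ocular(table, k=cfg.n_components, params=params,
                                feature_columns=list(state.schema.names))
        aug["event_index"] = aug.index
        state.candidates[sid] = aug
        from .features import META_COLUMNS

        outputs.append(_write(
            aug[["event_index", *META_COLUMNS, "cluster_id", "cluster_size",
                 "distance_to_median", "is_candidate", "reason"]],
            out / "ocular" / f"{sid}_candidates.tsv"))
        counts[sid] = int(aug["is_candidate"].sum())
        log.info("slide %s: %d/%d OCULAR candidates", sid, counts[sid], len(aug))
    return {"outputs": outputs, "counts": counts,
            "params": {"n_components": cfg.n_components,
                       "cluster_size_max": cfg.cluster_size_max,
                       "distance_quantile": cfg.distance_quantile}}


def _training_labels(cfg: PipelineConfig, state: RunState) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label the training slide's events from its ground truth.

    Positives: detected events matched to planted rare cells. Negatives:
    non-rare OCULAR candidates (artifacts, swept-up common cells) plus a
    seeded background sample of ordinary events, mirroring analyst-rejected
    candidates.
    """
    sid = TRAIN_SLIDE
    aug = state.candidates[sid]
    truth_df = truth_to_table(state.truths[sid])
    match = match_truth_to_events(truth_df, aug)
    matched = truth_df.assign(event_index=match.to_numpy())
    matched = matched[matched["event_index"] >= 0]

    rare_idx = matched.loc[matched["true_class"].isin(CELL_TYPES), "event_index"]
    pos = set(rare_idx)
    cand_idx = set(aug.index[aug["is_candidate"]])
    neg = cand_idx - pos
    rng = np.random.default_rng(_sub_seed(cfg.seed, 101))
    background = [i for i in aug.index if i not in pos and i not in neg]
    n_extra = min(cfg.n_background_negatives, len(background))
    if n_extra:
        neg |= set(rng.choice(background, size=n_extra, replace=False))

    idx = sorted(pos | neg)
    train_table = aug.loc[idx]
    labels = pd.Series([i in pos for i in idx], index=idx, name="interesting")

    # channel positivity of matched *cells* (artifacts are not cells)
    cells = matched[matched["true_class"].isin(CELL_TYPES) |
                    (matched["true_class"] == "common")]
    chan = cells.set_index("event_index")[["ck_positive", "v_positive", "cd_positive"]]
    chan.columns = ["CK", "V", "CD"]
    chan = chan[~chan.index.duplicated()]
    chan_table = aug.loc[chan.index]
    return (train_table.assign(interesting=labels),
            chan_table.join(chan))


def _stage_train(cfg: PipelineConfig, state: RunState, out: Path) -> dict:
    train_table, chan_table = _training_labels(cfg, state)
    cv = clf.CVConfig(k=cfg.cv_k, iterations=cfg.cv_iterations)
    seed = _sub_seed(cfg.seed, 202)
    state.interesting_model = clf.train_interesting(
        train_table, train_table["interesting"].to_numpy(), state.schema,
        cv=cv, seed=seed)
    state.channel_trio = clf.train_channel_models(
        chan_table, chan_table[["CK", "V", "CD"]], state.schema, seed=seed)
    report = state.interesting_model.cv_report
    outputs = [_write(report, out / "train" / "cv_report.tsv")]
    with open(out / "train" / "training_manifest.json", "w") as fh:
        json.dump({"best_params": state.interesting_model.best_params,
                   "schema_hash": state.schema.hash,
                   "n_train_events": len(train_table),
                   "n_positive": int(train_table["interesting"].sum()),
                   "seed": seed}, fh, indent=1)
    outputs.append(str(out / "train" / "training_manifest.json"))
    return {"outputs": outputs, "seed": seed,
            "counts": {"train_events": len(train_table),
                       "positives": int(train_table["interesting"].sum())}}


def _stage_classify(cfg: PipelineConfig, state: RunState, out: Path) -> dict:
    outputs, counts = [], {}
    for sid, aug in state.candidates.items():
        if sid == TRAIN_SLIDE:
            continue
        cand = aug[aug["is_candidate"]].copy()
        if cand.empty:
            state.typed[sid] = cand.assign(
                confidence=pd.Series(dtype=float),
                cell_type=pd.Series(dtype=object),
                interesting=pd.Series(dtype=bool))
            counts[sid] = 0
            continue
        conf = clf.score_confidence(state.interesting_model, cand, state.schema)
        calls = clf.predict_channels(state.channel_trio, cand, state.schema)
        typed = cand.join(calls).assign(confidence=conf)
        typed["interesting"] = typed["confidence"] >= cfg.confidence_threshold
        state.typed[sid] = typed
        keep = ["event_index", "slide_id", "frame_row", "frame_col",
                "centroid_row", "centroid_col", "cluster_size",
                "distance_to_median", "reason", "confidence", "interesting",
                "CK_prob", "V_prob", "CD_prob", "CK_positive", "V_positive",
                "CD_positive", "cell_type"]
        outputs.append(_write(typed[keep], out / "classify" / f"{sid}_typed.tsv"))
        counts[sid] = int(typed["interesting"].sum())

    # threshold sweep and spike recovery on the evaluation slide, against truth
    sid = SPIKE_SLIDE
    if sid in state.typed:
        truth_df = truth_to_table(state.truths[sid])
        typed = state.typed[sid]
        events = state.events[sid]
        match = match_truth_to_events(truth_df, events)
        rare_events = set(
            match[truth_df["true_class"].isin(CELL_TYPES).to_numpy()]
            .loc[lambda s: s >= 0]
        )
        y = typed["event_index"].isin(rare_events).to_numpy()
        if y.any() and (~y).any():
            state.sweep = clf.sweep_thresholds(
                typed["confidence"].to_numpy(), y,
                typed["slide_id"].to_numpy())
            outputs.append(_write(state.sweep, out / "classify" / "threshold_sweep.tsv"))
        state.spike_recovery = evaluate_spike_recovery(
            truth_df, typed, events, cfg.confidence_threshold)
        log.info("spike recovery on %s: %s", sid, state.spike_recovery)
    return {"outputs": outputs, "counts": counts,
            "spike_recovery": state.spike_recovery}


def _stage_enumerate(cfg: PipelineConfig, state: RunState, out: Path) -> dict:
    outputs = []
    rows = []
    for sid, typed in state.typed.items():
        interesting = typed[typed["interesting"]]
        census = census_from_typed_events(
            interesting, sid, total_nucleated_events=len(state.events[sid]),
            nominal_volume_ml=cfg.nominal_volume_ml)
        state.censuses[sid] = census
        rows.append((sid, state.cohorts[sid], normalize_counts(census)))
    state.cohort_counts = cohort_table(rows)
    outputs.append(_write(state.cohort_counts, out / "enumerate" / "cohort_counts.tsv"))
    return {"outputs": outputs,
            "counts": {sid: sum(c.counts.values())
                       for sid, c in state.censuses.items()}}


def _stage_compare(cfg: PipelineConfig, state: RunState, out: Path) -> dict:
    outputs = []
    mwu = compare_cohorts(state.cohort_counts, alpha=cfg.alpha)
    outputs.append(_write(mwu, out / "compare" / "mwu.tsv"))
    box = out / "compare" / "cohort_boxplot.png"
    plot_cohort_counts(state.cohort_counts, str(box))
    outputs.append(str(box))

    pooled = []
    for sid, typed in state.typed.items():
        t = typed[typed["interesting"]].copy()
        t["cohort"] = state.cohorts[sid]
        pooled.append(t)
    if pooled:
        allint = pd.concat(pooled, ignore_index=True)
        if len(allint) >= 10:
            emb = umap_embed(allint, seed=_sub_seed(cfg.seed, 303))
            outputs.append(_write(emb, out / "compare" / "umap.tsv"))
            for cohort in allint["cohort"].unique():
                sub = emb[emb["cohort"] == cohort]
                if len(sub) >= 2:
                    p = out / "compare" / f"umap_{cohort}.png"
                    plot_embedding(sub, str(p), title=str(cohort))
                    outputs.append(str(p))
    return {"outputs": outputs,
            "counts": {"significant": int(mwu["significant"].sum())}}
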