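"""Two-stage supervised classification of candidate events.

Stage 1 filters candidates into *interesting* (biologically relevant rare
events) versus *not interesting* (technical artifacts such as bubbles and
fluorescent flares, plus ordinary cells swept up by outlier detection). The
model is a histogram gradient-boosted tree ensemble selected by randomized
search over a hyperparameter grid and over morphometric feature-group subsets,
scored by k-fold cross-validated balanced accuracy. Per-event prediction
confidences serve as adjustable cutpoints trading sensitivity against
precision/specificity.

Stage 2 assigns marker positivity with a trio of independent random-forest
models, one per channel (CK, V, CD), and maps the three calls onto the 8
channel phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import ParameterSampler, StratifiedKFold

from .features import FeatureSchema
from .phenotypes import MARKERS, assign_cell_type  # noqa: F401  (re-exported API)

DEFAULT_THRESHOLDS = (0.50, 0.60, 0.70, 0.80, 0.90)

#: Feature-group subsets searched for the interesting model.
FEATURE_GROUP_SUBSETS: dict[str, tuple[str, ...]] = {
    "shape_only": ("shape",),
    "intensity_only": ("intensity_", "pair_"),
    "all": ("shape", "intensity_", "pair_"),
    "all_plus_neighbor": ("shape", "intensity_", "pair_", "neighbor"),
}

DEFAULT_GRID: dict[str, list] = {
    "max_iter": [50, 100, 200],
    "learning_rate": [0.05, 0.1, 0.3],
    "max_leaf_nodes": [15, 31],
    "l2_regularization": [0.0, 1.0],
    "feature_subset": list(FEATURE_GROUP_SUBSETS),
}


@dataclass
class CVConfig:
    """Model-selection settings: k folds, number of sampled candidates, grid."""

    k: int = 5
    iterations: int = 50
    grid: dict[str, list] = field(default_factory=lambda: dict(DEFAULT_GRID))


class SchemaMismatchError(ValueError):
    """Feature table does not match the schema the model was trained on."""


@dataclass
class InterestingModel:
    """Fitted interesting/not-interesting classifier with its training report."""

    estimator: HistGradientBoostingClassifier
    feature_names: list[str]
    schema_hash: str
    best_params: dict
    cv_report: pd.DataFrame
    seed: int

    def check_schema(self, schema_hash: str) -> None:
        if schema_hash != self.schema_hash:
            raise SchemaMismatchError(
                f"event table schema hash {schema_hash} differs from the "
                f"training schema {self.schema_hash}"
            )


def _subset_columns(schema: FeatureSchema, subset: str) -> list[str]:
    return schema.select(FEATURE_GROUP_SUBSETS[subset])


def train_interesting(
    table: pd.DataFrame,
    labels: np.ndarray,
    schema: FeatureSchema,
    cv: CVConfig | None = None,
    seed: int = 0,
) -> InterestingModel:
    """Select and fit the best interesting-event classifier.

    ``labels`` is boolean (True = interesting). ``cv.iterations`` candidate
    configurations are sampled from the grid (hyperparameters x feature-group
    subsets) and scored by mean k-fold cross-validated balanced accuracy; ties
    break toward the smaller ensemble (fewer boosting iterations). Deterministic
    for a fixed seed. Raises on single-class input.
    """
    cv = cv or CVConfig()
    y = np.asarray(labels, dtype=bool)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if len(y) != len(table):
        raise ValueError("labels and table length mismatch")

    sampler = ParameterSampler(cv.grid, n_iter=cv.iterations, random_state=seed)
    n_min = int(min(np.sum(y), np.sum(~y)))
    k = max(2, min(cv.k, n_min))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)

    rows = []
    for params in sampler:
        params = dict(params)
        subset = params.pop("feature_subset")
        cols = _subset_columns(schema, subset)
        x = table[cols].to_numpy(dtype=np.float64)
        scores = []
        for tr, te in skf.split(x, y):
            est = HistGradientBoostingClassifier(random_state=seed, **params)
            est.fit(x[tr], y[tr])
            scores.append(balanced_accuracy_score(y[te], est.predict(x[te])))
        rows.append({**params, "feature_subset": subset,
                     "mean_balanced_accuracy": float(np.mean(scores))})
    report = pd.DataFrame(rows)
    # best score; ties break toward the smaller ensemble, then sample order
    order = report.sort_values(
        ["mean_balanced_accuracy", "max_iter"], ascending=[False, True],
        kind="stable",
    )
    best = order.iloc[0].to_dict()
    score = best.pop("mean_balanced_accuracy")
    subset = best.pop("feature_subset")
    best = {k_: (int(v) if k_ in ("max_iter", "max_leaf_nodes") else v)
            for k_, v in best.items()}
    cols = _subset_columns(schema, subset)
    est = HistGradientBoostingClassifier(random_state=seed, **best)
    est.fit(table[cols].to_numpy(dtype=np.float64), y)
    return InterestingModel(
        estimator=est,
        feature_names=cols,
        schema_hash=schema.hash,
        best_params={**best, "feature_subset": subset,
                     "cv_balanced_accuracy": score, "k_folds": k,
                     "iterations": cv.iterations},
        cv_report=report,
        seed=seed,
    )


def score_confidence(
    model: InterestingModel, table: pd.DataFrame, schema: FeatureSchema
) -> np.ndarray:
    """Interesting-class confidence in [0, 1], one per event."""
    model.check_schema(schema.hash)
    x = table[model.feature_names].to_numpy(dtype=np.float64)
    return model.estimator.predict_proba(x)[:, 1]


def sweep_thresholds(
    confidences: np.ndarray,
    labels: np.ndarray,
    slide_ids: np.ndarray | None = None,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Confusion metrics at each confidence cutpoint.

    Prediction is positive when confidence >= threshold (closed lower bound).
    Rates are percentages; false negatives ("rare events missed") and false
    positives ("common predicted rare") are averaged per slide.
    """
    conf = np.asarray(confidences, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if conf.size == 0:
        raise ValueError("empty input")
    if conf.shape != y.shape:
        raise ValueError("confidences and labels must have equal length")
    if any(not 0 < t < 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1)")
    if slide_ids is None:
        slide_ids = np.zeros(conf.size, dtype=int)
    slide_ids = np.asarray(slide_ids)
    n_slides = len(np.unique(slide_ids))

    rows = []
    for t in thresholds:
        pred = conf >= t
        tp = int(np.sum(pred & y))
        fp = int(np.sum(pred & ~y))
        fn = int(np.sum(~pred & y))
        tn = int(np.sum(~pred & ~y))
        rows.append(
            {
                "threshold": t,
                "tp": tp, "fp": fp, "fn": fn, "tn": tn,
                "accuracy_pct": 100.0 * (tp + tn) / conf.size,
                "precision_pct": 100.0 * tp / (tp + fp) if tp + fp else 0.0,
                "sensitivity_pct": 100.0 * tp / (tp + fn) if tp + fn else 0.0,
                "specificity_pct": 100.0 * tn / (tn + fp) if tn + fp else 0.0,
                "avg_false_negatives_per_slide": fn / n_slides,
                "avg_false_positives_per_slide": fp / n_slides,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ChannelModelTrio:
    """Three independent per-channel positivity models (CK, V, CD)."""

    models: dict[str, RandomForestClassifier]
    feature_names: dict[str, list[str]]
    schema_hash: str
    seed: int


def train_channel_models(
    table: pd.DataFrame,
    positivity: pd.DataFrame,
    schema: FeatureSchema,
    seed: int = 0,
    n_estimators: int = 200,
) -> ChannelModelTrio:
    """Fit one random forest per marker channel.

    ``positivity`` has boolean columns CK, V, CD. Each channel model consumes
    only the intensity and pair features involving its own channel. Raises,
    naming the channel, when a channel lacks one of the two classes.
    """
    models: dict[str, RandomForestClassifier] = {}
    feature_names: dict[str, list[str]] = {}
    for ch in MARKERS:
        y = positivity[ch].to_numpy(dtype=bool)
        if len(np.unique(y)) < 2:
            raise ValueError(f"channel {ch} has a single class in training data")
        cols = schema.channel_subset(ch)
        rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        rf.fit(table[cols].to_numpy(dtype=np.float64), y)
        models[ch] = rf
        feature_names[ch] = cols
    return ChannelModelTrio(models, feature_names, schema.hash, seed)


def predict_channels(
    trio: ChannelModelTrio, table: pd.DataFrame, schema: FeatureSchema
) -> pd.DataFrame:
    """Per-event marker calls with probabilities, plus the phenotype label."""
    if schema.hash != trio.schema_hash:
        raise SchemaMismatchError("schema hash differs from channel-model training")
    out = {}
    for ch in MARKERS:
        x = table[trio.feature_names[ch]].to_numpy(dtype=np.float64)
        proba = trio.models[ch].predict_proba(x)[:, 1]
        out[f"{ch}_prob"] = proba
        out[f"{ch}_positive"] = proba >= 0.5
    res = pd.DataFrame(out, index=table.index)
    res["cell_type"] = [
        assign_cell_type(ck, v, cd)
        for ck, v, cd in zip(res["CK_positive"], res["V_positive"], res["CD_positive"])
    ]
    return res
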