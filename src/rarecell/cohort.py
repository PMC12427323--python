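"""Cohort-level comparison of normalized phenotype counts.

Samples are compared pairwise across cohorts (e.g. normal donors, early-stage,
late-stage) with two-sided Mann-Whitney U tests per phenotype at alpha = 0.05
(no multiple-testing correction by default, Benjamini-Hochberg optional), and
the morphometrics of the interesting rare events are visualized with a UMAP
embedding built from cellular and nuclear area plus the four per-channel mean
intensities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phenotypes import CELL_TYPES

#: Default morphometric subset for the rare-event embedding.
DEFAULT_UMAP_FEATURES = (
    "shape_cellular_area",
    "shape_nuclear_area",
    "int_D_cellular_mean",
    "int_CK_cellular_mean",
    "int_V_cellular_mean",
    "int_CD_cellular_mean",
)


def mwu_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie correction.

    Exact null distribution when both groups are small (n <= 20) and untied;
    tie-corrected normal approximation otherwise. Returns (U of the first
    group, p-value); p is clipped into (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and max(len(x), len(y)) <= 20:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class MWUResult:
    cohort_a: str
    cohort_b: str
    phenotype: str
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    significant: bool


def compare_cohorts(
    table: pd.DataFrame,
    alpha: float = 0.05,
    bh_correction: bool = False,
    phenotypes: tuple[str, ...] = CELL_TYPES,
) -> pd.DataFrame:
    """Pairwise Mann-Whitney U across cohorts for each phenotype.

    ``table`` is a cohort table (``cohort`` column plus the 8 phenotype
    cells/mL columns). Every cohort pair x phenotype yields one row. Raises if
    any compared cohort has fewer than 2 samples.
    """
    cohorts = list(dict.fromkeys(table["cohort"]))
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts")
    for c in cohorts:
        if (table["cohort"] == c).sum() < 2:
            raise ValueError(f"cohort {c!r} has fewer than 2 samples")

    rows = []
    for a, b in itertools.combinations(cohorts, 2):
        xa = table[table["cohort"] == a]
        xb = table[table["cohort"] == b]
        for ptype in phenotypes:
            u, p = mwu_test(xa[ptype].to_numpy(), xb[ptype].to_numpy())
            rows.append(MWUResult(a, b, ptype, u, p, len(xa), len(xb), p < alpha))
    out = pd.DataFrame([r.__dict__ for r in rows])
    if bh_correction:
        from statsmodels.stats.multitest import multipletests  # lazy: optional path

        rej, padj, _, _ = multipletests(out["p_value"], alpha=alpha, method="fdr_bh")
        out["p_adjusted"] = padj
        out["significant"] = rej
    return out


def umap_embed(
    table: pd.DataFrame,
    feature_subset: tuple[str, ...] = DEFAULT_UMAP_FEATURES,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """2-D UMAP embedding of interesting events from a morphometric subset.

    Deterministic for a fixed seed (single-threaded exact mode). Raises,
    naming the column, if a subset feature is missing from the table.
    """
    import umap  # deferred: numba JIT import is slow

    missing = [c for c in feature_subset if c not in table.columns]
    if missing:
        raise KeyError(f"feature subset column(s) missing from table: {missing}")
    if len(table) < 10:
        raise ValueError("need at least 10 events for an embedding")
    x = table[list(feature_subset)].to_numpy(dtype=np.float64)
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    reducer = umap.UMAP(
        n_neighbors=min(n_neighbors, len(table) - 1),
        min_dist=min_dist,
        metric="euclidean",
        random_state=seed,
        n_jobs=1,
        force_approximation_algorithm=False,
    )
    coords = reducer.fit_transform(x)
    out = pd.DataFrame(coords, columns=["umap1", "umap2"], index=table.index)
    if "cell_type" in table.columns:
        out["cell_type"] = table["cell_type"]
    if "cohort" in table.columns:
        out["cohort"] = table["cohort"]
    return out


def plot_embedding(embedding: pd.DataFrame, path: str, title: str = "") -> None:
    """Scatter the embedding colored by phenotype; one static image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    groups = embedding.groupby("cell_type") if "cell_type" in embedding else [
        ("events", embedding)
    ]
    for name, grp in groups:
        ax.scatter(grp["umap1"], grp["umap2"], s=8, label=str(name), alpha=0.8)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend(fontsize=7, markerscale=1.5)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cohort_counts(table: pd.DataFrame, path: str) -> None:
    """Box plots of log-transformed cells/mL per phenotype and cohort.

    Zeros are kept visible via log(count + eps) with eps = smallest nonzero
    count / 10.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = table[list(CELL_TYPES)].to_numpy()
    nonzero = vals[vals > 0]
    eps = nonzero.min() / 10.0 if nonzero.size else 1e-3
    cohorts = list(dict.fromkeys(table["cohort"]))
    fig, axes = plt.subplots(2, 4, figsize=(14, 6), sharey=True)
    for ax, ptype in zip(axes.ravel(), CELL_TYPES):
        data = [np.log(table.loc[table["cohort"] == c, ptype] + eps) for c in cohorts]
        ax.boxplot(data, tick_labels=cohorts)
        ax.set_title(ptype, fontsize=9)
    axes[0, 0].set_ylabel("log(cells/mL + eps)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
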