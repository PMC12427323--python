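"""Outlier-clustering candidate detection (OCULAR-style).

The event table is z-scored and reduced by PCA (761 features to 350 components
by default). Candidate rare events are then flagged in the reduced space on two
grounds, and their union taken:

* membership in a *small* hierarchical cluster (Ward linkage, tree cut at a
  height quantile), and
* *large distance* from the median cell — the component-wise median of the PC
  coordinates, a synthetic reference point, with Euclidean distance above a
  high quantile of the per-event distances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)

DEFAULT_N_COMPONENTS = 350


@dataclass
class PCModel:
    """Fitted standardize-then-PCA reduction."""

    feature_names: list[str]      # columns used (zero-variance columns dropped)
    center: np.ndarray
    scale: np.ndarray
    components: np.ndarray        # (K, F_used), orthonormal rows
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components: int
    requested_components: int

    @property
    def capped(self) -> bool:
        return self.n_components < self.requested_components

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.feature_names].to_numpy(dtype=np.float64)
        z = (x - self.center) / self.scale
        return z @ self.components.T


def fit_reduce(
    feature_table: pd.DataFrame,
    k: int = DEFAULT_N_COMPONENTS,
    feature_columns: list[str] | None = None,
) -> tuple[PCModel, np.ndarray]:
    """Standardize the features and project onto the top-``k`` principal components.

    Zero-variance features are dropped with a warning before scaling. If ``k``
    exceeds the admissible rank (min(F, n_events - 1)), the component count is
    capped and the cap reported on the returned model.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if feature_columns is None:
        feature_columns = [c for c in feature_table.columns
                           if feature_table[c].dtype.kind == "f"]
    x = feature_table[feature_columns].to_numpy(dtype=np.float64)
    n, f = x.shape
    if n < 2:
        raise ValueError("need at least 2 events for PCA")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature table contains non-finite values")

    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k_ in zip(feature_columns, keep) if not k_]
        log.warning("dropping %d zero-variance features (e.g. %s)",
                    len(dropped), dropped[:3])
        warnings.warn(f"{len(dropped)} zero-variance features dropped before PCA",
                      stacklevel=2)
    used = [c for c, k_ in zip(feature_columns, keep) if k_]
    x = x[:, keep]
    center = x.mean(axis=0)
    scale = x.std(axis=0)
    z = (x - center) / scale

    k_eff = min(k, len(used), n - 1)
    if k_eff < k:
        log.info("capping components at %d (requested %d)", k_eff, k)
    pca = PCA(n_components=k_eff, svd_solver="full")
    coords = pca.fit_transform(z)
    model = PCModel(
        feature_names=used,
        center=center,
        scale=scale,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_components=k_eff,
        requested_components=k,
    )
    return model, coords


@dataclass
class OcularParams:
    """Candidate-detection parameters.

    ``distance_calibration`` chooses how the large-distance cutoff at
    ``distance_quantile`` is located: ``"bulk-robust"`` (default) models the
    typical-cell distance distribution as a chi distribution with Satterthwaite
    effective degrees of freedom from robust (MAD-based) per-component scales,
    anchored at the median distance — so spiked outliers cannot mask
    themselves by inflating the empirical quantile; ``"empirical"`` thresholds
    at the plain empirical quantile of the observed distances.
    """

    cluster_size_max: int = 10
    distance_quantile: float = 0.999
    cut_height_quantile: float = 0.99
    distance_calibration: str = "bulk-robust"


def _bulk_distance_threshold(coords: np.ndarray, dist: np.ndarray, q: float) -> float:
    """Distance cutoff at bulk quantile ``q``, robust to contamination.

    For a Gaussian bulk, the distance from the median is a weighted chi
    variable; with robust per-component scales s_i, its quantiles follow a chi
    distribution with n_eff = (sum s_i^2)^2 / sum s_i^4 degrees of freedom up
    to a common scale. Anchoring at the observed median distance gives
    thr = median(dist) * chi_ppf(q, n_eff) / chi_ppf(0.5, n_eff), which
    recovers the plain quantile on clean data but is insensitive to a small
    fraction of extreme outliers.
    """
    from scipy.stats import chi as chi_dist

    med = np.median(coords, axis=0)
    s2 = (1.4826 * np.median(np.abs(coords - med), axis=0)) ** 2
    tot, tot2 = float(s2.sum()), float((s2**2).sum())
    n_eff = max(1.0, tot**2 / tot2) if tot2 > 0 else 1.0
    ratio = chi_dist.ppf(q, n_eff) / chi_dist.ppf(0.5, n_eff)
    return float(np.median(dist) * ratio)


def detect_candidates(
    coords: np.ndarray,
    params: OcularParams = OcularParams(),
) -> pd.DataFrame:
    """Flag candidate rare events in PC space.

    Returns a frame with columns ``cluster_id``, ``cluster_size``,
    ``distance_to_median``, ``is_candidate`` and ``reason`` (one of
    small_cluster / large_distance / both / none). Ward linkage is cut at the
    ``cut_height_quantile`` of merge heights; clusters of size <=
    ``cluster_size_max`` are small-cluster candidates; events whose Euclidean
    distance from the component-wise median exceeds the ``distance_quantile``
    of all such distances are large-distance candidates.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 events")

    degenerate = bool(np.allclose(coords, coords[0]))
    if degenerate:
        cluster_id = np.ones(n, dtype=int)
    else:
        zlink = linkage(coords, method="ward")
        heights = zlink[:, 2]
        cut = float(np.quantile(heights, params.cut_height_quantile))
        cluster_id = fcluster(zlink, t=cut, criterion="distance")

    sizes = pd.Series(cluster_id).map(pd.Series(cluster_id).value_counts())
    median_cell = np.median(coords, axis=0)
    dist = np.linalg.norm(coords - median_cell, axis=1)
    if np.ptp(dist) == 0:
        large = np.zeros(n, dtype=bool)
    else:
        if params.distance_calibration == "bulk-robust":
            thr = _bulk_distance_threshold(coords, dist, params.distance_quantile)
        elif params.distance_calibration == "empirical":
            thr = float(np.quantile(dist, params.distance_quantile))
        else:
            raise ValueError(
                f"unknown distance_calibration {params.distance_calibration!r}"
            )
        large = dist > thr
    small = (sizes.to_numpy() <= params.cluster_size_max) & (not degenerate)

    reason = np.where(
        small & large, "both",
        np.where(small, "small_cluster", np.where(large, "large_distance", "none")),
    )
    return pd.DataFrame(
        {
            "cluster_id": cluster_id,
            "cluster_size": sizes.to_numpy(),
            "distance_to_median": dist,
            "is_candidate": reason != "none",
            "reason": reason,
        }
    )


def run_ocular(
    feature_table: pd.DataFrame,
    k: int = DEFAULT_N_COMPONENTS,
    params: OcularParams = OcularParams(),
    feature_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, PCModel]:
    """Reduce + detect; returns the event table augmented with OCULAR columns."""
    model, coords = fit_reduce(feature_table, k=k, feature_columns=feature_columns)
    res = detect_candidates(coords, params)
    out = feature_table.reset_index(drop=True).join(res)
    return out, model
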