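"""Morphometric feature schema and per-event feature extraction.

Each DAPI+ event yields a fixed-length, deterministically ordered feature vector
covering four families:

* **shape** — geometry of the nuclear mask (area, perimeter, eccentricity, axis
  lengths, boundary-radius statistics, solidity, Hu moments, ...) plus a few
  cellular-compartment shape terms;
* **intensity** — per channel (D, CK, V, CD) and per compartment (nuclear =
  the DAPI mask; cellular = the mask dilated by 3 px, since cytoplasmic markers
  extend beyond the nucleus): basic statistics, a dense quantile profile,
  gradient texture and a radial intensity profile;
* **pair** — co-expression statistics for every unordered channel pair
  (correlation, overlap, intensity ratios) in both compartments;
* **neighbor** — local context from the other events on the same frame.

With the default parameters the schema has exactly 761 features. The schema is a
pure function of its parameters: two calls with equal parameters produce the
identical ordered name list.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from scipy.stats import rankdata
from skimage.measure import regionprops
from skimage.morphology import dilation, disk, erosion

from .frames import CHANNELS, FrameStack
from .segment import EventMask

DEFAULT_FEATURE_COUNT = 761

_BASIC_STATS = (
    "mean", "sd", "mad", "min", "max", "total", "energy", "entropy",
    "skewness", "kurtosis", "mass_displacement", "center_shift", "uniformity",
)
_TEXTURE_STATS = ("grad_mean", "grad_sd", "grad_max", "laplace_sd")
_PAIR_STATS = (
    "corr_pearson", "corr_spearman", "covariance", "cosine", "mean_ratio",
    "mean_diff", "total_log_ratio", "jaccard_over_median", "manders_ab",
    "manders_ba", "product_mean", "sum_sd", "diff_sd",
)
_SHAPE_NUCLEAR = (
    "area", "perimeter", "eccentricity", "major_axis", "minor_axis",
    "aspect_ratio", "orientation", "solidity", "extent", "equivalent_diameter",
    "convex_area", "form_factor", "mean_radius", "radius_sd", "radius_min",
    "radius_max", "feret_diameter", "euler_number",
    "hu1", "hu2", "hu3", "hu4", "hu5", "hu6", "hu7",
)
_SHAPE_CELLULAR = (
    "area", "perimeter", "eccentricity", "solidity", "equivalent_diameter",
    "form_factor", "nuclear_area_ratio",
)
_NEIGHBOR = (
    "dist_nearest", "dist_knn3_mean", "n_within_50px", "n_within_100px",
    "frame_event_count",
)
_COMPARTMENTS = ("nuclear", "cellular")


@dataclass(frozen=True)
class SchemaParams:
    """Parameters the feature schema is generated from."""

    channels: tuple[str, ...] = CHANNELS
    n_quantiles: int = 48          # quantile grid 0.02, 0.04, ..., 0.96
    n_radial_rings: int = 6
    cellular_dilation_px: int = 3
    include_pairs: bool = True
    include_neighbors: bool = True
    expected_length: int | None = DEFAULT_FEATURE_COUNT

    @property
    def quantiles(self) -> np.ndarray:
        return np.round(np.arange(1, self.n_quantiles + 1) * 0.02, 2)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names with group tags; the contract for every event table."""

    names: tuple[str, ...]
    groups: tuple[str, ...]  # parallel to names: shape | intensity_<ch> | pair_<a>_<b> | neighbor
    params: SchemaParams

    def __len__(self) -> int:
        return len(self.names)

    @property
    def hash(self) -> str:
        return hashlib.sha256("\n".join(self.names).encode()).hexdigest()[:16]

    def select(self, group_prefixes: tuple[str, ...]) -> list[str]:
        """Feature names whose group tag starts with any given prefix."""
        return [n for n, g in zip(self.names, self.groups)
                if any(g.startswith(p) for p in group_prefixes)]

    def channel_subset(self, channel: str) -> list[str]:
        """Intensity + pair features involving one channel (for channel models)."""
        out = []
        for n, g in zip(self.names, self.groups):
            if g == f"intensity_{channel}":
                out.append(n)
            elif g.startswith("pair_") and channel in g.split("_")[1:]:
                out.append(n)
        return out


def build_feature_schema(params: SchemaParams = SchemaParams()) -> FeatureSchema:
    """Construct the deterministic ordered feature schema.

    Default parameters yield exactly 761 features:
    4 channels x 2 compartments x (13 basic + 48 quantiles + 4 texture +
    6 radial) = 568, 6 pairs x 2 compartments x 13 = 156, 32 shape,
    5 neighbor-context. Raises if the realized length differs from
    ``params.expected_length``.
    """
    names: list[str] = []
    groups: list[str] = []

    for s in _SHAPE_NUCLEAR:
        names.append(f"shape_nuclear_{s}")
        groups.append("shape")
    for s in _SHAPE_CELLULAR:
        names.append(f"shape_cellular_{s}")
        groups.append("shape")

    qlabels = [f"q{int(round(q * 100)):02d}" for q in params.quantiles]
    rings = [f"ring{i}" for i in range(params.n_radial_rings)]
    for ch in params.channels:
        for comp in _COMPARTMENTS:
            for s in itertools.chain(_BASIC_STATS, qlabels, _TEXTURE_STATS, rings):
                names.append(f"int_{ch}_{comp}_{s}")
                groups.append(f"intensity_{ch}")

    if params.include_pairs:
        for a, b in itertools.combinations(params.channels, 2):
            for comp in _COMPARTMENTS:
                for s in _PAIR_STATS:
                    names.append(f"pair_{a}_{b}_{comp}_{s}")
                    groups.append(f"pair_{a}_{b}")

    if params.include_neighbors:
        for s in _NEIGHBOR:
            names.append(f"nbr_{s}")
            groups.append("neighbor")

    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in schema")
    if params.expected_length is not None and len(names) != params.expected_length:
        raise ValueError(
            f"schema parameters produce {len(names)} features, "
            f"expected {params.expected_length}"
        )
    return FeatureSchema(tuple(names), tuple(groups), params)


@dataclass
class EventRecord:
    """One segmented event with its metadata and schema-aligned feature vector."""

    slide_id: str
    frame_pos: int
    frame_row: int
    frame_col: int
    label_id: int
    centroid: tuple[float, float]
    nuclear_area: int
    cellular_area: int
    features: np.ndarray  # length len(schema), finite


META_COLUMNS = (
    "slide_id", "frame_pos", "frame_row", "frame_col", "label_id",
    "centroid_row", "centroid_col", "nuclear_area", "cellular_area",
)


def records_to_table(records: list[EventRecord], schema: FeatureSchema) -> pd.DataFrame:
    """Event table: metadata columns followed by the schema-ordered features."""
    meta = pd.DataFrame(
        [
            (r.slide_id, r.frame_pos, r.frame_row, r.frame_col, r.label_id,
             r.centroid[0], r.centroid[1], r.nuclear_area, r.cellular_area)
            for r in records
        ],
        columns=list(META_COLUMNS),
    )
    feats = pd.DataFrame(
        np.vstack([r.features for r in records]) if records
        else np.empty((0, len(schema))),
        columns=list(schema.names),
    )
    return pd.concat([meta, feats], axis=1)


# ---------------------------------------------------------------------------
# per-event computation


def _finite(x: float) -> float:
    return float(x) if np.isfinite(x) else 0.0


def _basic_stats(vals: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                 centroid: tuple[float, float], equiv_radius: float) -> list[float]:
    mean = vals.mean()
    sd = vals.std()
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    total = vals.sum()
    energy = float(np.mean(vals.astype(np.float64) ** 2))
    # entropy / uniformity over a 32-bin histogram of the compartment
    if vals.max() > vals.min():
        hist, _ = np.histogram(vals, bins=32)
        p = hist / hist.sum()
        p = p[p > 0]
        entropy = float(-(p * np.log2(p)).sum())
        uniformity = float((p**2).sum())
    else:
        entropy, uniformity = 0.0, 1.0
    if sd > 0:
        z = (vals - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
    else:
        skew = kurt = 0.0
    if total > 0:
        wr = float((rows * vals).sum() / total)
        wc = float((cols * vals).sum() / total)
        mass_disp = float(np.hypot(wr - centroid[0], wc - centroid[1]))
    else:
        mass_disp = 0.0
    center_shift = mass_disp / equiv_radius if equiv_radius > 0 else 0.0
    return [
        _finite(mean), _finite(sd), _finite(mad), _finite(vals.min()),
        _finite(vals.max()), _finite(total), _finite(energy), entropy,
        skew, kurt, mass_disp, center_shift, uniformity,
    ]


def _texture_stats(img: np.ndarray, bbox: tuple[int, int, int, int],
                   mask_local: np.ndarray) -> list[float]:
    r0, c0, r1, c1 = bbox
    patch = img[r0:r1, c0:c1]
    if patch.shape[0] < 2 or patch.shape[1] < 2:
        return [0.0, 0.0, 0.0, 0.0]
    gr, gc = np.gradient(patch)
    gmag = np.hypot(gr, gc)[mask_local]
    lap = ndi.laplace(patch)[mask_local]
    return [_finite(gmag.mean()), _finite(gmag.std()), _finite(gmag.max()),
            _finite(lap.std())]


def _radial_profile(vals: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                    centroid: tuple[float, float], n_rings: int) -> list[float]:
    d = np.hypot(rows - centroid[0], cols - centroid[1])
    rmax = d.max()
    if rmax == 0:
        return [float(vals.mean())] + [0.0] * (n_rings - 1)
    idx = np.minimum((d / rmax * n_rings).astype(int), n_rings - 1)
    out = []
    for i in range(n_rings):
        sel = idx == i
        out.append(float(vals[sel].mean()) if sel.any() else 0.0)
    return out


def _pair_stats(a: np.ndarray, b: np.ndarray) -> list[float]:
    af = a.astype(np.float64)
    bf = b.astype(np.float64)
    sa, sb = af.std(), bf.std()
    if sa > 0 and sb > 0:
        pearson = float(np.corrcoef(af, bf)[0, 1])
        ra, rb = rankdata(af), rankdata(bf)
        if ra.std() > 0 and rb.std() > 0:
            spearman = float(np.corrcoef(ra, rb)[0, 1])
        else:
            spearman = 0.0
    else:
        pearson = spearman = 0.0
    cov = float(np.mean((af - af.mean()) * (bf - bf.mean())))
    na, nb = np.linalg.norm(af), np.linalg.norm(bf)
    cosine = float(af @ bf / (na * nb)) if na > 0 and nb > 0 else 0.0
    mean_ratio = float(af.mean() / (bf.mean() + 1e-9))
    mean_diff = float(af.mean() - bf.mean())
    total_log_ratio = float(np.log((af.sum() + 1.0) / (bf.sum() + 1.0)))
    above_a = af > np.median(af)
    above_b = bf > np.median(bf)
    union = np.count_nonzero(above_a | above_b)
    jaccard = float(np.count_nonzero(above_a & above_b) / union) if union else 0.0
    manders_ab = float(af[above_b].sum() / af.sum()) if af.sum() > 0 else 0.0
    manders_ba = float(bf[above_a].sum() / bf.sum()) if bf.sum() > 0 else 0.0
    product_mean = float(np.mean(af * bf))
    sum_sd = float((af + bf).std())
    diff_sd = float((af - bf).std())
    return [_finite(v) for v in (
        pearson, spearman, cov, cosine, mean_ratio, mean_diff, total_log_ratio,
        jaccard, manders_ab, manders_ba, product_mean, sum_sd, diff_sd,
    )]


def _shape_features(mask_local: np.ndarray, offset: tuple[int, int]) -> tuple[list[float], dict]:
    """Nuclear shape family from a boolean patch (geometry only)."""
    lbl = mask_local.astype(np.uint8)
    p = regionprops(lbl)[0]
    area = float(p.area)
    perim = float(p.perimeter) if p.perimeter > 0 else 1.0
    major = float(p.axis_major_length)
    minor = float(p.axis_minor_length)
    aspect = major / minor if minor > 0 else 1.0
    form = 4 * np.pi * area / perim**2
    # boundary radius statistics about the centroid
    boundary = mask_local & ~erosion(mask_local, disk(1))
    br, bc = np.nonzero(boundary if boundary.any() else mask_local)
    cr, cc = p.centroid
    rad = np.hypot(br - cr, bc - cc)
    hu = p.moments_hu
    vals = [
        area, perim, float(p.eccentricity), major, minor, _finite(aspect),
        float(p.orientation), float(p.solidity), float(p.extent),
        float(p.equivalent_diameter_area), float(p.area_convex), _finite(form),
        float(rad.mean()), float(rad.std()), float(rad.min()), float(rad.max()),
        float(p.feret_diameter_max), float(p.euler_number),
        *[_finite(h) for h in hu],
    ]
    info = {"centroid": (cr + offset[0], cc + offset[1]), "area": area}
    return vals, info


def _cellular_shape(mask_local: np.ndarray, nuclear_area: float) -> list[float]:
    p = regionprops(mask_local.astype(np.uint8))[0]
    area = float(p.area)
    perim = float(p.perimeter) if p.perimeter > 0 else 1.0
    form = 4 * np.pi * area / perim**2
    return [
        area, perim, float(p.eccentricity), float(p.solidity),
        float(p.equivalent_diameter_area), _finite(form),
        nuclear_area / area if area > 0 else 0.0,
    ]


def extract_features(
    masks: list[EventMask],
    stack: FrameStack,
    schema: FeatureSchema,
) -> list[EventRecord]:
    """Compute the schema-aligned feature vector for every mask.

    Masks must come from the DAPI channel of ``stack``. Intensity features are
    computed over the nuclear mask and over its ``cellular_dilation_px``
    dilation; neighbor features use every event centroid on the same frame.
    Raises on a mask referencing out-of-bounds pixels. Output vectors contain
    no non-finite values.
    """
    params = schema.params
    h, w = stack.frame_shape
    frame_diag = float(np.hypot(h, w))
    n_rings = params.n_radial_rings
    qs = params.quantiles
    selem = disk(params.cellular_dilation_px)
    pad = params.cellular_dilation_px

    by_frame: dict[int, list[EventMask]] = {}
    for m in masks:
        if m.rows.min() < 0 or m.rows.max() >= h or m.cols.min() < 0 or m.cols.max() >= w:
            raise IndexError(f"mask {m.label_id} on frame {m.frame_pos} is out of bounds")
        by_frame.setdefault(m.frame_pos, []).append(m)

    records: list[EventRecord] = []
    for pos, frame_masks in sorted(by_frame.items()):
        imgs = {ch: stack.frame(pos, ch).astype(np.float64) for ch in params.channels}
        cents = np.array([m.centroid for m in frame_masks])
        tree = cKDTree(cents) if len(cents) > 1 else None
        fr, fc = stack.grid.position_rc(pos)

        for mi, m in enumerate(frame_masks):
            r0 = max(0, m.bbox[0] - pad)
            c0 = max(0, m.bbox[1] - pad)
            r1 = min(h, m.bbox[2] + pad)
            c1 = min(w, m.bbox[3] + pad)
            nuc_local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
            nuc_local[m.rows - r0, m.cols - c0] = True
            cell_local = dilation(nuc_local, selem)

            vec: list[float] = []
            shape_vals, _ = _shape_features(nuc_local, (r0, c0))
            nuclear_area = float(m.rows.size)
            vec.extend(shape_vals)
            vec.extend(_cellular_shape(cell_local, nuclear_area))

            cell_rr, cell_cc = np.nonzero(cell_local)
            comp_coords = {
                "nuclear": (m.rows.astype(np.float64), m.cols.astype(np.float64)),
                "cellular": ((cell_rr + r0).astype(np.float64),
                             (cell_cc + c0).astype(np.float64)),
            }
            comp_local = {"nuclear": nuc_local, "cellular": cell_local}
            equiv_r = {
                comp: float(np.sqrt(len(rr) / np.pi))
                for comp, (rr, _) in comp_coords.items()
            }
            # pixel values per (channel, compartment), reused by pair features
            pix: dict[tuple[str, str], np.ndarray] = {}
            for ch in params.channels:
                img = imgs[ch]
                for comp in _COMPARTMENTS:
                    rr, cc = comp_coords[comp]
                    vals = img[rr.astype(int), cc.astype(int)]
                    pix[(ch, comp)] = vals
                    vec.extend(_basic_stats(vals, rr, cc, m.centroid, equiv_r[comp]))
                    vec.extend(np.quantile(vals, qs).tolist())
                    vec.extend(_texture_stats(img, (r0, c0, r1, c1), comp_local[comp]))
                    vec.extend(_radial_profile(vals, rr, cc, m.centroid, n_rings))

            if params.include_pairs:
                for a, b in itertools.combinations(params.channels, 2):
                    for comp in _COMPARTMENTS:
                        vec.extend(_pair_stats(pix[(a, comp)], pix[(b, comp)]))

            if params.include_neighbors:
                if tree is not None:
                    k = min(4, len(cents))
                    dists, _ = tree.query(m.centroid, k=k)
                    dists = np.atleast_1d(dists)[1:]  # drop self
                    nn = float(dists[0])
                    knn3 = float(dists.mean())
                    n50 = float(len(tree.query_ball_point(m.centroid, 50.0)) - 1)
                    n100 = float(len(tree.query_ball_point(m.centroid, 100.0)) - 1)
                else:
                    nn = knn3 = frame_diag  # no-neighbor sentinel, finite
                    n50 = n100 = 0.0
                vec.extend([nn, knn3, n50, n100, float(len(frame_masks))])

            arr = np.asarray(vec, dtype=np.float64)
            if arr.size != len(schema):
                raise RuntimeError(
                    f"feature vector length {arr.size} != schema length {len(schema)}"
                )
            if not np.all(np.isfinite(arr)):
                bad = [schema.names[i] for i in np.nonzero(~np.isfinite(arr))[0][:5]]
                raise RuntimeError(f"non-finite features {bad} on event {m.label_id}")
            records.append(
                EventRecord(
                    slide_id=stack.slide_id,
                    frame_pos=pos,
                    frame_row=fr,
                    frame_col=fc,
                    label_id=m.label_id,
                    centroid=m.centroid,
                    nuclear_area=int(nuclear_area),
                    cellular_area=int(cell_local.sum()),
                    features=arr,
                )
            )
    return records


def segment_slide(
    stack: FrameStack,
    schema: FeatureSchema,
    seg_params=None,
) -> pd.DataFrame:
    """Mask and featurize every frame of a slide; returns the event table."""
    from .segment import SegmentationParams, mask_events

    if seg_params is None:
        seg_params = SegmentationParams()
    all_masks: list[EventMask] = []
    for pos in range(stack.grid.n_positions):
        all_masks.extend(mask_events(stack.frame(pos, "D"), seg_params, frame_pos=pos))
    records = extract_features(all_masks, stack, schema)
    return records_to_table(records, schema)
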