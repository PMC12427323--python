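import math

import numpy as np
import pytest

import rarecell as rc
from rarecell.features import SchemaParams, build_feature_schema, extract_features
from rarecell.frames import CHANNELS, FrameGrid, FrameStack
from rarecell.segment import EventMask


class TestSchema:
    def test_default_schema_has_761_unique_features(self, schema):
        assert len(schema) == 761
        assert len(set(schema.names)) == 761

    def test_schema_is_deterministic(self):
        a = build_feature_schema(SchemaParams())
        b = build_feature_schema(SchemaParams())
        assert a.names == b.names
        assert a.hash == b.hash

    def test_single_channel_reduced_schema_is_smaller_and_stable(self):
        params = SchemaParams(channels=("D",), expected_length=None)
        s = build_feature_schema(params)
        # shape (32) + one channel x two compartments x 71 + neighbor (5)
        assert len(s) == 32 + 2 * 71 + 5
        assert s.names == build_feature_schema(params).names

    def test_declared_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="expected 761"):
            build_feature_schema(SchemaParams(n_quantiles=10))

    def test_group_tags_cover_the_four_families(self, schema):
        groups = set(schema.groups)
        assert "shape" in groups and "neighbor" in groups
        assert {f"intensity_{ch}" for ch in CHANNELS} <= groups
        assert sum(g.startswith("pair_") for g in groups) == 6

    def test_channel_subset_only_involves_that_channel(self, schema):
        cols = schema.channel_subset("CK")
        assert cols
        for c in cols:
            assert "CK" in c
            assert not c.startswith(("shape_", "nbr_"))


def disk_mask(cr, cc, radius):
    rr, cc_ = np.mgrid[0:256, 0:256]
    return (rr - cr) ** 2 + (cc_ - cc) ** 2 <= radius**2


def stack_from_frames(frames_by_channel):
    grid = FrameGrid(1, 1)
    h, w = next(iter(frames_by_channel.values())).shape
    data = np.zeros((1, 4, h, w), dtype=np.uint16)
    for ch, img in frames_by_channel.items():
        data[0, list(grid.channels).index(ch)] = img
    return FrameStack(grid, data, slide_id="test")


def mask_from_bool(b, frame_pos=0, label_id=1):
    rows, cols = np.nonzero(b)
    from skimage.measure import regionprops

    p = regionprops(b.astype(np.uint8))[0]
    return EventMask(frame_pos, label_id, rows.astype(np.int32),
                     cols.astype(np.int32), tuple(p.bbox),
                     (float(p.centroid[0]), float(p.centroid[1])))


class TestExtraction:
    def test_uniform_disk_mean_intensity_and_eccentricity(self, schema):
        v = 1200
        b = disk_mask(128, 128, 10)
        img = np.where(b, v, 0).astype(np.uint16)
        stack = stack_from_frames({"D": img})
        [rec] = extract_features([mask_from_bool(b)], stack, schema)
        feats = dict(zip(schema.names, rec.features))
        assert feats["int_D_nuclear_mean"] == pytest.approx(v)
        assert feats["shape_nuclear_eccentricity"] < 0.05
        assert feats["shape_nuclear_area"] == b.sum() == rec.nuclear_area

    def test_mask_pixel_count_is_the_nuclear_area_feature(self, schema):
        b = np.zeros((256, 256), dtype=bool)
        b[100:110, 100:110] = True  # 100 pixels
        stack = stack_from_frames({"D": np.full((256, 256), 7, dtype=np.uint16)})
        [rec] = extract_features([mask_from_bool(b)], stack, schema)
        feats = dict(zip(schema.names, rec.features))
        assert feats["shape_nuclear_area"] == 100.0
        assert rec.nuclear_area == 100

    def test_features_match_independent_pixel_recomputation(self, schema):
        """Representative features from each family recomputed from raw pixels
        with an independent brute-force pass."""
        rng = np.random.default_rng(7)
        imgs = {ch: rng.integers(0, 4000, (256, 256)).astype(np.uint16)
                for ch in CHANNELS}
        b = disk_mask(90, 140, 8)
        stack = stack_from_frames(imgs)
        [rec] = extract_features([mask_from_bool(b)], stack, schema)
        feats = dict(zip(schema.names, rec.features))

        rows, cols = np.nonzero(b)
        # brute-force cellular compartment: every pixel within 3 px (Euclidean)
        # of some nuclear pixel
        cell = np.zeros_like(b)
        for r in range(256):
            for c in range(256):
                d2 = (rows - r) ** 2 + (cols - c) ** 2
                if d2.min() <= 9:
                    cell[r, c] = True
        assert cell.sum() == rec.cellular_area

        for ch in CHANNELS:
            nuc_vals = [float(imgs[ch][r, c]) for r, c in zip(rows, cols)]
            assert feats[f"int_{ch}_nuclear_mean"] == pytest.approx(
                sum(nuc_vals) / len(nuc_vals))
            assert feats[f"int_{ch}_nuclear_total"] == pytest.approx(sum(nuc_vals))
            assert feats[f"int_{ch}_nuclear_min"] == min(nuc_vals)
            assert feats[f"int_{ch}_nuclear_max"] == max(nuc_vals)
            assert feats[f"int_{ch}_nuclear_q50"] == pytest.approx(
                np.quantile(nuc_vals, 0.5))
            cell_vals = imgs[ch][cell].astype(float)
            assert feats[f"int_{ch}_cellular_mean"] == pytest.approx(cell_vals.mean())

        # pair pearson correlation, manual formula
        a = np.array([float(imgs["D"][r, c]) for r, c in zip(rows, cols)])
        d = np.array([float(imgs["CK"][r, c]) for r, c in zip(rows, cols)])
        manual = (((a - a.mean()) * (d - d.mean())).sum()
                  / math.sqrt(((a - a.mean()) ** 2).sum() * ((d - d.mean()) ** 2).sum()))
        assert feats["pair_D_CK_nuclear_corr_pearson"] == pytest.approx(manual)

    def test_shape_features_are_translation_invariant(self, schema):
        b1 = disk_mask(80, 80, 9) | disk_mask(86, 90, 5)  # asymmetric blob
        b2 = np.roll(np.roll(b1, 37, axis=0), 21, axis=1)
        img = np.full((256, 256), 500, dtype=np.uint16)
        stack = stack_from_frames({"D": img})
        [r1] = extract_features([mask_from_bool(b1)], stack, schema)
        [r2] = extract_features([mask_from_bool(b2)], stack, schema)
        shape_cols = [i for i, g in enumerate(schema.groups) if g == "shape"]
        np.testing.assert_allclose(r1.features[shape_cols], r2.features[shape_cols],
                                   rtol=1e-9)

    def test_mean_intensity_features_scale_with_pixel_values(self, schema):
        rng = np.random.default_rng(3)
        base = rng.integers(50, 400, (256, 256)).astype(np.uint16)
        b = disk_mask(128, 128, 10)
        s1 = stack_from_frames({ch: base for ch in CHANNELS})
        s3 = stack_from_frames({ch: (base * 3) for ch in CHANNELS})
        [r1] = extract_features([mask_from_bool(b)], s1, schema)
        [r3] = extract_features([mask_from_bool(b)], s3, schema)
        f1 = dict(zip(schema.names, r1.features))
        f3 = dict(zip(schema.names, r3.features))
        for ch in CHANNELS:
            for comp in ("nuclear", "cellular"):
                for stat in ("mean", "total", "q24", "q50", "q90"):
                    key = f"int_{ch}_{comp}_{stat}"
                    assert f3[key] == pytest.approx(3 * f1[key])

    def test_out_of_bounds_mask_raises(self, schema):
        stack = stack_from_frames({"D": np.zeros((256, 256), dtype=np.uint16)})
        bad = EventMask(0, 1, np.array([255, 256], dtype=np.int32),
                        np.array([0, 0], dtype=np.int32), (255, 0, 257, 1),
                        (255.5, 0.0))
        with pytest.raises(IndexError):
            extract_features([bad], stack, schema)

    def test_every_record_is_finite_and_schema_length(self, mini_events, schema):
        cols = list(schema.names)
        assert mini_events[cols].shape[1] == 761
        assert np.isfinite(mini_events[cols].to_numpy()).all()
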