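import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rarecell import classify as clf
from rarecell.classify import SchemaMismatchError
from rarecell.features import SchemaParams, build_feature_schema
from rarecell.phenotypes import CELL_TYPES, assign_cell_type, positivity_of

from conftest import random_feature_table

FAST_CV = clf.CVConfig(
    k=3, iterations=4,
    grid={"max_iter": [30, 60], "learning_rate": [0.1, 0.3],
          "max_leaf_nodes": [15], "l2_regularization": [0.0],
          "feature_subset": ["all"]},
)


class TestCellType:
    def test_definition_examples(self):
        assert assign_cell_type(True, False, False) == "D|CK"
        assert assign_cell_type(True, True, True) == "D|CK|V|CD"
        assert assign_cell_type(False, False, False) == "D"

    def test_all_combinations_give_eight_distinct_types(self):
        labels = {assign_cell_type(*c) for c in itertools.product([0, 1], repeat=3)}
        assert labels == set(CELL_TYPES)
        assert len(labels) == 8

    def test_positivity_roundtrip_is_a_bijection(self):
        for t in CELL_TYPES:
            assert assign_cell_type(*positivity_of(t)) == t


class TestSweepThresholds:
    def test_hand_computed_example(self):
        conf = np.array([0.95, 0.55, 0.20])
        labels = np.array([True, True, False])
        res = clf.sweep_thresholds(conf, labels, thresholds=(0.5, 0.9))
        at = res.set_index("threshold")
        assert at.loc[0.5, "sensitivity_pct"] == 100.0
        assert at.loc[0.5, "specificity_pct"] == 100.0
        assert at.loc[0.9, "sensitivity_pct"] == 50.0

    def test_boundary_is_closed_lower_bound(self):
        res = clf.sweep_thresholds(np.array([0.5]), np.array([True]),
                                   thresholds=(0.5,))
        assert res["tp"].iloc[0] == 1  # confidence == threshold counts positive

    @given(
        conf=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=200),
        bits=st.lists(st.booleans(), min_size=1, max_size=200),
    )
    def test_monotonicity_and_count_conservation(self, conf, bits):
        n = min(len(conf), len(bits))
        conf = np.array(conf[:n])
        labels = np.array(bits[:n])
        res = clf.sweep_thresholds(conf, labels)
        assert (res[["tp", "fp", "fn", "tn"]].sum(axis=1) == n).all()
        sens = res["sensitivity_pct"].to_numpy()
        spec = res["specificity_pct"].to_numpy()
        assert (np.diff(sens) <= 1e-9).all()
        assert (np.diff(spec) >= -1e-9).all()
        rates = res[["accuracy_pct", "precision_pct", "sensitivity_pct",
                     "specificity_pct"]].to_numpy()
        assert ((rates >= 0) & (rates <= 100)).all()

    def test_per_slide_averaging(self):
        conf = np.array([0.9, 0.9, 0.1, 0.1])
        labels = np.array([False, False, True, True])  # all wrong at tau=0.5
        slides = np.array(["a", "b", "a", "b"])
        res = clf.sweep_thresholds(conf, labels, slides, thresholds=(0.5,))
        assert res["avg_false_positives_per_slide"].iloc[0] == 1.0
        assert res["avg_false_negatives_per_slide"].iloc[0] == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            clf.sweep_thresholds(np.array([]), np.array([]))
        with pytest.raises(ValueError, match="thresholds"):
            clf.sweep_thresholds(np.array([0.5]), np.array([True]),
                                 thresholds=(1.5,))


@pytest.fixture(scope="module")
def separable(schema):
    """Linearly separable synthetic events: rare-like events shifted in
    intensity feature space."""
    rng = np.random.default_rng(20)
    neg = random_feature_table(schema, 80, rng)
    pos = random_feature_table(schema, 80, rng, shift_groups=("intensity_",),
                               shift=8.0)
    table = pd.concat([neg, pos], ignore_index=True)
    labels = np.array([False] * 80 + [True] * 80)
    return table, labels


class TestInterestingModel:
    def test_separable_data_gives_perfect_heldout_metrics(self, schema, separable):
        table, labels = separable
        tr = np.arange(0, 160, 2)
        te = np.arange(1, 160, 2)
        model = clf.train_interesting(table.iloc[tr], labels[tr], schema,
                                      cv=FAST_CV, seed=0)
        conf = clf.score_confidence(model, table.iloc[te], schema)
        pred = conf >= 0.5
        assert (pred == labels[te]).all()
        assert (conf >= 0).all() and (conf <= 1).all()
        assert len(conf) == len(te)

    def test_permuted_labels_score_at_chance(self, schema, separable):
        table, labels = separable
        rng = np.random.default_rng(0)
        perm = rng.permutation(labels)
        tr = np.arange(0, 160, 2)
        te = np.arange(1, 160, 2)
        model = clf.train_interesting(table.iloc[tr], perm[tr], schema,
                                      cv=FAST_CV, seed=0)
        conf = clf.score_confidence(model, table.iloc[te], schema)
        from sklearn.metrics import balanced_accuracy_score

        acc = balanced_accuracy_score(perm[te], conf >= 0.5)
        assert 0.3 < acc < 0.7

    def test_same_seed_reproduces_selection_and_predictions(self, schema, separable):
        table, labels = separable
        m1 = clf.train_interesting(table, labels, schema, cv=FAST_CV, seed=5)
        m2 = clf.train_interesting(table, labels, schema, cv=FAST_CV, seed=5)
        assert m1.best_params == m2.best_params
        np.testing.assert_array_equal(
            clf.score_confidence(m1, table, schema),
            clf.score_confidence(m2, table, schema))

    def test_single_class_input_rejected(self, schema, separable):
        table, _ = separable
        with pytest.raises(ValueError, match="both classes"):
            clf.train_interesting(table, np.ones(len(table), bool), schema,
                                  cv=FAST_CV, seed=0)

    def test_schema_mismatch_refused(self, schema, separable):
        table, labels = separable
        model = clf.train_interesting(table, labels, schema, cv=FAST_CV, seed=0)
        other = build_feature_schema(SchemaParams(channels=("D",),
                                                  expected_length=None))
        with pytest.raises(SchemaMismatchError):
            clf.score_confidence(model, table, other)


@pytest.fixture(scope="module")
def channel_separable(schema):
    """Events whose per-channel positivity is encoded as a clean shift in that
    channel's own intensity features."""
    rng = np.random.default_rng(30)
    n = 120
    table = random_feature_table(schema, n, rng)
    pos = pd.DataFrame({ch: rng.random(n) < 0.5 for ch in ("CK", "V", "CD")})
    for ch in ("CK", "V", "CD"):
        cols = [i for i, g in enumerate(schema.groups) if g == f"intensity_{ch}"]
        table.iloc[pos[ch].to_numpy(), cols] += 5.0
    return table, pos


class TestChannelTrio:
    def test_separable_channels_classified_perfectly(self, schema, channel_separable):
        table, pos = channel_separable
        tr = np.arange(0, 120, 2)
        te = np.arange(1, 120, 2)
        trio = clf.train_channel_models(table.iloc[tr], pos.iloc[tr], schema, seed=0)
        calls = clf.predict_channels(trio, table.iloc[te], schema)
        for ch in ("CK", "V", "CD"):
            assert (calls[f"{ch}_positive"].to_numpy() == pos[ch].iloc[te].to_numpy()).all()
        # phenotype label consistent with the three calls
        for _, row in calls.iterrows():
            assert row["cell_type"] == assign_cell_type(
                row["CK_positive"], row["V_positive"], row["CD_positive"])

    def test_permuted_channel_labels_score_at_chance(self, schema, channel_separable):
        table, pos = channel_separable
        rng = np.random.default_rng(1)
        perm = pos.sample(frac=1.0, random_state=2).reset_index(drop=True)
        tr = np.arange(0, 120, 2)
        te = np.arange(1, 120, 2)
        trio = clf.train_channel_models(table.iloc[tr], perm.iloc[tr], schema, seed=0)
        calls = clf.predict_channels(trio, table.iloc[te], schema)
        acc = np.mean(calls["CK_positive"].to_numpy() == perm["CK"].iloc[te].to_numpy())
        assert 0.25 < acc < 0.75

    def test_missing_class_error_names_the_channel(self, schema, channel_separable):
        table, pos = channel_separable
        bad = pos.copy()
        bad["V"] = True
        with pytest.raises(ValueError, match="channel V"):
            clf.train_channel_models(table, bad, schema, seed=0)

    def test_same_seed_identical_predictions(self, schema, channel_separable):
        table, pos = channel_separable
        t1 = clf.train_channel_models(table, pos, schema, seed=3)
        t2 = clf.train_channel_models(table, pos, schema, seed=3)
        c1 = clf.predict_channels(t1, table, schema)
        c2 = clf.predict_channels(t2, table, schema)
        pd.testing.assert_frame_equal(c1, c2)
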