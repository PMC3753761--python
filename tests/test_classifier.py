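"""Standardization, grid search, SVM training and the anatomical constraint."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from ovoseg.classifier import (
    TrainingConfig,
    _numeric_matrix,
    classify_specimen,
    classify_table,
    grid_search,
    standardize,
    train,
)
from ovoseg.model import ANNOTATION_COLUMN, FEATURE_COLUMNS, NOI
from ovoseg.phantom import GROUP2_CLASS_COUNTS, generate_feature_table


@pytest.fixture(scope="module")
def small_table():
    counts = {"humerus": 8, "radius": 8, "ulna": 8, "carpometacarpus": 8,
              "femur": 8, "tibiotarsus": 8, "tarsometatarsus": 8, NOI: 60}
    return generate_feature_table(counts, seed=5, days=(14, 15),
                                  specimens=[("e1", 14), ("e2", 14),
                                             ("e3", 15), ("e4", 15)])


class TestStandardize:
    def test_train_mode_zero_mean_unit_sd(self, group1_table):
        std, _ = standardize(group1_table)
        x = _numeric_matrix(std)
        assert np.abs(x.mean(axis=0)).max() < 1e-9
        assert np.abs(x.std(axis=0) - 1).max() < 1e-9

    def test_constant_column_warns_and_zeroes(self, small_table):
        table = small_table.copy()
        table["roundness"] = 0.5
        with pytest.warns(UserWarning, match="zero-variance"):
            std, _ = standardize(table)
        assert (std["roundness"] == 0).all()

    def test_stored_stats_reproduce_manual_transform(self, small_table):
        _, stats = standardize(small_table)
        other = generate_feature_table(
            {"femur": 2, NOI: 4}, seed=9, days=(15,), specimens=[("x", 15)])
        std, _ = standardize(other, stats)
        mean, sd = stats
        manual = (_numeric_matrix(other) - mean) / sd
        np.testing.assert_allclose(_numeric_matrix(std), manual, rtol=1e-12)

    def test_annotation_untouched(self, small_table):
        std, _ = standardize(small_table)
        assert (std[ANNOTATION_COLUMN] == small_table[ANNOTATION_COLUMN]).all()


class TestGridSearch:
    def test_single_point_grid_returns_that_point(self, small_table):
        config = TrainingConfig(c_grid=(2.0,), gamma_grid=(0.25,), cv_folds=3)
        assert grid_search(small_table, config) == (2.0, 0.25)

    def test_empty_grid_rejected(self, small_table):
        with pytest.raises(ValueError, match="empty"):
            grid_search(small_table,
                        TrainingConfig(c_grid=(), gamma_grid=(1.0,)))

    def test_winner_beats_every_other_grid_point(self, small_table):
        """Exhaustive re-score: no grid point outperforms the returned pair."""
        config = TrainingConfig(c_grid=(0.5, 2.0), gamma_grid=(0.05, 0.5),
                                cv_folds=3, seed=2)
        c_best, g_best = grid_search(small_table, config)
        std, _ = standardize(small_table)
        x = _numeric_matrix(std)
        y = small_table[ANNOTATION_COLUMN].to_numpy()
        cv = StratifiedKFold(3, shuffle=True, random_state=2)

        def score(c, g):
            return cross_val_score(SVC(kernel="rbf", C=c, gamma=g,
                                       random_state=2),
                                   x, y, cv=cv).mean()

        best = score(c_best, g_best)
        for c in config.c_grid:
            for g in config.gamma_grid:
                assert best >= score(c, g) - 1e-12


class TestTrain:
    def test_missing_class_named(self, small_table):
        partial = small_table[small_table[ANNOTATION_COLUMN] != "femur"]
        with pytest.raises(ValueError, match="femur"):
            train(partial)

    def test_single_class_rejected(self, small_table):
        noi_only = small_table[small_table[ANNOTATION_COLUMN] == NOI]
        with pytest.raises(ValueError):
            train(noi_only)

    def test_same_seed_identical_predictions(self, small_table):
        probe = generate_feature_table(GROUP2_CLASS_COUNTS, seed=8,
                                       days=(14, 15))
        m1 = train(small_table, seed=3)
        m2 = train(small_table, seed=3)
        pd.testing.assert_frame_equal(m1.predict_proba(probe),
                                      m2.predict_proba(probe))

    def test_save_load_round_trip(self, small_table, tmp_path):
        from ovoseg.classifier import ClassifierModel
        model = train(small_table, seed=0)
        probe = small_table.iloc[:10]
        model.save(tmp_path / "m.pkl")
        back = ClassifierModel.load(tmp_path / "m.pkl")
        pd.testing.assert_frame_equal(back.predict_proba(probe),
                                      model.predict_proba(probe))

    def test_schema_mismatch_names_columns(self, small_table):
        model = train(small_table, seed=0)
        broken = small_table.drop(columns=["roundness"])
        with pytest.raises(ValueError, match="roundness"):
            model.predict_proba(broken)


class _StubModel:
    """Fixed-probability model for exercising the constraint logic."""

    def __init__(self, proba: pd.DataFrame):
        self._proba = proba
        self.classes = tuple(proba.columns)

    def predict_proba(self, table):
        return self._proba.loc[table.index]


def _proba_frame(rows, classes=("femur", NOI)):
    return pd.DataFrame(rows, columns=classes)


class TestTwoPerClassConstraint:
    def test_three_femurs_keep_top_two(self):
        proba = _proba_frame([[0.9, 0.1], [0.8, 0.2], [0.7, 0.3]])
        table = pd.DataFrame({"object_id": [1, 2, 3],
                              **{c: [0.0] * 3 for c in FEATURE_COLUMNS}})
        labels, _ = classify_specimen(_StubModel(proba), table)
        assert list(labels) == ["femur", "femur", NOI]

    def test_two_or_fewer_is_identity(self):
        proba = _proba_frame([[0.9, 0.1], [0.2, 0.8]])
        table = pd.DataFrame({"object_id": [1, 2],
                              **{c: [0.0] * 2 for c in FEATURE_COLUMNS}})
        labels, _ = classify_specimen(_StubModel(proba), table)
        assert list(labels) == ["femur", NOI]

    def test_probability_tie_breaks_by_object_id(self):
        proba = _proba_frame([[0.8, 0.2], [0.8, 0.2], [0.8, 0.2]])
        table = pd.DataFrame({"object_id": [30, 10, 20],
                              **{c: [0.0] * 3 for c in FEATURE_COLUMNS}})
        labels, _ = classify_specimen(_StubModel(proba), table)
        # ids 10 and 20 keep the label, id 30 demoted
        assert list(labels) == [NOI, "femur", "femur"]

    def test_noi_is_never_constrained(self):
        proba = _proba_frame([[0.1, 0.9]] * 5)
        table = pd.DataFrame({"object_id": range(5),
                              **{c: [0.0] * 5 for c in FEATURE_COLUMNS}})
        labels, _ = classify_specimen(_StubModel(proba), table)
        assert (labels == NOI).all()

    def test_constraint_never_exceeds_two_per_class(self, group1_table):
        model = train(group1_table, seed=1)
        g2 = generate_feature_table(GROUP2_CLASS_COUNTS, seed=12,
                                    days=(13, 14, 15))
        labels, _ = classify_table(model, g2)
        counts = (pd.DataFrame({"specimen": g2["specimen_id"], "label": labels})
                  .groupby(["specimen", "label"]).size())
        bones = counts[counts.index.get_level_values("label") != NOI]
        assert (bones <= 2).all()
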