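"""Splits, base models, stacking, cross-validation, accuracy families."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fishspec import (
    ConfusionMatrix,
    ModelSpec,
    StudyConfig,
    crossval,
    evaluate_model,
    fit_model,
    fit_stacking,
    grouped_accuracy,
    simulate_study,
    split_train_test,
    tolerance_accuracy,
)
from fishspec.containers import VoxelTable, make_voxel_frame


def _toy_table(n_per_class=20, classes=(1, 3), bands=8, sep=5.0, seed=0):
    """Linearly separable two-class voxel table."""
    rng = np.random.default_rng(seed)
    frames = []
    for i, day in enumerate(classes):
        spectra = rng.normal(i * sep, 0.3, size=(n_per_class, bands))
        frames.append(make_voxel_frame(spectra, np.arange(bands) + 400.0,
                                       day=day, start_id=i * n_per_class))
    return VoxelTable(frame=pd.concat(frames, ignore_index=True), mode="FL")


class TestSplit:
    def test_balanced_80_20_split(self):
        ds = simulate_study(StudyConfig(days=(1, 3, 5, 7, 9),
                                        fillet_ids=("f1",),
                                        voxels_per_fillet_day=100), seed=0)
        table = ds.voxel_tables["FL"]
        train, test = split_train_test(table, 0.8, seed=0)
        assert len(train) == 400 and len(test) == 100
        assert all(c == 80 for c in train.frame["day"].value_counts())
        assert all(c == 20 for c in test.frame["day"].value_counts())

    def test_reproducible_and_exhaustive(self, small_study):
        table = small_study.voxel_tables["SWIR"]
        a_train, a_test = split_train_test(table, 0.8, seed=3)
        b_train, b_test = split_train_test(table, 0.8, seed=3)
        pd.testing.assert_frame_equal(a_train.frame, b_train.frame)
        ids = set(a_train.frame["voxel_id"]) | set(a_test.frame["voxel_id"])
        assert ids == set(table.frame["voxel_id"])
        assert not set(a_train.frame["voxel_id"]) & set(a_test.frame["voxel_id"])

    def test_singleton_class_errors(self):
        table = _toy_table(n_per_class=1)
        with pytest.raises(ValueError):
            split_train_test(table, 0.8, seed=0)


class TestBaseModels:
    def test_lda_separable_training_accuracy(self):
        table = _toy_table()
        model = fit_model(ModelSpec("LDA"), table)
        assert np.mean(model.predict(table.spectra()) == table.days()) == 1.0

    def test_knn_k1_memorizes_training_set(self):
        table = _toy_table()
        model = fit_model(ModelSpec("KNN", {"n_neighbors": 1}), table)
        assert np.mean(model.predict(table.spectra()) == table.days()) == 1.0

    def test_lr_iteration_cap_is_pinned(self):
        model = fit_model(ModelSpec("LR"), _toy_table())
        assert model.max_iter == 1000

    def test_permuted_labels_score_at_chance(self):
        rng = np.random.default_rng(1)
        table = _toy_table(n_per_class=40, classes=(1, 3, 5, 7), sep=4.0)
        frame = table.frame.copy()
        frame["day"] = rng.permutation(frame["day"].to_numpy())
        shuffled = VoxelTable(frame=frame, mode="FL")
        accs = crossval(shuffled, ModelSpec("LDA"), k=5, seed=0)
        # chance level 1/4; binomial noise band for n=160
        assert abs(accs.mean() - 0.25) < 0.15

    def test_unknown_model_errors(self):
        with pytest.raises(ValueError):
            fit_model(ModelSpec("MLP"), _toy_table())


class TestStacking:
    def test_meta_feature_width_is_bands_plus_three(self, small_study):
        train, _ = split_train_test(small_study.voxel_tables["FL"], 0.8, 0)
        model = fit_stacking(train, seed=0)
        assert model.meta_feature_width_ == 60 + 3

    def test_perfect_on_separable_data(self):
        table = _toy_table(n_per_class=40)
        train, test = split_train_test(table, 0.8, seed=0)
        model = fit_stacking(train, seed=0)
        cm = evaluate_model(model, test)
        assert cm.accuracy() == 1.0

    def test_augmented_meta_beats_predictions_only(self):
        """Meta-model on features+predictions >= meta on predictions alone."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(3)
        n, bands = 300, 12
        X = rng.normal(size=(n, bands))
        # label depends on a feature direction the base models only
        # partially capture under heavy label noise
        y = (X[:, :4].sum(axis=1) + rng.normal(0, 1.5, n) > 0).astype(int) + 1
        frame = make_voxel_frame(X, np.arange(bands) + 400.0)
        frame["day"] = y
        table = VoxelTable(frame=frame, mode="FL")
        train, test = split_train_test(table, 0.8, seed=0)
        stacked = fit_stacking(train, seed=0)
        acc_aug = evaluate_model(stacked, test).accuracy()
        preds_only = np.column_stack([
            m.predict(train.spectra()) for _, m in stacked.base_models_
        ])
        meta = LinearDiscriminantAnalysis().fit(preds_only, train.days())
        test_preds = np.column_stack([
            m.predict(test.spectra()) for _, m in stacked.base_models_
        ])
        acc_pred_only = np.mean(meta.predict(test_preds) == test.days())
        assert acc_aug >= acc_pred_only

    def test_fit_never_sees_test_rows(self, small_study):
        """Shuffling test labels must not change fitted parameters."""
        table = small_study.voxel_tables["FL"]
        train, test = split_train_test(table, 0.8, seed=0)
        model = fit_stacking(train, seed=0)
        before = model.predict(test.spectra())
        shuffled = test.frame.copy()
        shuffled["day"] = np.random.default_rng(9).permutation(
            shuffled["day"].to_numpy()
        )
        after = model.predict(VoxelTable(frame=shuffled, mode="FL").spectra())
        np.testing.assert_array_equal(before, after)
        np.testing.assert_array_equal(
            model.meta_model_.coef_, fit_stacking(train, seed=0).meta_model_.coef_
        )


class TestCrossval:
    def test_folds_partition_rows(self):
        table = _toy_table(n_per_class=25)
        accs = crossval(table, ModelSpec("LDA"), k=5, seed=0)
        assert len(accs) == 5
        assert np.all((accs >= 0) & (accs <= 1))

    def test_perfect_separability_all_folds(self):
        accs = crossval(_toy_table(n_per_class=25), ModelSpec("LDA"), k=5,
                        seed=0)
        assert np.all(accs == 1.0)

    def test_class_smaller_than_k_errors(self):
        with pytest.raises(ValueError):
            crossval(_toy_table(n_per_class=3), ModelSpec("LDA"), k=5, seed=0)


class TestAccuracyFamilies:
    perfect = ConfusionMatrix((1, 3, 7), np.diag([5, 6, 7]))

    def test_perfect_predictions_are_diagonal(self):
        table = _toy_table()
        model = fit_model(ModelSpec("LDA"), table)
        cm = evaluate_model(model, table)
        assert np.trace(cm.counts) == cm.total

    def test_row_sums_equal_class_sizes(self, small_study):
        table = small_study.voxel_tables["VISNIR"]
        train, test = split_train_test(table, 0.8, seed=0)
        cm = evaluate_model(fit_model(ModelSpec("KNN"), train), test)
        expected = test.frame["day"].value_counts().sort_index().to_numpy()
        np.testing.assert_array_equal(cm.counts.sum(axis=1), expected)

    def test_tolerance_zero_is_trace_over_total(self):
        cm = ConfusionMatrix((1, 2, 3),
                             np.array([[4, 1, 0], [0, 5, 1], [0, 0, 4]]))
        assert tolerance_accuracy(cm, 0) == pytest.approx(13 / 15)

    def test_sparse_day_grid_tolerance_one_equals_exact(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 30, size=(5, 5))
        cm = ConfusionMatrix((1, 3, 7, 9, 11), counts)
        assert tolerance_accuracy(cm, 1) == cm.accuracy()

    def test_adjacent_errors_within_one_day(self):
        cm = ConfusionMatrix((1, 2, 3),
                             np.array([[4, 1, 0], [1, 5, 1], [0, 2, 4]]))
        assert tolerance_accuracy(cm, 1) == 1.0

    @given(st.integers(0, 2**31 - 1), st.integers(0, 3))
    def test_tolerance_accuracy_monotone(self, seed, t):
        rng = np.random.default_rng(seed)
        cm = ConfusionMatrix((1, 2, 3, 5),
                             rng.integers(0, 20, size=(4, 4)) + 1)
        assert tolerance_accuracy(cm, t) <= tolerance_accuracy(cm, t + 1)

    def test_identity_grouping_is_ungrouped_accuracy(self):
        cm = ConfusionMatrix((1, 3, 7),
                             np.array([[4, 1, 0], [0, 5, 1], [2, 0, 4]]))
        assert grouped_accuracy(cm, {1: "a", 3: "b", 7: "c"}) == cm.accuracy()

    @given(st.integers(0, 2**31 - 1))
    def test_grouping_never_reduces_accuracy(self, seed):
        rng = np.random.default_rng(seed)
        cm = ConfusionMatrix((1, 3, 7, 9, 11),
                             rng.integers(0, 20, size=(5, 5)) + 1)
        grouping = {1: "fresh", 3: "fresh", 7: "mid", 9: "spoilt",
                    11: "spoilt"}
        assert grouped_accuracy(cm, grouping) >= cm.accuracy()

    def test_missing_day_in_grouping_errors(self):
        with pytest.raises(ValueError):
            grouped_accuracy(self.perfect, {1: "a", 3: "a"})
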