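"""Upsampling, splitting and meta-learner behaviour of the stacking ensemble."""

import numpy as np
import pandas as pd
import pytest

from tierstack import LOS_SCHEME, TierStackingClassifier, assign_class
from tierstack.ensemble import (
    META_FAMILIES,
    META_FEATURE_COLUMNS,
    fit_meta,
    predict_tier,
    split_train_test,
    upsample_balance,
)
from tierstack.errors import (
    EmptyInputError,
    InvalidSpecError,
    MissingTierError,
    UnbalancedInputError,
)


def _meta_rows(n, rng):
    return pd.DataFrame(
        {
            "p_ge_t1": rng.random(n),
            "p_ge_t2": rng.random(n),
            "p_ge_t3": rng.random(n),
            "current_usage": rng.integers(0, 30, n).astype(float),
        }
    )


def _labels_with_counts(counts):
    return np.repeat([0, 1, 2, 3], counts)


class TestUpsampleBalance:
    def test_counts_equalized(self, rng):
        labels = _labels_with_counts([100, 50, 30, 20])
        rows = _meta_rows(200, rng)
        out_rows, out_labels = upsample_balance(rows, labels, seed=0)
        assert np.bincount(out_labels, minlength=4).tolist() == [100, 100, 100, 100]
        assert len(out_rows) == 400

    def test_balanced_input_is_fixed_point(self, rng):
        labels = _labels_with_counts([25, 25, 25, 25])
        rows = _meta_rows(100, rng)
        out_rows, out_labels = upsample_balance(rows, labels, seed=0)
        assert np.bincount(out_labels, minlength=4).tolist() == [25, 25, 25, 25]
        pd.testing.assert_frame_equal(out_rows.sort_values(list(out_rows.columns)).reset_index(drop=True),
                                      rows.sort_values(list(rows.columns)).reset_index(drop=True))

    def test_missing_tier_rejected(self, rng):
        labels = np.repeat([0, 2, 3], [10, 5, 5])
        with pytest.raises(MissingTierError):
            upsample_balance(_meta_rows(20, rng), labels, seed=0)

    def test_original_multiset_retained(self, rng):
        """Upsampling only adds duplicates: originals remain a sub-multiset."""
        labels = _labels_with_counts([40, 25, 20, 15])
        rows = _meta_rows(100, rng)
        rows["row_id"] = np.arange(100)
        out_rows, _ = upsample_balance(rows, labels, seed=3)
        orig_counts = rows.row_id.value_counts()
        out_counts = out_rows.row_id.value_counts()
        assert all(out_counts.get(i, 0) >= 1 for i in orig_counts.index)


class TestSplit:
    def test_sizes(self, rng):
        rows = _meta_rows(1000, rng)
        labels = _labels_with_counts([400, 300, 200, 100])
        tr, te, ltr, lte = split_train_test(rows, labels, fraction=0.75, seed=0)
        assert len(tr) == 750 and len(te) == 250

    def test_same_seed_identical(self, rng):
        rows = _meta_rows(400, rng)
        labels = _labels_with_counts([100, 100, 100, 100])
        a = split_train_test(rows, labels, seed=5)
        b = split_train_test(rows, labels, seed=5)
        pd.testing.assert_frame_equal(a[0], b[0])
        np.testing.assert_array_equal(a[2], b[2])

    def test_stratification_preserves_shares(self, rng):
        rows = _meta_rows(10_000, rng)
        labels = _labels_with_counts([5000, 2500, 1500, 1000])
        _, _, _, lte = split_train_test(rows, labels, fraction=0.75, seed=1)
        overall = np.bincount(labels) / labels.size
        test_share = np.bincount(lte, minlength=4) / lte.size
        assert np.all(np.abs(test_share - overall) < 0.05)

    def test_empty_input_rejected(self, rng):
        with pytest.raises(EmptyInputError):
            split_train_test(_meta_rows(0, rng), np.array([]), seed=0)
        with pytest.raises(InvalidSpecError):
            split_train_test(_meta_rows(10, rng), np.zeros(10, int), fraction=1.5)


class TestMetaLearner:
    def _oracle_rows(self, n_per_tier, rng):
        """Meta-features that perfectly encode the tier (monotone staircase)."""
        frames, labels = [], []
        for tier in range(4):
            p = [1.0 if tier >= j else 0.0 for j in (1, 2, 3)]
            frames.append(
                pd.DataFrame(
                    {
                        "p_ge_t1": p[0],
                        "p_ge_t2": p[1],
                        "p_ge_t3": p[2],
                        "current_usage": rng.integers(0, 5, n_per_tier).astype(float),
                    }
                )
            )
            labels.append(np.full(n_per_tier, tier))
        return pd.concat(frames, ignore_index=True), np.concatenate(labels)

    @pytest.mark.parametrize("meta_family", META_FAMILIES)
    def test_perfect_meta_features_give_perfect_heldout_accuracy(self, meta_family, rng):
        rows, labels = self._oracle_rows(60, rng)
        tr, te, ltr, lte = split_train_test(rows, labels, fraction=0.75, seed=0)
        tr, ltr = upsample_balance(tr, ltr, seed=0)
        meta = fit_meta(meta_family, tr, ltr, seed=0)
        assert np.mean(predict_tier(meta, te) == lte) == 1.0

    def test_permuted_labels_give_chance_accuracy(self, rng):
        """Balanced 4-class task with uninformative features: held-out accuracy ~ 0.25."""
        rows = _meta_rows(2000, rng)
        labels = rng.permutation(_labels_with_counts([500, 500, 500, 500]))
        tr, te, ltr, lte = split_train_test(rows, labels, fraction=0.75, seed=1)
        meta = fit_meta("boosted_tree", tr, ltr, seed=1, require_balanced=False)
        acc = np.mean(predict_tier(meta, te) == lte)
        assert abs(acc - 0.25) < 0.05

    def test_identical_rows_predict_single_tier(self, rng):
        rows = pd.DataFrame(
            {"p_ge_t1": 0.5, "p_ge_t2": 0.5, "p_ge_t3": 0.5, "current_usage": 1.0}, index=range(100)
        )
        labels = _labels_with_counts([25, 25, 25, 25])
        meta = fit_meta("random_forest", rows, labels, seed=0)
        pred = predict_tier(meta, rows)
        assert np.unique(pred).size == 1

    def test_unbalanced_input_rejected_when_balance_required(self, rng):
        rows = _meta_rows(100, rng)
        labels = _labels_with_counts([40, 30, 20, 10])
        with pytest.raises(UnbalancedInputError):
            fit_meta("boosted_tree", rows, labels, seed=0, require_balanced=True)

    def test_probabilities_outside_unit_interval_rejected(self):
        rows = pd.DataFrame({"p_ge_t1": [1.2], "p_ge_t2": [0.5], "p_ge_t3": [0.1], "current_usage": [0.0]})
        from tierstack.errors import SchemaMismatchError

        with pytest.raises(SchemaMismatchError):
            fit_meta("boosted_tree", pd.concat([rows] * 4, ignore_index=True), np.array([0, 1, 2, 3]), seed=0)

    def test_linear_svm_scores_are_probability_like(self, rng):
        rows, labels = self._oracle_rows(40, rng)
        rows_b, labels_b = upsample_balance(rows, labels, seed=0)
        meta = fit_meta("linear_svm", rows_b, labels_b, seed=0)
        scores = meta.predict_scores(rows)
        assert scores.shape == (len(rows), 4)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)


class TestStackingEstimator:
    def test_end_to_end_determinism(self, small_cohort, los_design_cols):
        year0 = small_cohort[small_cohort.year_index == 0]
        X = year0[los_design_cols]
        y = year0.next_los_days.to_numpy()
        preds = []
        for _ in range(2):
            clf = TierStackingClassifier(base_family="logistic", meta_family="boosted_tree", seed=9)
            clf.fit(X, y)
            preds.append(clf.predict(X))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_sklearn_params_clone(self):
        from sklearn.base import clone

        clf = TierStackingClassifier(base_family="mars", meta_family="linear_svm", seed=3)
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()

    def test_predict_proba_shape_and_classes(self, small_cohort, los_design_cols):
        year0 = small_cohort[small_cohort.year_index == 0].head(1200)
        clf = TierStackingClassifier(base_family="logistic", meta_family="random_forest", seed=2)
        clf.fit(year0[los_design_cols], year0.next_los_days.to_numpy())
        scores = clf.predict_proba(year0[los_design_cols])
        assert scores.shape == (1200, 4)
        assert np.all(clf.predict(year0[los_design_cols]) == clf.classes_[scores.argmax(axis=1)])

    def test_meta_feature_assembly_matches_scheme(self, small_cohort, los_design_cols):
        year0 = small_cohort[small_cohort.year_index == 0].head(800)
        clf = TierStackingClassifier(base_family="logistic", meta_family="boosted_tree", seed=4)
        clf.fit(year0[los_design_cols], year0.next_los_days.to_numpy())
        meta = clf._meta_for(year0[los_design_cols])
        assert list(meta.columns) == list(META_FEATURE_COLUMNS)
        np.testing.assert_array_equal(meta.current_usage.to_numpy(), year0.current_los_days.to_numpy(dtype=float))

    def test_temporal_hygiene_validation_year_never_fit(self, small_cohort, los_design_cols):
        """Fitting on the train year and scoring the validation year leaves the
        validation records untouched by any fit: refitting without them yields
        the same model outputs."""
        year0 = small_cohort[small_cohort.year_index == 0]
        year1 = small_cohort[small_cohort.year_index == 1]
        clf = TierStackingClassifier(base_family="logistic", meta_family="boosted_tree", seed=5)
        clf.fit(year0[los_design_cols], year0.next_los_days.to_numpy())
        pred_before = clf.predict(year1[los_design_cols])
        # scoring must not mutate the fitted model
        pred_after = clf.predict(year1[los_design_cols])
        np.testing.assert_array_equal(pred_before, pred_after)
        actual = assign_class(year1.next_los_days.to_numpy(), LOS_SCHEME)
        assert pred_before.shape == actual.shape
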