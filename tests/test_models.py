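"""QC calibration, embedding and phenotype-classification contracts."""

import warnings

import numpy as np
import pandas as pd
import pytest

from senotex.datasets import make_condition_dataset
from senotex.models import (
    QCParams,
    REJECT_ALL,
    apply_qc,
    classify_treated,
    condition_summaries,
    embed,
    feature_columns,
    predict_condition,
    standardize,
    train_condition,
    train_qc,
)


class TestStandardize:
    def test_fit_transforms_to_zero_mean_unit_sd(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        Z, stats = standardize(X)
        assert Z["a"].mean() == pytest.approx(0.0)
        assert Z["a"].std(ddof=0) == pytest.approx(1.0)

    def test_constant_column_zeroed_and_flagged(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        Z, stats = standardize(X)
        assert (Z["c"] == 0.0).all()
        assert "c" in stats.zero_variance

    def test_heldout_transform_uses_stored_stats(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        _, stats = standardize(X)
        heldout = pd.DataFrame({"a": [10.0, 11.0, 12.0]})
        Z, _ = standardize(heldout, stats)
        # shifted data is not re-centred: stored mean 1, sd sqrt(2/3)
        assert Z["a"].mean() == pytest.approx((11 - 1) / np.sqrt(2 / 3))

    def test_single_row_fit_rejected(self):
        with pytest.raises(ValueError):
            standardize(pd.DataFrame({"a": [1.0]}))


class TestQC:
    def test_separable_features_calibrate_to_finite_threshold(self, qc_small):
        df, labels, _ = qc_small
        model = train_qc(df, labels, QCParams(n_trees=100, seed=0))
        assert 0.0 <= model.threshold <= 1.0
        assert not model.reject_all

    def test_heldout_precision_reaches_target(self, qc_small):
        from senotex.datasets import make_qc_dataset

        df, labels, _ = qc_small
        model = train_qc(df, labels, QCParams(n_trees=100, seed=0))
        df_te, labels_te, _ = make_qc_dataset(40, 40, seed=77)
        keep, _ = apply_qc(model, df_te)
        assert keep.any()
        assert np.asarray(labels_te)[keep].mean() >= 0.9  # small-n spot check

    def test_shuffled_labels_trigger_reject_all(self, qc_small):
        df, labels, _ = qc_small
        rng = np.random.default_rng(0)
        sentinel_hits = 0
        for trial in range(5):
            y = rng.permutation(labels)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = train_qc(df, y, QCParams(n_trees=50, seed=trial))
            if model.reject_all:
                sentinel_hits += 1
        assert sentinel_hits >= 4  # a random scorer cannot reach 95% precision

    def test_single_class_rejected(self, qc_small):
        df, labels, _ = qc_small
        with pytest.raises(ValueError):
            train_qc(df, np.ones_like(labels), QCParams())

    def test_threshold_zero_keeps_everything(self, qc_small):
        import dataclasses

        df, labels, _ = qc_small
        model = train_qc(df, labels, QCParams(n_trees=50, seed=0))
        model = dataclasses.replace(model, threshold=0.0)
        keep, _ = apply_qc(model, df)
        assert keep.all()

    def test_reject_all_keeps_nothing(self, qc_small):
        import dataclasses

        df, labels, _ = qc_small
        model = train_qc(df, labels, QCParams(n_trees=50, seed=0))
        model = dataclasses.replace(model, threshold=REJECT_ALL)
        keep, _ = apply_qc(model, df)
        assert not keep.any()

    def test_schema_mismatch_rejected(self, qc_small):
        df, labels, _ = qc_small
        model = train_qc(df, labels, QCParams(n_trees=50, seed=0))
        with pytest.raises(ValueError):
            apply_qc(model, df.drop(columns=["area_px"]))

    def test_threshold_computed_from_training_half_only(self, qc_small):
        # identical training data => identical threshold, regardless of what
        # is later scored (no test-set leakage into calibration)
        df, labels, _ = qc_small
        m1 = train_qc(df, labels, QCParams(n_trees=50, seed=3))
        m2 = train_qc(df, labels, QCParams(n_trees=50, seed=3))
        assert m1.threshold == m2.threshold


class TestEmbedding:
    def test_shape_and_determinism(self, two_cond_train):
        df, _ = two_cond_train
        r1 = embed(df, perplexity=10, seed=4)
        r2 = embed(df, perplexity=10, seed=4)
        assert r1.coords.shape == (len(df), 2)
        np.testing.assert_array_equal(r1.coords, r2.coords)

    def test_too_few_points_rejected(self, two_cond_train):
        df, _ = two_cond_train
        with pytest.raises(ValueError):
            embed(df.head(10), perplexity=30, seed=0)

    def test_disjoint_conditions_separate_in_embedding(self, two_cond_train):
        from sklearn.metrics import silhouette_score

        df, labels = two_cond_train
        scores = [
            silhouette_score(embed(df, perplexity=10, seed=s).coords, labels)
            for s in range(5)
        ]
        assert np.mean(scores) >= 0.5


class TestConditionModel:
    def test_missing_class_rejected(self, two_cond_train):
        df, labels = two_cond_train
        sub = df[labels == "senescent"]
        with pytest.raises(ValueError):
            train_condition(sub, ["senescent"] * len(sub))

    def test_heldout_accuracy_on_disjoint_generators(
        self, two_cond_train, two_cond_test
    ):
        df, labels = two_cond_train
        model = train_condition(df, labels)
        df_te, labels_te = two_cond_test
        acc = (predict_condition(model, df_te) == labels_te).mean()
        assert acc >= 0.95

    def test_identical_generators_give_chance_accuracy(self):
        # both "classes" drawn from the proliferating generator
        df, _ = make_condition_dataset(30, ("proliferating",), seed=31)
        y = np.array(["proliferating", "senescent"] * 15)
        train_idx = np.arange(0, 20)
        test_idx = np.arange(20, 30)
        model = train_condition(df.iloc[train_idx], y[train_idx])
        acc = (predict_condition(model, df.iloc[test_idx]) == y[test_idx]).mean()
        # 95% binomial CI of 0.5 at n=10
        assert abs(acc - 0.5) <= 1.96 * np.sqrt(0.25 / len(test_idx))

    def test_small_fit_serializes(self, two_cond_train, tmp_path):
        from senotex.io import load_model_bundle, save_model_bundle

        df, labels = two_cond_train
        sub = pd.concat(
            [df[labels == c].head(10) for c in ("proliferating", "senescent")]
        )
        suby = ["proliferating"] * 10 + ["senescent"] * 10
        model = train_condition(sub, suby)
        path = tmp_path / "svm.zip"
        save_model_bundle(path, {"model": model}, {"kind": "condition"})
        payload, manifest = load_model_bundle(path)
        assert manifest["kind"] == "condition"
        np.testing.assert_array_equal(
            predict_condition(payload["model"], df), predict_condition(model, df)
        )


class TestClassifyTreated:
    def test_senescent_drawn_group_scores_senescent(self, two_cond_train, two_cond_test):
        df, labels = two_cond_train
        model = train_condition(df, labels)
        df_te, labels_te = two_cond_test
        sen = df_te[labels_te == "senescent"]
        summary = classify_treated(model, {"treated_d6": sen})
        fr = summary.fractions["treated_d6"]
        assert fr["senescent"] >= 0.9
        assert fr["proliferating"] + fr["senescent"] == pytest.approx(1.0, abs=1e-12)
        assert summary.call("treated_d6") == "senescent"

    def test_balanced_mixture_is_ambiguous(self, two_cond_train, two_cond_test):
        df, labels = two_cond_train
        model = train_condition(df, labels)
        df_te, labels_te = two_cond_test
        summary = classify_treated(model, {"mix": df_te})
        fr = summary.fractions["mix"]
        n = len(df_te)
        assert abs(fr["senescent"] - 0.5) <= 1.96 * np.sqrt(0.25 / n) + 1e-9
        assert summary.call("mix") == "ambiguous"

    def test_empty_group_omitted_with_warning(self, two_cond_train):
        df, labels = two_cond_train
        model = train_condition(df, labels)
        with pytest.warns(UserWarning):
            summary = classify_treated(model, {"empty": df.head(0)})
        assert "empty" not in summary.fractions


class TestConditionSummaries:
    def test_senescent_median_area_exceeds_proliferating(self, two_cond_train):
        df, labels = two_cond_train
        tab = condition_summaries(df, labels)
        med = tab.set_index(["condition", "feature"])["median"]
        assert med[("senescent", "area_px")] > med[("proliferating", "area_px")]

    def test_default_features_present(self, two_cond_train):
        df, labels = two_cond_train
        tab = condition_summaries(df, labels)
        assert set(tab["feature"]) == {
            "area_px", "glcm_energy_d4_a0", "glcm_dissimilarity_d2_a90",
        }

    def test_single_condition_one_row_per_feature(self, two_cond_train):
        df, labels = two_cond_train
        sub = df[labels == "senescent"]
        tab = condition_summaries(sub, ["senescent"] * len(sub))
        assert len(tab) == 3

    def test_empty_input_empty_table(self, two_cond_train):
        df, _ = two_cond_train
        tab = condition_summaries(df.head(0), [])
        assert tab.empty


def test_aux_features_excluded_from_model_columns(two_cond_train):
    df, _ = two_cond_train
    cols = feature_columns(df, include_aux=False)
    assert "n_blank_rows" not in cols
    assert "img_width" not in cols
    assert "glcm_energy_d4_a0" in cols
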