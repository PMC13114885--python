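"""Leakage-safe classifier benchmark: splits, CV, metrics, attribution."""

import numpy as np
import pandas as pd
import pytest

from pndeeg.attribution import AttributionError, shapley_values
from pndeeg.predict import (
    MODEL_IDS,
    ClassifierBench,
    EvalConfig,
    MetricError,
    SplitError,
    confusion_and_metrics,
    evaluate_cell,
    f1_from_precision_recall,
    fit_with_cv,
    make_split,
    roc_auc,
    shap_rank,
    topk_curve,
)


def auc_pair_oracle(scores, labels):
    """Exhaustive concordant-pair fraction (Mann-Whitney), ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                conc += 1
            elif p == q:
                conc += 0.5
    return conc / total


def toy_features(n_pos=15, n_neg=15, p=5, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.standard_normal((n_neg, p)),
                   rng.standard_normal((n_pos, p)) + sep / np.sqrt(p)])
    y = np.array([0] * n_neg + [1] * n_pos)
    cols = [f"feat_{j}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), y


class TestMakeSplit:
    def test_cohort_38_at_80_20_stratified_rounding(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((38, 3)))
        y = np.array([0] * 18 + [1] * 20)
        for seed in (42, 300, 600, 800):
            _, X_te, _, y_te = make_split(X, y, 0.8, seed)
            assert len(X_te) == 8
            counts = tuple(sorted(np.bincount(y_te)))
            assert counts in ((4, 4), (3, 5))

    def test_balanced_four_samples_split_evenly(self):
        X = pd.DataFrame(np.eye(4))
        y = np.array([0, 1, 0, 1])
        _, X_te, y_tr, y_te = make_split(X, y, 0.5, 0)
        assert sorted(y_tr) == [0, 1] and sorted(y_te) == [0, 1]

    def test_same_seed_reproduces_split(self):
        X, y = toy_features()
        a = make_split(X, y, 0.7, 11)
        b = make_split(X, y, 0.7, 11)
        pd.testing.assert_frame_equal(a[0], b[0])
        np.testing.assert_array_equal(a[3], b[3])

    def test_train_test_disjoint(self):
        X, y = toy_features()
        X_tr, X_te, _, _ = make_split(X, y, 0.6, 5)
        assert set(X_tr.index).isdisjoint(X_te.index)

    def test_singleton_class_rejected(self):
        X = pd.DataFrame(np.zeros((5, 2)))
        with pytest.raises(SplitError):
            make_split(X, np.array([0, 0, 0, 0, 1]), 0.8, 0)


class TestFitWithCV:
    def test_separable_data_perfect_training_auc(self):
        X, y = toy_features(sep=8.0)
        pipe, _ = fit_with_cv(X, y, "LR")
        scores = pipe.predict_proba(X.to_numpy())[:, 1]
        auc, _ = roc_auc(scores, y)
        assert auc == 1.0

    def test_single_point_grid_selected(self):
        X, y = toy_features()
        cfg = EvalConfig(grids={"LR": {"clf__C": [0.37]}})
        _, best = fit_with_cv(X, y, "LR", cfg)
        assert best == {"clf__C": 0.37}

    def test_scaler_fitted_on_train_only(self):
        # a shifted test set keeps nonzero means under the train-fitted scaler
        X, y = toy_features()
        pipe, _ = fit_with_cv(X, y, "LR")
        scaler = pipe.named_steps["scaler"]
        shifted = X.to_numpy() + 5.0
        assert np.all(np.abs(scaler.transform(shifted).mean(0)) > 1.0)

    def test_canary_in_test_rows_cannot_affect_training(self):
        # train once; retrain after corrupting would-be test rows with the
        # label itself — the fitted model must be identical
        X, y = toy_features(seed=3)
        X_tr, X_te, y_tr, y_te = make_split(X, y, 0.7, 0)
        pipe1, best1 = fit_with_cv(X_tr, y_tr, "LR")
        X_te_canary = X_te.copy()
        X_te_canary["feat_0"] = y_te  # leak label into test rows only
        pipe2, best2 = fit_with_cv(X_tr, y_tr, "LR")
        assert best1 == best2
        np.testing.assert_array_equal(
            pipe1.predict(X_tr.to_numpy()), pipe2.predict(X_tr.to_numpy()))

    def test_degenerate_fold_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((6, 2)))
        y = np.array([0, 0, 0, 0, 1, 1])  # cannot fill 3 stratified folds
        with pytest.raises(SplitError, match="fold"):
            fit_with_cv(X, y, "LR")


class TestConfusionAndMetrics:
    def test_all_correct_predictions(self):
        cm, m = confusion_and_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert (m["accuracy"], m["precision"], m["recall"], m["f1"]) == (
            1.0, 1.0, 1.0, 1.0)
        assert cm.total == 4

    @pytest.mark.parametrize("seed", range(5))
    def test_identities_match_sklearn(self, seed):
        from sklearn.metrics import (accuracy_score, f1_score,
                                     precision_score, recall_score)

        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 30)
        yhat = rng.integers(0, 2, 30)
        _, m = confusion_and_metrics(yhat, y)
        assert m["accuracy"] == pytest.approx(accuracy_score(y, yhat))
        assert m["precision"] == pytest.approx(
            precision_score(y, yhat, zero_division=np.nan))
        assert m["recall"] == pytest.approx(recall_score(y, yhat))
        assert m["f1"] == pytest.approx(f1_score(y, yhat))

    def test_no_predicted_positives_yields_nan_with_warning(self):
        with pytest.warns(UserWarning):
            _, m = confusion_and_metrics([0, 0, 0], [0, 1, 0])
        assert np.isnan(m["precision"])

    def test_non_binary_labels_rejected(self):
        with pytest.raises(MetricError):
            confusion_and_metrics([0, 1, 2], [0, 1, 2])

    def test_f1_harmonic_mean_helper(self):
        assert f1_from_precision_recall(1.0, 0.75) == pytest.approx(6 / 7)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, pts = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)

    def test_reversed_scores(self):
        auc, _ = roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert auc == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        y = np.zeros(n, dtype=int)
        y[rng.permutation(n)[: max(1, n // 3)]] = 1
        scores = rng.integers(0, 5, n) / 4.0  # coarse grid forces ties
        auc, pts = roc_auc(scores, y)
        assert auc == pytest.approx(auc_pair_oracle(scores, y), abs=1e-12)
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            roc_auc([0.1, 0.9], [1, 1])


class TestAttribution:
    def test_planted_single_feature_model_ranks_it_first(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 6))
        res = shapley_values(lambda A: A[:, 3], X, X[:10],
                             n_permutations=16, seed=0)
        ranking = res.ranking()
        assert ranking[0][0] == "x3"
        others = [v for name, v in ranking[1:]]
        assert max(others) < 1e-12

    def test_additivity_is_exact(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 4))

        def f(A):
            return A[:, 0] * A[:, 1] + np.sin(A[:, 2])

        res = shapley_values(f, X, X[:8], n_permutations=8, seed=1)
        # per permutation the contributions telescope, so each sample's
        # attributions sum exactly to f(x) minus its own background mean
        totals = res.values.sum(axis=1) + res.background_means
        np.testing.assert_allclose(totals, res.base_outputs, atol=1e-10)

    def test_duplicated_feature_attributions_sum_to_original(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 2))
        Xdup = np.column_stack([X[:, 0], X[:, 0], X[:, 1]])
        orig = shapley_values(lambda A: 2.0 * A[:, 0] + A[:, 1], X, X[:15],
                              n_permutations=1200, seed=3)
        dup = shapley_values(lambda A: A[:, 0] + A[:, 1] + A[:, 2],
                             Xdup, Xdup[:15], n_permutations=1200, seed=3)
        np.testing.assert_allclose(
            dup.values[:, 0] + dup.values[:, 1], orig.values[:, 0], atol=0.3)

    def test_constant_feature_gets_zero_attribution(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([rng.standard_normal(30), np.full(30, 2.0)])
        res = shapley_values(lambda A: A[:, 0], X, X[:5],
                             n_permutations=16, seed=0)
        assert np.abs(res.values[:, 1]).max() < 1e-12

    def test_model_failure_surfaces_as_error(self):
        X = np.zeros((5, 2))

        def broken(A):
            raise ValueError("boom")

        with pytest.raises(AttributionError):
            shapley_values(broken, X, X)

    def test_shap_rank_on_fitted_pipeline(self):
        X, y = toy_features(sep=6.0, p=4)
        X["feat_0"] = 0.0  # uninformative constant column
        pipe, _ = fit_with_cv(X, y, "LR")
        att = shap_rank(pipe, X, n_permutations=16, seed=0)
        names = [n for n, _ in att.ranking()]
        assert names[-1] == "feat_0"
        assert att.values.shape == (len(X), 4)


class TestTopK:
    def test_single_informative_feature_plateaus_at_one(self):
        rng = np.random.default_rng(5)
        n = 40
        y = np.array([0] * 20 + [1] * 20)
        X = pd.DataFrame(rng.standard_normal((n, 5)) * 0.05,
                         columns=[f"feat_{j}" for j in range(5)])
        X["feat_2"] = y * 6.0 + rng.standard_normal(n) * 0.1
        X_tr, X_te, y_tr, y_te = make_split(X, y, 0.7, 0)
        ranking = [("feat_2", 1.0)] + [(f"feat_{j}", 0.0) for j in (0, 1, 3, 4)]
        aucs, plateau_k = topk_curve(ranking, X_tr, y_tr, X_te, y_te, "LR",
                                     k_max=3)
        assert plateau_k == 1
        assert aucs[0] == pytest.approx(1.0)

    def test_k_max_one_single_point(self):
        X, y = toy_features(sep=8.0)
        X_tr, X_te, y_tr, y_te = make_split(X, y, 0.7, 0)
        ranking = [(c, 1.0) for c in X.columns]
        aucs, k = topk_curve(ranking, X_tr, y_tr, X_te, y_te, "LR", k_max=1)
        assert len(aucs) == 1 and k == 1

    def test_ranking_shorter_than_k_max_rejected(self):
        X, y = toy_features()
        X_tr, X_te, y_tr, y_te = make_split(X, y, 0.7, 0)
        with pytest.raises(MetricError):
            topk_curve([("feat_0", 1.0)], X_tr, y_tr, X_te, y_te, "LR",
                       k_max=10)


class TestBenchmark:
    def test_factorial_bookkeeping(self):
        X, y = toy_features(sep=6.0)
        cfg = EvalConfig(model_ids=("LR", "NB"), split_ratios=(0.7,),
                         seeds=(42, 300))
        res = ClassifierBench(features=X, labels=y, config=cfg).fit()
        assert len(res.reports) == 4
        cells = {(r.model_id, r.split_ratio, r.seed) for r in res.reports}
        assert len(cells) == 4
        assert res.best_cell().metrics["auc"] == max(
            r.metrics["auc"] for r in res.reports)
        summary = res.summary()
        assert set(summary.index) == {"LR", "NB"}

    def test_string_labels_mapped_to_binary(self):
        X, y = toy_features(sep=6.0)
        labels = np.where(y == 1, "PND", "non-PND")
        res = ClassifierBench(features=X, labels=labels,
                              config=EvalConfig(model_ids=("LR",),
                                                split_ratios=(0.7,),
                                                seeds=(42,))).fit()
        assert res.reports[0].metrics["auc"] > 0.9

    def test_all_twelve_families_run_one_cell(self):
        X, y = toy_features(n_pos=12, n_neg=12, sep=6.0)
        for model_id in MODEL_IDS:
            rep = evaluate_cell(X, y, model_id, 0.7, 42,
                                EvalConfig(model_ids=(model_id,),
                                           split_ratios=(0.7,), seeds=(42,)))
            assert 0.0 <= rep.metrics["auc"] <= 1.0
            assert rep.confusion.total == 8  # 0.7 split of 24 balanced
            assert len(rep.roc_points) >= 2

    def test_failing_cell_identified(self):
        X, y = toy_features(n_pos=3, n_neg=3)
        cfg = EvalConfig(model_ids=("LR",), split_ratios=(0.6,), seeds=(42,))
        with pytest.raises(RuntimeError, match="model=LR"):
            ClassifierBench(features=X, labels=y, config=cfg).fit()

    def test_unknown_model_rejected(self):
        with pytest.raises(SplitError):
            EvalConfig(model_ids=("CatBoost",)).validate()
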