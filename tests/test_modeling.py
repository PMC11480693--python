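"""Filters, splitting, elastic net, AUC metrics and the subset search."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from neuroplay.errors import DegenerateInputError
from neuroplay.modeling import (
    CvScheme,
    EvalReport,
    ModelSpec,
    PipelineConfig,
    PnpClassifier,
    binary_auc,
    correlation_filter,
    evaluate,
    fit_elastic_net_logistic,
    multiclass_auc,
    rank_importance,
    stratified_split,
    subset_search,
    univariate_filter,
    variance_filter,
)


def _toy(n=80, p=6, informative=1, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    x = rng.normal(size=(n, p))
    for j in range(informative):
        x[:, j] += 1.5 * y
    cols = [f"f{j:02d}" for j in range(p)]
    return pd.DataFrame(x, columns=cols), y


class TestFilters:
    def test_variance_filter_drops_degenerate_columns(self):
        df = pd.DataFrame({
            "const": np.ones(30),
            "binaryish": np.tile([0.0, 1.0], 15),
            "rich": np.random.default_rng(0).normal(size=30)})
        out = variance_filter(df)
        assert list(out.columns) == ["rich"]

    def test_correlation_filter_removes_one_duplicate(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=50)
        df = pd.DataFrame({"a": a, "a_copy": a.copy(),
                           "b": rng.normal(size=50)})
        out = correlation_filter(df)
        assert "b" in out.columns
        assert ("a" in out.columns) != ("a_copy" in out.columns)

    def test_threshold_is_strict(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=60)
        b = 0.5 * a + rng.normal(size=60)
        df = pd.DataFrame({"a": a, "b": b})
        r = abs(np.corrcoef(a, b)[0, 1])
        # setting the threshold to the exact observed |r| keeps both
        out = correlation_filter(df, threshold=r)
        assert list(out.columns) == ["a", "b"]

    def test_orthogonal_features_untouched_vs_brute_force(self):
        rng = np.random.default_rng(3)
        x = np.linalg.qr(rng.normal(size=(40, 5)))[0]  # orthonormal columns
        df = pd.DataFrame(x, columns=list("abcde"))
        out = correlation_filter(df)
        # brute-force pairwise scan confirms no pair above threshold
        for i in range(5):
            for j in range(i + 1, 5):
                assert abs(np.corrcoef(x[:, i], x[:, j])[0, 1]) <= 0.75
        assert list(out.columns) == list("abcde")

    def test_univariate_filter_keeps_shifted_feature(self):
        df, y = _toy(n=100, p=5, informative=1, seed=4)
        out = univariate_filter(df, y)
        assert "f00" in out.columns

    def test_univariate_filter_fallback_keeps_smallest_p(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(12, 30)),
                          columns=[f"n{j}" for j in range(30)])
        y = rng.integers(0, 2, 12)
        out = univariate_filter(df, y, alpha=1e-9, fallback_k=7)
        assert out.shape[1] == 7

    def test_constant_labels_rejected(self):
        df, _ = _toy()
        with pytest.raises(DegenerateInputError):
            univariate_filter(df, np.ones(len(df)))


class TestRanking:
    def test_informative_feature_ranked_first(self):
        df, y = _toy(n=200, p=10, informative=1, seed=6)
        assert rank_importance(df, y)[0] == "f00"

    def test_reversed_feature_ranks_by_distance_from_chance(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 200)
        df = pd.DataFrame({
            "rev": -1.5 * y + rng.normal(size=200),
            "noise": rng.normal(size=200)})
        assert rank_importance(df, y)[0] == "rev"

    def test_tie_broken_by_id_order(self):
        df = pd.DataFrame({"z_dup": [1.0, 2, 3, 4] * 5,
                           "a_dup": [1.0, 2, 3, 4] * 5})
        y = np.tile([0, 1], 10)
        order = rank_importance(df, y)
        assert order == ["a_dup", "z_dup"]


class TestSplit:
    def test_published_cohort_arithmetic(self):
        labels = np.array([1] * 118 + [0] * 55)
        tr, te = stratified_split(None, labels, 0.3, seed=1)
        assert len(tr) == 122 and len(te) == 51
        p_all = labels.mean()
        p_te = labels[te].mean()
        assert abs(p_te * len(te) - p_all * len(te)) <= 1.0

    def test_small_balanced_split(self):
        labels = np.array([0, 1] * 5)
        tr, te = stratified_split(None, labels, 0.3, seed=0)
        assert len(tr) == 7 and len(te) == 3
        assert 0 < labels[te].sum() < len(te)

    def test_deterministic_given_seed(self):
        labels = np.random.default_rng(0).integers(0, 2, 60)
        a = stratified_split(None, labels, 0.3, seed=9)
        b = stratified_split(None, labels, 0.3, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_tiny_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            stratified_split(None, np.array([0, 1, 1, 1]), 0.3, 0)

    def test_cv_folds_conserve_proportions(self):
        y = np.array([1] * 70 + [0] * 30)
        cv = CvScheme(folds=5, repeats=2, seed=0)
        for tr, va in cv.splitter().split(np.zeros((100, 1)), y):
            assert abs(y[va].sum() - 0.7 * len(va)) <= 1.0


class TestElasticNet:
    def test_unpenalized_matches_mle_oracle(self):
        df, y = _toy(n=150, p=3, informative=2, seed=8)
        fit = fit_elastic_net_logistic(df, y, alpha=0.5, lam=0.0)
        xs = (df.to_numpy() - fit.mean) / fit.scale
        ref = sm.Logit(y, sm.add_constant(xs)).fit(disp=0)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-4)
        np.testing.assert_allclose(fit.coef, ref.params[1:], atol=1e-4)

    def test_huge_penalty_zeroes_coefficients(self):
        df, y = _toy(seed=9)
        fit = fit_elastic_net_logistic(df, y, alpha=0.5, lam=1e4)
        np.testing.assert_allclose(fit.coef, 0.0, atol=1e-6)

    def test_lasso_produces_exact_zeros(self):
        df, y = _toy(n=120, p=8, informative=1, seed=10)
        fit = fit_elastic_net_logistic(df, y, alpha=1.0, lam=0.1)
        assert np.sum(fit.coef == 0.0) >= 1
        assert np.sum(np.abs(fit.coef) > 0) >= 1

    def test_non_finite_rejected(self):
        df, y = _toy()
        df.iloc[0, 0] = np.inf
        with pytest.raises(DegenerateInputError):
            fit_elastic_net_logistic(df, y, 0.5, 0.01)

    def test_spec_validation(self):
        with pytest.raises(Exception):
            ModelSpec(alpha=1.5)


class TestAuc:
    def test_matches_brute_force_concordance(self):
        rng = np.random.default_rng(11)
        scores = np.round(rng.normal(size=150), 1)  # ties on purpose
        y = rng.integers(0, 2, 150)
        pos = scores[y == 1]
        neg = scores[y == 0]
        conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert binary_auc(scores, y) == pytest.approx(
            conc / (len(pos) * len(neg)), abs=1e-12)
        assert binary_auc(scores, y) == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            binary_auc([0.2, 0.8], [1, 1])

    def test_two_class_hand_till_reduces_to_binary(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=100)
        y = rng.integers(0, 2, 100)
        scores = pd.DataFrame({0: 1 - p, 1: p})
        assert multiclass_auc(scores, y) == pytest.approx(binary_auc(p, y))

    def test_perfectly_separated_classes(self):
        y = np.repeat(["a", "b", "c", "d"], 10)
        scores = pd.DataFrame(0.0, index=range(40),
                              columns=["a", "b", "c", "d"])
        for i, c in enumerate(["a", "b", "c", "d"]):
            scores.loc[scores.index[i * 10:(i + 1) * 10], c] = 1.0
        assert multiclass_auc(scores, y) == pytest.approx(1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(13)
        y = np.repeat(["a", "b", "c", "d"], 100)
        scores = pd.DataFrame(rng.uniform(size=(400, 4)),
                              columns=["a", "b", "c", "d"])
        assert 0.45 <= multiclass_auc(scores, y) <= 0.55

    def test_absent_class_rejected(self):
        scores = pd.DataFrame({"a": [0.1, 0.9], "b": [0.9, 0.1]})
        with pytest.raises(DegenerateInputError):
            multiclass_auc(scores, ["a", "a"])


class TestEvaluate:
    @pytest.mark.parametrize("tp,fn,fp,tn,sens,spec,bal", [
        (27, 8, 4, 12, 77.1, 75.0, 76.1),
        (30, 6, 3, 12, 83.3, 80.0, 81.7)])
    def test_confusion_metric_arithmetic(self, tp, fn, fp, tn, sens, spec, bal):
        rep = EvalReport.from_confusion(tp, fn, fp, tn)
        assert rep.sensitivity == sens
        assert rep.specificity == spec
        assert rep.balanced_accuracy == bal

    def test_perfect_model(self):
        df, y = _toy(n=60, p=2, informative=2, seed=14)
        df["f00"] += 10 * y  # overwhelming separation
        fit = fit_elastic_net_logistic(df, y, 0.1, 1e-4)
        rep = evaluate(fit, df, y)
        assert rep.auc_roc == pytest.approx(1.0)
        assert rep.sensitivity == 100.0 and rep.specificity == 100.0

    def test_single_class_test_labels_rejected(self):
        df, y = _toy(seed=15)
        fit = fit_elastic_net_logistic(df, y, 0.1, 1e-3)
        with pytest.raises(DegenerateInputError):
            evaluate(fit, df, np.ones(len(df)))


class TestSubsetSearch:
    CV = CvScheme(folds=5, repeats=1, seed=0)
    GRID = dict(alphas=(0.1, 1.0), lambdas=tuple(np.logspace(-3, 0, 4)),
                max_features=6)

    def test_informative_feature_selected(self):
        df, y = _toy(n=120, p=8, informative=1, seed=16)
        ranking = rank_importance(df, y)
        res = subset_search(ranking, df, y, self.CV, **self.GRID)
        assert "f00" in res.features
        assert res.cv_auc > 0.75

    def test_all_noise_near_chance(self):
        df, y = _toy(n=120, p=8, informative=0, seed=17)
        ranking = rank_importance(df, y)
        res = subset_search(ranking, df, y, self.CV, **self.GRID)
        assert 0.3 <= res.cv_auc <= 0.7

    def test_deterministic(self):
        df, y = _toy(n=100, p=6, informative=1, seed=18)
        ranking = rank_importance(df, y)
        a = subset_search(ranking, df, y, self.CV, **self.GRID)
        b = subset_search(ranking, df, y, self.CV, **self.GRID)
        assert a.features == b.features and a.spec == b.spec

    def test_empty_ranking_rejected(self):
        df, y = _toy()
        with pytest.raises(DegenerateInputError):
            subset_search([], df, y, self.CV)


class TestPnpClassifierModel:
    def test_fit_and_summary(self):
        df, y = _toy(n=150, p=12, informative=2, seed=19)
        res = PnpClassifier(df, y, PipelineConfig.screen()).fit(seed=0)
        assert res.report.auc_roc > 0.8
        text = res.summary()
        assert "alpha" in text and "balanced accuracy" in text
        bundle = res.to_bundle()
        assert bundle["selected_features"] == res.selected_features

    def test_selection_blind_to_test_labels(self):
        """Permuting the held-out labels must not change the selected
        features (no leakage from the test partition)."""
        df, y = _toy(n=150, p=12, informative=2, seed=20)
        cfg = PipelineConfig.screen()
        split = stratified_split(None, y, cfg.test_fraction, 3)
        res1 = PnpClassifier(df, y, cfg).fit(seed=3, split=split)
        y2 = y.copy()
        rng = np.random.default_rng(0)
        y2[split[1]] = rng.permutation(y2[split[1]])
        res2 = PnpClassifier(df, y2, cfg).fit(seed=3, split=split)
        assert res1.selected_features == res2.selected_features
        assert res1.spec == res2.spec
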