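"""Splitting, the classifier bench, and exact ROC/AUC evaluation."""

import numpy as np
import pytest

from cmci.classify import (
    Scorer,
    _evaluate_scores,
    cross_validate,
    evaluate,
    stratified_split,
    train_baselines,
    train_classifier,
    train_ranking_forest,
)
from cmci.errors import DegenerateModelError, EvaluationError, StratificationError


def pairwise_auc(labels, scores, positive=1):
    """Exhaustive Mann-Whitney ordering oracle (ties count one half)."""
    pos = [s for s, y in zip(scores, labels) if y == positive]
    neg = [s for s, y in zip(scores, labels) if y != positive]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def two_gaussians(n, seed, delta=4.0, p=2):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n // 2, p)),
                   rng.normal(delta, 1, (n - n // 2, p))])
    y = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestStratifiedSplit:
    def test_thirteen_twelve_rounding(self):
        labels = np.array(["elite"] * 13 + ["expert"] * 12)
        plan = stratified_split(labels, 0.7, seed=0)
        train_labels = labels[plan.train_indices]
        assert np.sum(train_labels == "elite") == 9  # round(9.1)
        assert np.sum(train_labels == "expert") == 8  # round(8.4)
        assert plan.test_indices.size == 8

    def test_partition_disjoint_and_exhaustive(self):
        labels = np.array([0] * 13 + [1] * 12)
        plan = stratified_split(labels, 0.7, seed=3)
        union = np.union1d(plan.train_indices, plan.test_indices)
        np.testing.assert_array_equal(union, np.arange(25))
        assert np.intersect1d(plan.train_indices, plan.test_indices).size == 0

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(StratificationError):
            stratified_split([0, 0, 1, 1], 1.0, seed=0)

    def test_tiny_class_rejected(self):
        with pytest.raises(StratificationError):
            stratified_split([0, 0, 0, 1], 0.7, seed=0)

    def test_seed_determinism_and_entropy(self):
        labels = np.array([0] * 10 + [1] * 10)
        a = stratified_split(labels, 0.7, seed=5)
        b = stratified_split(labels, 0.7, seed=5)
        np.testing.assert_array_equal(a.train_indices, b.train_indices)
        distinct = sum(
            not np.array_equal(
                stratified_split(labels, 0.7, seed=s).train_indices,
                stratified_split(labels, 0.7, seed=s + 1).train_indices)
            for s in range(0, 200, 2))
        assert distinct >= 95


class TestRankingForest:
    def test_separable_feature_perfect_training_auc(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.uniform(-2, -0.5, 20), rng.uniform(0.5, 2, 20)]
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        scorer = train_ranking_forest(x[:, None], y, seed=1)
        assert evaluate(scorer, x[:, None], y).auc == 1.0

    def test_permuted_labels_give_null_auc(self):
        # test sets large enough that the null AUC sd (~0.07) keeps the
        # band probability near 1
        X, y = two_gaussians(200, seed=2, delta=3.0)
        tr, te = np.arange(0, 140), np.arange(140, 200)
        inside = 0
        for rep in range(50):
            rng = np.random.default_rng(100 + rep)
            y_perm = rng.permutation(y)
            try:
                scorer = train_ranking_forest(X[tr], y_perm[tr], seed=rep)
                auc = evaluate(scorer, X[te], y_perm[te]).auc
            except (DegenerateModelError, EvaluationError):
                continue
            inside += 0.3 <= auc <= 0.7
        assert inside >= 45

    def test_single_tree_ensemble_equals_its_tree(self):
        X, y = two_gaussians(30, seed=3)
        scorer = train_ranking_forest(X, y, n_trees=1, seed=7)
        forest = scorer.model
        tree_proba = forest.estimators_[0].predict_proba(X)
        np.testing.assert_array_equal(forest.predict_proba(X), tree_proba)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateModelError):
            train_ranking_forest(np.zeros((5, 2)), np.ones(5, int))

    def test_score_reproducible_from_seed(self):
        X, y = two_gaussians(40, seed=4)
        s1 = train_ranking_forest(X, y, seed=9).scores(X)
        s2 = train_ranking_forest(X, y, seed=9).scores(X)
        np.testing.assert_array_equal(s1, s2)


class TestBaselines:
    @pytest.mark.parametrize("which", ["naive_bayes", "logistic", "svm"])
    def test_separated_gaussians_high_auc(self, which):
        X, y = two_gaussians(100, seed=5)
        tr, te = np.arange(0, 70), np.arange(70, 100)
        scorer = train_baselines(X[tr], y[tr], which=which, seed=0)
        assert evaluate(scorer, X[te], y[te]).auc > 0.95

    def test_naive_bayes_matches_gaussian_likelihood_ratio_ranking(self):
        rng = np.random.default_rng(6)
        x = np.r_[rng.normal(0, 1, 30), rng.normal(2, 1.5, 30)]
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        scorer = train_baselines(x[:, None], y, which="naive_bayes", seed=0)
        scores = scorer.scores(x[:, None])
        # closed-form oracle on the z-scored feature with NB's estimates
        z = (x - x.mean()) / x.std()
        mu0, s0 = z[y == 0].mean(), z[y == 0].var()
        mu1, s1 = z[y == 1].mean(), z[y == 1].var()
        llr = (-0.5 * np.log(s1) - (z - mu1) ** 2 / (2 * s1)
               + 0.5 * np.log(s0) + (z - mu0) ** 2 / (2 * s0))
        assert np.array_equal(np.argsort(scores), np.argsort(llr))

    def test_logistic_separable_is_regularized_finite(self):
        x = np.r_[np.linspace(-2, -1, 20), np.linspace(1, 2, 20)]
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        scorer = train_baselines(x[:, None], y, which="logistic", seed=0)
        coef = scorer.model.named_steps["clf"].coef_
        assert np.all(np.isfinite(coef))
        assert evaluate(scorer, x[:, None], y).auc == 1.0

    def test_scaling_statistics_come_from_training_data_only(self):
        X, y = two_gaussians(60, seed=7)
        tr = np.arange(0, 40)
        scorer = train_baselines(X[tr], y[tr], which="logistic", seed=0)
        scaler = scorer.model.named_steps["scale"]
        np.testing.assert_allclose(scaler.mean_, X[tr].mean(axis=0))
        np.testing.assert_allclose(scaler.scale_, X[tr].std(axis=0))

    def test_zero_variance_feature_warns_under_nb(self):
        X = np.c_[np.ones(20), np.r_[np.zeros(10), np.ones(10)]]
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        with pytest.warns(UserWarning, match="zero-variance"):
            train_baselines(X, y, which="naive_bayes", seed=0)


class TestEvaluate:
    def _const_scorer(self, value=0.5):
        class _M:
            def decision_function(self, X):
                return np.full(len(X), value)
        return Scorer(name="const", model=_M(), positive_label=1,
                      score_kind="decision")

    def test_perfect_ranking(self):
        auc, sen, spc, roc, _ = _evaluate_scores(
            np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9]), 1)
        assert auc == 1.0 and sen == 1.0 and spc == 1.0

    def test_constant_scores_are_uninformative(self):
        auc, *_ = _evaluate_scores(np.array([0, 1, 0, 1]),
                                   np.full(4, 0.3), 1)
        assert auc == 0.5

    def test_roc_shape_and_trapezoid_consistency(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        s = rng.normal(size=100)
        auc, _, _, roc, _ = _evaluate_scores(y, s, 1)
        assert tuple(roc[0]) == (0.0, 0.0) and tuple(roc[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc[:, 0]) >= 0)
        assert np.all(np.diff(roc[:, 1]) >= 0)
        assert auc == pytest.approx(np.trapezoid(roc[:, 1], roc[:, 0]),
                                    abs=1e-12)

    @pytest.mark.parametrize("seed", range(15))
    def test_auc_equals_pairwise_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        scores = rng.normal(size=n)
        if seed % 2:
            scores = np.round(scores, 1)  # force tied scores
        auc, *_ = _evaluate_scores(y, scores, 1)
        assert auc == pairwise_auc(y, scores)

    def test_single_class_test_set_rejected(self):
        scorer = self._const_scorer()
        with pytest.raises(EvaluationError):
            evaluate(scorer, np.zeros((3, 1)), np.ones(3, int))

    def test_youden_tie_takes_lower_threshold(self):
        # J = 0 everywhere for a constant scorer; the lowest threshold wins,
        # which is the all-positive corner (sens 1, spec 0)
        scorer = self._const_scorer()
        res = evaluate(scorer, np.zeros((4, 1)), np.array([0, 1, 0, 1]))
        assert res.sensitivity == 1.0 and res.specificity == 0.0


class TestCrossValidate:
    def test_separable_data_high_mean_auc(self):
        X, y = two_gaussians(60, seed=9)
        for seed in range(3):
            res = cross_validate(X, y, classifier="logistic", k=5, seed=seed)
            assert res.cv_mean_auc >= 0.95

    def test_small_class_rejected_with_suggestion(self):
        X, y = two_gaussians(10, seed=10)
        with pytest.raises(EvaluationError, match="lower k"):
            cross_validate(X, y, classifier="logistic", k=8, seed=0)

    def test_fold_metrics_have_k_entries(self):
        X, y = two_gaussians(40, seed=11)
        res = cross_validate(X, y, classifier="naive_bayes", k=4, seed=1)
        assert len(res.cv_fold_auc) == 4
        assert len(res.cv_fold_sensitivity) == 4

    def test_dispatcher_covers_all_classifiers(self):
        X, y = two_gaussians(40, seed=12)
        for name in ("ranking_forest", "naive_bayes", "logistic", "svm"):
            scorer = train_classifier(name, X, y, seed=0)
            assert 0.0 <= evaluate(scorer, X, y).auc <= 1.0
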