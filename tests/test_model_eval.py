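"""Elastic-net fitting and Mann-Whitney AUC with confidence intervals."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from eventbank.assembly import FeatureMatrix
from eventbank.cohort import AssessmentPoint
from eventbank.model_eval import (
    DegenerateLabelsError,
    ModelConfig,
    auc_mann_whitney,
    fit_elastic_net,
    run_experiment,
)


def pair_counting_auc(scores, labels):
    """Independent oracle: exhaustive concordant-pair enumeration."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        r = auc_mann_whitney([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_all_ties_give_half(self):
        r = auc_mann_whitney([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert r.auc == 0.5

    def test_worked_example(self):
        # pos {0.9, 0.4}, neg {0.5, 0.1}: 3 of 4 pairs concordant
        r = auc_mann_whitney([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.75)
        assert (r.n_pos, r.n_neg) == (2, 2)

    def test_matches_pair_counting_and_sklearn(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(4, 200))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
            r = auc_mann_whitney(scores, labels)
            assert r.auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)
            assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        labels[0], labels[1] = 0, 1
        base = auc_mann_whitney(scores, labels).auc
        for f in (np.exp, np.tanh, lambda s: 3 * s + 7):
            assert auc_mann_whitney(f(scores), labels).auc == pytest.approx(base)

    def test_label_flip_antisymmetry(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[0], labels[1] = 0, 1
        assert auc_mann_whitney(scores, 1 - labels).auc == pytest.approx(
            1 - auc_mann_whitney(scores, labels).auc
        )

    @pytest.mark.parametrize("method", ["hanley-mcneil", "delong"])
    def test_ci_brackets_auc_within_unit_interval(self, method):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=100) + rng.integers(0, 2, 100)
        labels = rng.integers(0, 2, 100)
        labels[0], labels[1] = 0, 1
        r = auc_mann_whitney(scores, labels, ci_method=method)
        assert 0.0 <= r.ci_low <= r.auc <= r.ci_high <= 1.0
        assert r.ci_high - r.ci_low > 0

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            auc_mann_whitney([0.1, 0.2], [1, 1])


class TestElasticNet:
    def _config(self):
        return ModelConfig(Cs=(1.0,), cv_folds=3, max_iter=500, seed=0)

    def test_separating_column_gets_dominant_positive_coefficient(self):
        rng = np.random.default_rng(0)
        n = 200
        y = rng.integers(0, 2, n)
        X = rng.uniform(size=(n, 5)) * 0.3
        X[:, 2] = y * 0.9 + 0.05  # near-perfect separator in [0, 1]
        fit = fit_elastic_net(X, y, config=self._config())
        coefs = np.array([fit.coefficients[f"x{i}"] for i in range(5)])
        assert np.argmax(np.abs(coefs)) == 2 and coefs[2] > 0

    def test_uninformative_features_give_prevalence_intercept(self):
        rng = np.random.default_rng(1)
        y = np.array([1] * 60 + [0] * 140)
        X = np.zeros((200, 4))
        fit = fit_elastic_net(X, y, config=self._config())
        assert all(abs(b) < 1e-8 for b in fit.coefficients.values())
        assert fit.intercept == pytest.approx(np.log(60 / 140), abs=0.05)

    def test_strong_l1_limit_shrinks_everything_to_zero(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 150)
        X = rng.normal(size=(150, 6))
        fit = fit_elastic_net(
            X, y, config=ModelConfig(Cs=(1e-4,), cv_folds=3, max_iter=300, seed=0)
        )
        assert max(abs(b) for b in fit.coefficients.values()) < 1e-6

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 120)
        X = rng.uniform(size=(120, 8))
        a = fit_elastic_net(X, y, config=self._config())
        b = fit_elastic_net(X, y, config=self._config())
        assert a.coefficients == b.coefficients and a.intercept == b.intercept

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            fit_elastic_net(np.zeros((10, 2)), np.ones(10, dtype=int))


class TestRunExperiment:
    def _matrices(self, n=160, p=6, seed=0):
        rng = np.random.default_rng(seed)
        aps = [AssessmentPoint(f"P{i}", 1) for i in range(n)]
        y6 = rng.integers(0, 2, n)
        y12 = np.maximum(y6, rng.integers(0, 2, n))
        X = rng.uniform(size=(n, p))
        X[:, 0] = 0.7 * y6 + 0.3 * rng.uniform(size=n)
        mats = {
            name: FeatureMatrix(name, [f"{name}_c{j}" for j in range(p)], X.copy(), aps)
            for name in ("baseline_3Y", "MR")
        }
        mask = np.array([True] * (2 * n // 3) + [False] * (n - 2 * n // 3))
        return mats, {6: y6, 12: y12}, mask

    def test_one_row_per_set_and_horizon(self):
        mats, labels, mask = self._matrices()
        cfg = ModelConfig(Cs=(1.0,), cv_folds=3, max_iter=200, seed=0)
        df, fits = run_experiment(mats, labels, mask, config=cfg)
        assert len(df) == 4
        assert set(zip(df.feature_set, df.horizon_months)) == {
            ("baseline_3Y", 6), ("baseline_3Y", 12), ("MR", 6), ("MR", 12),
        }
        assert ((df.ci_low <= df.auc) & (df.auc <= df.ci_high)).all()
        assert len(fits) == 4

    def test_identical_matrices_give_identical_aucs(self):
        mats, labels, mask = self._matrices()
        mats["MR"] = FeatureMatrix(
            "MR", mats["baseline_3Y"].column_names, mats["baseline_3Y"].values,
            mats["baseline_3Y"].aps,
        )
        cfg = ModelConfig(Cs=(1.0,), cv_folds=3, max_iter=200, seed=0)
        df, _ = run_experiment(mats, labels, mask, config=cfg)
        by = df.set_index(["feature_set", "horizon_months"]).auc
        assert by["MR", 6] == by["baseline_3Y", 6]

    def test_empty_validation_cohort_rejected(self):
        mats, labels, _ = self._matrices()
        mask = np.ones(len(labels[6]), dtype=bool)
        with pytest.raises(ValueError):
            run_experiment(mats, labels, mask)
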