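import numpy as np
import pytest
from scipy import stats

from crisislda.evaluation import (confusion, cv_paired_ttest, metrics,
                                  roc_pr_curves, ttest_critical_value)


class TestConfusion:
    def test_direct_enumeration(self):
        cm = confusion([0, 0, 1], [0, 1, 1], 2)
        np.testing.assert_array_equal(cm.matrix, [[1, 1], [0, 1]])

    def test_perfect_predictions_are_diagonal(self):
        y = [0, 1, 2, 1, 0]
        cm = confusion(y, y, 3)
        assert np.all(cm.matrix == np.diag(np.diag(cm.matrix)))
        assert cm.total == 5

    def test_empty_input_gives_zero_matrix(self):
        cm = confusion([], [], 3)
        assert cm.total == 0

    def test_out_of_range_label_fatal(self):
        with pytest.raises(ValueError):
            confusion([0, 3], [0, 1], 3)

    def test_one_vs_rest_decomposition(self):
        cm = confusion([0, 0, 1, 2, 2, 2], [0, 1, 1, 2, 0, 2], 3)
        c = cm.per_class_counts()
        assert c["tp"].tolist() == [1, 1, 2]
        assert (c["tp"] + c["fp"] + c["fn"] + c["tn"]).tolist() == [6, 6, 6]


class TestMetrics:
    def test_formula_arithmetic(self):
        # class 0: TP=3, FP=1, FN=2 in a 2-class matrix
        cm = confusion([0] * 5 + [1] * 4, [0, 0, 0, 1, 1, 0, 1, 1, 1], 2)
        rep = metrics(cm)
        assert rep.per_class["precision"][0] == pytest.approx(0.75)
        assert rep.per_class["recall"][0] == pytest.approx(0.6)
        assert rep.per_class["f1"][0] == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_diagonal_matrix_is_perfect(self):
        cm = confusion([0, 1, 2], [0, 1, 2], 3)
        rep = metrics(cm)
        for key in ("precision", "recall", "f1"):
            np.testing.assert_allclose(rep.per_class[key], 1.0)
        np.testing.assert_allclose(rep.per_class["fpr"], 0.0)
        np.testing.assert_allclose(rep.per_class["specificity"], 1.0)

    def test_micro_f1_equals_accuracy_identity(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 100)
        y_pred = rng.integers(0, 4, 100)
        rep = metrics(confusion(y_true, y_pred, 4))
        assert rep.micro["f1"] == pytest.approx(rep.accuracy, abs=1e-15)

    def test_zero_division_flagged_not_crashed(self):
        cm = confusion([0, 0], [0, 0], 2)  # class 1 never predicted/true
        rep = metrics(cm)
        assert rep.per_class["precision"][1] == 0.0
        assert rep.zero_division_flags["precision"][1]

    def test_all_metrics_in_unit_interval(self):
        rng = np.random.default_rng(1)
        rep = metrics(confusion(rng.integers(0, 3, 60),
                                rng.integers(0, 3, 60), 3))
        for v in rep.per_class.values():
            assert np.all((v >= 0) & (v <= 1))
        for v in (*rep.macro.values(), *rep.micro.values(), rep.accuracy):
            assert 0 <= v <= 1


class TestCurves:
    def test_perfect_ranking_gives_auc_one(self):
        y = np.array([[1, 0], [1, 0], [0, 1], [0, 1]])
        s = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        out = roc_pr_curves(y, s)
        assert out["roc_auc"][0] == 1.0 and out["roc_auc"][1] == 1.0

    def test_binary_auc_equals_mann_whitney_pair_probability(self):
        rng = np.random.default_rng(5)
        n = 200
        labels = rng.integers(0, 2, n)
        scores = rng.random(n)
        y = np.stack([1 - labels, labels], axis=1)
        s = np.stack([1 - scores, scores], axis=1)
        out = roc_pr_curves(y, s)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert out["roc_auc"][1] == pytest.approx(wins / (len(pos) * len(neg)),
                                                  abs=1e-9)

    def test_constant_scores_give_chance_auc(self):
        y = np.array([[1, 0], [0, 1], [1, 0], [0, 1]])
        s = np.full((4, 2), 0.5)
        out = roc_pr_curves(y, s)
        assert out["roc_auc"][0] == pytest.approx(0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        y = np.eye(3)[rng.integers(0, 3, 50)]
        s = rng.random((50, 3))
        a1 = roc_pr_curves(y, s)["roc_auc"]
        a2 = roc_pr_curves(y, np.exp(3 * s))["roc_auc"]
        for k in a1:
            assert a1[k] == pytest.approx(a2[k], abs=1e-12)

    def test_absent_class_excluded_from_macro_with_flag(self):
        y = np.array([[1, 0, 0], [0, 1, 0], [1, 0, 0]])
        s = np.random.default_rng(0).random((3, 3))
        out = roc_pr_curves(y, s)
        assert out["absent_classes"] == [2]
        assert np.isnan(out["roc_auc"][2])
        assert np.isfinite(out["roc_auc"]["macro"])

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_curves(np.eye(2), np.array([[np.nan, 1], [0, 1]]))


class _MajorityModel:
    """Deterministic stand-in classifier: predicts the training majority."""

    def __init__(self, noise_seed=None):
        self.noise_seed = noise_seed

    def fit(self, X, y):
        self.label_ = np.bincount(y).argmax()
        return self

    def predict(self, X):
        return np.full(len(X), self.label_)


class _OracleModel:
    """Reads the answer directly from the feature (x mod n_classes)."""

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.asarray(X).ravel() % 3


class _RandomModel:
    def __init__(self, seed):
        self.seed = seed

    def fit(self, X, y):
        return self

    def predict(self, X):
        rng = np.random.Generator(np.random.PCG64(self.seed))
        return rng.integers(0, 3, len(X))


class TestPairedTTest:
    def test_critical_value_df5(self):
        assert ttest_critical_value(5) == pytest.approx(2.571, abs=5e-4)

    def test_model_vs_identical_copy_gives_t_zero(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 30, size=(60, 1))
        y = (X.ravel() % 3).astype(int)
        res = cv_paired_ttest(lambda s: _OracleModel(),
                              lambda s: _OracleModel(), X, y, seed=1)
        assert res.t == 0.0 and not res.reject and res.zero_variance
        assert res.df == 5
        assert res.threshold == pytest.approx(2.571, abs=5e-4)

    def test_strong_vs_random_rejects(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 30, size=(90, 1))
        y = (X.ravel() % 3).astype(int)
        n_reject = 0
        for rep in range(10):
            res = cv_paired_ttest(lambda s: _OracleModel(),
                                  lambda s: _RandomModel(s), X, y,
                                  seed=100 + rep)
            n_reject += res.reject
        assert n_reject >= 9

    def test_statistic_matches_hand_computed_formula(self):
        # freeze the per-repetition pairs and recompute Dietterich's t by hand
        res = cv_paired_ttest(lambda s: _OracleModel(),
                              lambda s: _MajorityModel(),
                              np.arange(40).reshape(-1, 1),
                              (np.arange(40) % 3).astype(int), seed=7)
        pairs = np.array(res.pairs)
        s2 = [((p1 - (p1 + p2) / 2) ** 2 + (p2 - (p1 + p2) / 2) ** 2)
              for p1, p2 in pairs]
        expected_t = pairs[0, 0] / np.sqrt(np.sum(s2) / len(pairs))
        assert res.t == pytest.approx(expected_t, abs=1e-12)
        expected_p = 2 * stats.t.sf(abs(expected_t), 5)
        assert res.p_value == pytest.approx(expected_p, abs=1e-12)
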