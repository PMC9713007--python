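"""LASSO selection, scaling, SVM cross-validation, and permutation test."""

import numpy as np
import pandas as pd
import pytest

import ridgeconn.classifier as clf_mod
from ridgeconn.classifier import (
    ClassifierConfig,
    confusion_metrics,
    cross_validate_svm,
    lasso_select,
    minmax_scale,
    permutation_test_accuracy,
    roc_area,
)

SMALL = dict(lasso_repeats=2, lasso_path_size=12)


def separable_features(rng, n=60, n_noise=8, shift=3.0):
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    X = rng.standard_normal((n, 2 + n_noise))
    X[:, 0] += shift * y
    X[:, 1] -= shift * y
    return pd.DataFrame(X, columns=[f"f{k}" for k in range(2 + n_noise)]), y


class TestConfusionMetrics:
    def test_hand_enumerated_matrix(self):
        m = confusion_metrics(tp=40, fn=6, fp=6, tn=40)
        assert m["accuracy"] == pytest.approx(100 * 80 / 92, abs=1e-9)
        assert m["accuracy"] == pytest.approx(86.96, abs=0.01)
        assert m["kappa"] == pytest.approx(73.91, abs=0.01)
        assert m["sensitivity"] == pytest.approx(100 * 40 / 46, abs=1e-9)
        assert m["specificity"] == pytest.approx(100 * 40 / 46, abs=1e-9)

    def test_degenerate_all_one_class(self):
        m = confusion_metrics(tp=10, fn=0, fp=10, tn=0)
        assert m["kappa"] == 0.0


class TestMinmaxScale:
    def test_linear_map_and_extrapolation(self):
        train = np.array([[2.0], [4.0], [6.0]])
        scaled, applied = minmax_scale(train, np.array([[8.0]]))
        assert np.allclose(scaled.ravel(), [0, 0.5, 1])
        assert applied.ravel()[0] == pytest.approx(1.5)

    def test_constant_column_maps_to_zero(self):
        train = np.full((4, 2), 3.0)
        scaled, applied = minmax_scale(train, train + 1)
        assert np.all(scaled == 0) and np.all(applied == 0)


class TestRocArea:
    def test_perfect_ordering(self):
        assert roc_area(np.array([3.0, 2.0, 1.0, 0.0]),
                        np.array([1, 1, 0, 0])) == 1.0

    def test_printed_four_score_example(self):
        assert roc_area(np.array([0.9, 0.7, 0.6, 0.4]),
                        np.array([1, 0, 1, 0])) == pytest.approx(0.75)

    def test_label_inversion_symmetry(self, rng):
        scores = rng.standard_normal(30)
        y = (rng.random(30) < 0.5).astype(int)
        if 0 < y.sum() < 30:
            assert roc_area(scores, y) == pytest.approx(1 - roc_area(scores, 1 - y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_area(np.array([1.0, 2.0]), np.array([1, 1]))


class TestLassoSelect:
    def test_informative_feature_recovered_with_few_false_positives(self):
        wins = 0
        for seed in range(10):
            r = np.random.default_rng(1000 + seed)
            y = np.array([0] * 20 + [1] * 20)
            X = r.standard_normal((40, 51))
            X[:, 0] = y + 0.1 * r.standard_normal(40)
            feats = pd.DataFrame(X, columns=[f"g{k}" for k in range(51)])
            sel = lasso_select(feats, y, ClassifierConfig(seed=seed, **SMALL))
            wins += ("g0" in sel) and (len(sel) <= 6)
        assert wins >= 9

    def test_maximum_penalty_selects_nothing(self, rng):
        feats, y = separable_features(rng)
        from ridgeconn.classifier import _fit_l1

        X = feats.to_numpy()
        Xs = (X - X.mean(0)) / X.std(0)
        model = _fit_l1(Xs, y, lam=1e3)
        assert np.all(model.coef_ == 0)

    def test_seed_determinism(self, rng):
        feats, y = separable_features(rng)
        cfg = ClassifierConfig(seed=7, **SMALL)
        assert lasso_select(feats, y, cfg) == lasso_select(feats, y, cfg)

    def test_single_class_rejected(self, rng):
        feats, _ = separable_features(rng)
        with pytest.raises(ValueError):
            lasso_select(feats, np.ones(len(feats)), ClassifierConfig(**SMALL))


class TestCrossValidateSVM:
    def test_separable_cohort_near_perfect(self, rng):
        feats, y = separable_features(rng)
        cfg = ClassifierConfig(n_repeats=5, selection_mode="paper", seed=1, **SMALL)
        rep = cross_validate_svm(feats, y, cfg, positive_label=1)
        assert rep.accuracy_mean >= 90
        assert rep.roc_auc_mean >= 97
        assert rep.accuracy_sd >= 0

    def test_null_features_at_chance(self, rng):
        y = np.array([0] * 30 + [1] * 30)
        feats = pd.DataFrame(rng.standard_normal((60, 10)),
                             columns=[f"f{k}" for k in range(10)])
        cfg = ClassifierConfig(n_repeats=5, selection_mode="paper", seed=2, **SMALL)
        rep = cross_validate_svm(feats, y, cfg, positive_label=1)
        assert 35 <= rep.accuracy_mean <= 65

    def test_fold_confusion_counts_sum_to_fold_sizes(self, rng):
        feats, y = separable_features(rng, n=40)
        cfg = ClassifierConfig(n_repeats=2, selection_mode="paper", seed=3, **SMALL)
        rep = cross_validate_svm(feats, y, cfg, positive_label=1)
        for fm in rep.folds:
            assert fm.tp + fm.fn + fm.fp + fm.tn == 8  # 40 subjects / 5 folds

    def test_nested_selection_never_sees_test_rows(self, rng, monkeypatch):
        feats, y = separable_features(rng, n=40)
        n_total = len(feats)
        calls = []
        original = clf_mod.lasso_select

        def recording(f, labels, cfg=None, seed=None):
            calls.append(len(f))
            return original(f, labels, cfg, seed)

        monkeypatch.setattr(clf_mod, "lasso_select", recording)
        cfg = ClassifierConfig(n_repeats=1, selection_mode="nested", seed=4, **SMALL)
        clf_mod.cross_validate_svm(feats, y, cfg, positive_label=1)
        assert len(calls) == 5
        assert all(c == n_total - n_total // 5 for c in calls)

    def test_paper_mode_at_least_as_accurate_as_nested(self):
        # selection on the full data leaks test information, so across
        # seeds it should not underperform honest nested selection
        paper_acc, nested_acc = [], []
        for seed in range(10):
            r = np.random.default_rng(2000 + seed)
            y = np.array([0] * 20 + [1] * 20)
            X = r.standard_normal((40, 30))
            X[:, 0] += 1.2 * y  # weak signal among many noise features
            feats = pd.DataFrame(X, columns=[f"f{k}" for k in range(30)])
            for mode, bucket in (("paper", paper_acc), ("nested", nested_acc)):
                cfg = ClassifierConfig(n_repeats=1, selection_mode=mode,
                                       seed=seed, **SMALL)
                rep = cross_validate_svm(feats, y, cfg, positive_label=1)
                bucket.append(rep.accuracy_mean)
        assert np.mean(paper_acc) >= np.mean(nested_acc)


class TestPermutationTest:
    def test_separable_data_minimum_p(self, rng):
        feats, y = separable_features(rng)
        cfg = ClassifierConfig(n_repeats=2, n_perm=100, selection_mode="paper",
                               seed=5, **SMALL)
        p = permutation_test_accuracy(feats, y, cfg, positive_label=1)
        assert p <= 0.02
        assert p == pytest.approx(1 / 101, abs=1e-12)

    def test_invariant_to_subject_ordering(self, rng):
        feats, y = separable_features(rng, n=30)
        cfg = ClassifierConfig(n_repeats=1, n_perm=30, selection_mode="paper",
                               seed=6, **SMALL)
        p1 = permutation_test_accuracy(feats, y, cfg, positive_label=1)
        perm = rng.permutation(len(y))
        p2 = permutation_test_accuracy(feats.iloc[perm].reset_index(drop=True),
                                       y[perm], cfg, positive_label=1)
        assert abs(p1 - p2) < 0.2  # same distribution, Monte-Carlo jitter
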