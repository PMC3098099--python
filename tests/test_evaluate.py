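import numpy as np
import pytest

from duonorm.evaluate import (
    NearestShrunkenCentroid,
    bootstrap632,
    nsc_select_threshold,
    roc_from_pvalues,
    summarise_runs,
)

from oracles import pair_count_auc


class TestROC:
    def test_perfect_separation(self):
        p = np.array([0.001, 0.002, 0.9, 0.95])
        truth = np.array([1, 1, 0, 0])
        _, _, auc = roc_from_pvalues(p, truth)
        assert auc == 1.0

    def test_worked_six_probe_case(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05, 0.06])
        truth = np.array([1, 0, 1, 0, 1, 0])
        _, _, auc = roc_from_pvalues(p, truth)
        assert auc == pytest.approx(2.0 / 3.0)
        assert auc == pytest.approx(pair_count_auc(p, truth))

    def test_chance_level_when_independent(self, rng):
        p = rng.uniform(size=10_000)
        truth = rng.uniform(size=10_000) < 0.3
        _, _, auc = roc_from_pvalues(p, truth)
        assert abs(auc - 0.5) < 0.02

    def test_matches_pair_count_oracle_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 40))
            p = rng.choice([0.01, 0.05, 0.2, 0.5, 0.8], size=n)
            truth = rng.uniform(size=n) < 0.5
            if truth.all() or not truth.any():
                continue
            _, _, auc = roc_from_pvalues(p, truth)
            assert auc == pytest.approx(pair_count_auc(p, truth), abs=1e-12)

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError):
            roc_from_pvalues(np.array([0.1, 0.2]), np.array([1, 1]))


class TestSummariseRuns:
    def test_identical_runs_zero_width(self):
        fpr = np.array([0.0, 0.5, 1.0])
        tpr = np.array([0.0, 0.8, 1.0])
        summ = summarise_runs([(fpr, tpr)] * 12, [0.9] * 12)
        assert summ.ci_low == summ.ci_high == 0.9
        np.testing.assert_allclose(
            summ.median_sensitivity,
            np.interp(1.0 - summ.specificity_grid, fpr, tpr),
        )

    def test_percentile_ci(self):
        summ = summarise_runs(
            [(np.array([0.0, 1.0]), np.array([0.0, 1.0]))] * 3,
            [0.4, 0.5, 0.6] * 1,
        )
        # only 3 runs: CI suppressed
        assert summ.ci_low is None
        aucs = np.repeat([0.4, 0.5, 0.6], 4)
        summ = summarise_runs(
            [(np.array([0.0, 1.0]), np.array([0.0, 1.0]))] * 12, aucs
        )
        lo, hi = np.percentile([0.4, 0.5, 0.6], [2.5, 97.5])
        assert np.percentile([0.4, 0.5, 0.6], 2.5) == pytest.approx(0.405)
        assert summ.median_auc == 0.5

    def test_median_curve_monotone(self, rng):
        curves = []
        for _ in range(15):
            fpr = np.sort(np.r_[0.0, rng.uniform(size=20), 1.0])
            tpr = np.sort(np.r_[0.0, rng.uniform(size=20), 1.0])
            curves.append((fpr, tpr))
        summ = summarise_runs(curves, rng.uniform(size=15))
        # nondecreasing in 1 - specificity
        assert np.all(np.diff(summ.median_sensitivity[::-1]) >= -1e-12)


def _two_class_data(rng, n_per=20, n_feat=500, n_info=10, sep=1.5):
    X = rng.normal(0, 1, (2 * n_per, n_feat))
    X[n_per:, :n_info] += sep
    y = np.array(["a"] * n_per + ["b"] * n_per)
    return X, y


class TestNSC:
    def test_zero_threshold_is_nearest_centroid(self, rng):
        X, y = _two_class_data(rng)
        clf = NearestShrunkenCentroid(threshold=0.0).fit(X, y)
        assert clf.retained_.all()
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_total_shrinkage_falls_back_to_priors(self, rng):
        X = rng.normal(0, 1, (30, 50))
        y = np.array(["a"] * 20 + ["b"] * 10)
        clf = NearestShrunkenCentroid(threshold=1e6).fit(X, y)
        assert clf.n_retained_ == 0
        assert np.all(clf.predict(rng.normal(0, 1, (10, 50))) == "a")

    def test_negative_threshold_rejected(self, rng):
        X, y = _two_class_data(rng)
        with pytest.raises(ValueError, match="threshold"):
            NearestShrunkenCentroid(threshold=-1.0).fit(X, y)

    def test_informative_features_survive_cv_threshold(self, rng):
        X, y = _two_class_data(rng, n_per=25, n_feat=500, n_info=10, sep=1.2)
        thr, _, _ = nsc_select_threshold(X, y, seed=0)
        clf = NearestShrunkenCentroid(threshold=thr).fit(X, y)
        assert clf.retained_[:10].sum() >= 8
        # informative features should dominate the retained set
        assert clf.retained_[:10].sum() >= 0.1 * clf.n_retained_

    def test_threshold_selection_prefers_parsimony(self, rng):
        X, y = _two_class_data(rng, n_per=15, sep=3.0)
        thr, grid, errors = nsc_select_threshold(X, y, seed=1)
        zero_err = grid[errors <= errors.min() + 1e-12]
        assert thr == zero_err.max()

    def test_fold_reduction_warns(self, rng):
        X, y = _two_class_data(rng, n_per=5)
        with pytest.warns(UserWarning, match="reducing folds"):
            nsc_select_threshold(X, y, n_folds=10, seed=0)

    def test_deterministic_given_seed(self, rng):
        X, y = _two_class_data(rng)
        t1, _, e1 = nsc_select_threshold(X, y, seed=42)
        t2, _, e2 = nsc_select_threshold(X, y, seed=42)
        assert t1 == t2
        np.testing.assert_array_equal(e1, e2)


class TestBootstrap632:
    def test_separable_data_low_error(self, rng):
        X, y = _two_class_data(rng, n_per=12, n_feat=100, n_info=10, sep=3.0)
        res = bootstrap632(X, y, n_boot=20, seed=0)
        assert res.estimate < 0.05

    def test_null_labels_near_half(self, rng):
        # moderate n/p so the apparent-error optimism of .632 stays small
        X = rng.normal(0, 1, (60, 10))
        y = np.array(["a", "b"] * 30)
        res = bootstrap632(X, y, n_boot=30, seed=1)
        assert abs(res.estimate - 0.5) < 0.15
        assert abs(res.oob_errors.mean() - 0.5) < 0.15

    def test_convex_combination(self, rng):
        X, y = _two_class_data(rng, n_per=10, n_feat=80, sep=0.8)
        res = bootstrap632(X, y, n_boot=15, seed=2)
        expected = 0.368 * res.apparent_error + 0.632 * res.oob_errors.mean()
        assert res.estimate == pytest.approx(expected, abs=1e-12)
        lo = min(res.apparent_error, res.oob_errors.mean())
        hi = max(res.apparent_error, res.oob_errors.mean())
        assert lo - 1e-12 <= res.estimate <= hi + 1e-12

    def test_deterministic(self, rng):
        X, y = _two_class_data(rng, n_per=8, n_feat=60)
        a = bootstrap632(X, y, n_boot=10, seed=3)
        b = bootstrap632(X, y, n_boot=10, seed=3)
        assert a.estimate == b.estimate
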