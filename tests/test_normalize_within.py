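import numpy as np
import pytest

from duonorm.arraydata import compute_ma
from duonorm.normalize_within import (
    MANormalizer,
    RankInvariantParams,
    normalise_gl,
    normalise_invmod,
    normalise_invtseng,
    normalise_none,
    normalise_rdwgl,
    rank_difference_weights,
)

from conftest import make_array


def _selfself_with_bias(rng, n=600, bias_fn=None, noise=0.08):
    a = rng.normal(10.0, 1.8, n)
    bias = np.zeros(n) if bias_fn is None else bias_fn(a)
    m = bias + rng.normal(0.0, noise, n)
    return make_array(2.0 ** (a + m / 2), 2.0 ** (a - m / 2))


class TestGlobalLoess:
    def test_removes_dye_bias(self, biased_selfself):
        arr, a, bias = biased_selfself
        out, _ = normalise_gl(arr)
        assert np.mean(np.abs(out.m)) < np.mean(np.abs(arr.m))
        assert abs(np.average(out.m, weights=arr.weight)) < 1e-6

    def test_near_idempotent(self, biased_selfself):
        arr, _, _ = biased_selfself
        once, _ = normalise_gl(arr)
        twice, _ = normalise_gl(once)
        first_change = np.mean(np.abs(once.m - arr.m))
        second_change = np.mean(np.abs(twice.m - once.m))
        assert second_change < 0.02 and second_change < first_change / 5

    def test_location_equivariance(self, biased_selfself):
        arr, _, _ = biased_selfself
        shifted = arr.copy()
        shifted.m = arr.m + 1.0
        out, _ = normalise_gl(arr)
        out_shifted, _ = normalise_gl(shifted)
        np.testing.assert_allclose(out_shifted.m, out.m, atol=1e-9)


class TestInvTsengNormalise:
    def test_all_selected_equals_gl(self, rng):
        arr = _selfself_with_bias(rng, n=300)
        # decouple the channel maxima so no probe sits at average rank G
        # (the strict upper bound of the initial selection)
        arr.cy5[0] = arr.cy5.max() * 2
        arr.cy3[1] = arr.cy3.max() * 2
        arr = compute_ma(arr)
        params = RankInvariantParams(d=1e9, l=0, p=0.9999)
        out_t, _, sel = normalise_invtseng(arr, params)
        assert sel.selected.sum() == 300
        out_g, _ = normalise_gl(arr)
        np.testing.assert_allclose(out_t.m, out_g.m, atol=1e-8)

    def test_linear_bias_extrapolated(self, rng):
        # selection misses the intensity extremes; the linear tails must
        # still normalise them when the true bias is linear
        n = 500
        a = rng.uniform(6, 14, n)
        m = 0.1 * (a - 10.0) + rng.normal(0, 0.03, n)
        arr = make_array(2.0 ** (a + m / 2), 2.0 ** (a - m / 2))
        out, fit, sel = normalise_invtseng(
            arr, RankInvariantParams(d=100, l=50, p=0.6))
        sel_a = arr.a[sel.selected]
        extreme = (arr.a < sel_a.min()) | (arr.a > sel_a.max())
        if extreme.any():
            assert np.mean(np.abs(out.m[extreme])) < 0.08
        assert np.mean(np.abs(out.m[~extreme])) < 0.05


class TestInvModNormalise:
    def test_removes_nonlinear_bias(self, rng):
        arr = _selfself_with_bias(rng, bias_fn=lambda a: 0.5 * np.sin(a / 2))
        out, fit, sel = normalise_invmod(arr)
        from duonorm._loess import WeightedLoess

        resid_fit = WeightedLoess(span=0.4).fit(out.a, out.m)
        lo, hi = np.quantile(out.a, [0.05, 0.95])
        grid = np.linspace(lo, hi, 50)
        assert np.max(np.abs(resid_fit.predict(grid))) < 0.05

    def test_robust_to_asymmetric_upregulation(self, rng):
        # strong one-sided regulation drags the global curve but not the
        # rank-invariant one
        n = 800
        a = rng.normal(10, 1.8, n)
        de = np.zeros(n, dtype=bool)
        de[rng.choice(n, int(0.4 * n), replace=False)] = True
        shift = np.abs(rng.normal(0.3, 0.1, n)) * de
        m = shift + rng.normal(0, 0.08, n)
        arr = make_array(2.0 ** (a + m / 2), 2.0 ** (a - m / 2))
        out_mod, _, _ = normalise_invmod(arr)
        out_gl, _ = normalise_gl(arr)
        assert abs(np.mean(out_mod.m[~de])) < 0.05
        assert np.mean(out_gl.m[~de]) < -0.05

    def test_nothing_to_correct(self, rng):
        arr = _selfself_with_bias(rng, noise=0.08)
        out, _, _ = normalise_invmod(arr)
        assert np.mean(np.abs(out.m - arr.m)) < 0.05

    def test_selected_support_spans_range(self, rng):
        arr = _selfself_with_bias(rng, n=800)
        _, _, sel = normalise_invmod(arr)
        sel_a = arr.a[sel.selected]
        assert np.quantile(arr.a, 0.02) > sel_a.min() - 0.5
        assert np.quantile(arr.a, 0.98) < sel_a.max() + 0.5


class TestRDWGL:
    def test_equal_deltas_give_gl(self, rng):
        # exact self-self: all rank differences zero -> uniform weights
        a = rng.normal(10, 1.5, 300)
        cy5 = 2.0**a
        arr = make_array(cy5, cy5.copy())
        w = rank_difference_weights(arr)
        np.testing.assert_array_equal(w, np.ones(300))
        out_r, _ = normalise_rdwgl(arr)
        out_g, _ = normalise_gl(arr)
        np.testing.assert_allclose(out_r.m, out_g.m, atol=1e-10)

    def test_max_delta_probe_weight_zero(self, rng):
        arr = _selfself_with_bias(rng, n=200)
        w = rank_difference_weights(arr)
        from scipy.stats import rankdata

        delta = np.abs(rankdata(arr.cy5) - rankdata(arr.cy3))
        assert w[np.argmax(delta)] == 0.0


class TestNN:
    def test_identity_and_provenance(self, rng):
        arr = _selfself_with_bias(rng, n=100)
        out = normalise_none(arr)
        np.testing.assert_array_equal(out.m, arr.m)
        assert out.provenance["method"] == "NN"
        again = normalise_none(out)
        np.testing.assert_array_equal(again.m, arr.m)


class TestMethodAgreement:
    def test_pure_noise_all_methods_agree(self, rng):
        arr = _selfself_with_bias(rng, n=700, noise=0.1)
        results = {
            "gl": normalise_gl(arr)[0].m,
            "invtseng": normalise_invtseng(
                arr, RankInvariantParams(d=200, l=25, p=0.3))[0].m,
            "invmod": normalise_invmod(arr)[0].m,
            "rdwgl": normalise_rdwgl(arr)[0].m,
        }
        keys = list(results)
        for i, k1 in enumerate(keys):
            for k2 in keys[i + 1:]:
                both = np.isfinite(results[k1]) & np.isfinite(results[k2])
                assert np.mean(np.abs(results[k1][both] - results[k2][both])) < 0.05

    def test_residual_weighted_mean_zero_every_method(self, biased_selfself):
        arr, _, _ = biased_selfself
        for out, fit in [
            normalise_gl(arr),
            normalise_invtseng(arr, RankInvariantParams(d=200, l=25, p=0.3))[:2],
            normalise_invmod(arr)[:2],
            normalise_rdwgl(arr),
        ]:
            w = fit.weights_used
            ok = (w > 0) & np.isfinite(out.m)
            assert abs(np.average(out.m[ok], weights=w[ok])) < 1e-6


class TestMANormalizer:
    def test_sklearn_interface(self, rng):
        arr = _selfself_with_bias(rng, n=300, bias_fn=lambda a: 0.2 * (a - 10))
        X = np.column_stack([arr.cy5, arr.cy3])
        tf = MANormalizer(method="invmod")
        out = tf.fit_transform(X)
        assert out.shape == (300, 2)
        np.testing.assert_allclose(out[:, 0], arr.a, atol=1e-9)
        assert np.nanmean(np.abs(out[:, 1])) < np.nanmean(np.abs(arr.m))
        assert tf.selection_ is not None and tf.loess_ is not None
        params = tf.get_params()
        assert params["method"] == "invmod"
        from sklearn.base import clone

        clone(tf)  # must be cloneable for model selection

    def test_unknown_method_rejected(self, rng):
        X = np.ones((40, 2))
        with pytest.raises(ValueError, match="available"):
            MANormalizer(method="bogus").fit(X)
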