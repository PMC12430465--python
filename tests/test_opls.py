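import numpy as np
import pytest

from roplsda import (
    OPLSDA, cross_validate, fit_oplsda, permutation_test, s_plot,
    select_markers, vip_scores,
)
from .conftest import pls1_oracle


class TestFit:
    def test_perfect_single_feature_predictor(self):
        y = np.array(["a"] * 5 + ["b"] * 5)
        X = np.where(y == "b", 1.0, -1.0).reshape(-1, 1)
        m = fit_oplsda(X, y, n_ortho=0, scale="center")
        assert m.r2y_ == pytest.approx(1.0, abs=1e-10)
        corr = np.corrcoef(m.t_, np.where(y == "b", 1.0, -1.0))[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-10)

    def test_reduces_to_pls1_oracle_without_orthogonal_components(self, rng):
        X = rng.normal(size=(40, 10))
        y = np.array(["a"] * 20 + ["b"] * 20)
        m = fit_oplsda(X, y, n_ortho=0, scale="center")
        w_ref, t_ref = pls1_oracle(X, np.where(y == "b", 1.0, -1.0))
        sign = np.sign(w_ref @ m.w_)
        np.testing.assert_allclose(m.w_, sign * w_ref, atol=1e-8)
        np.testing.assert_allclose(m.t_, sign * t_ref, atol=1e-8)

    def test_orthogonal_filtering_beats_pls1_on_structured_confounder(self, rng):
        # X = t p' + t_o p_o' with t orthogonal to t_o and y = sign(t):
        # removing one orthogonal component must not hurt the t/y correlation
        n, d = 40, 10
        t = np.linspace(-1, 1, n)
        t_o = np.cos(np.linspace(0, 6 * np.pi, n))
        t_o -= t_o @ t / (t @ t) * t
        p = rng.normal(size=d)
        p_o = rng.normal(size=d)
        X = np.outer(t, p) + 3.0 * np.outer(t_o, p_o) + 0.01 * rng.normal(size=(n, d))
        y = np.where(t > 0, "hi", "lo")
        yc = np.where(y == "hi", 1.0, -1.0)

        m1 = fit_oplsda(X, y, n_ortho=1, scale="center")
        _, t_pls1 = pls1_oracle(X, yc)
        corr_opls = abs(np.corrcoef(m1.t_, yc)[0, 1])
        corr_pls1 = abs(np.corrcoef(t_pls1, yc)[0, 1])
        assert corr_opls >= corr_pls1 - 1e-12
        assert m1.n_ortho_ == 1

    def test_weights_unit_norm_and_orthogonality(self, two_blob_data):
        X, y = two_blob_data
        m = fit_oplsda(X, y, n_ortho=2, scale="pareto")
        assert np.linalg.norm(m.w_) == pytest.approx(1.0, abs=1e-10)
        for a in range(m.n_ortho_):
            assert np.linalg.norm(m.W_o_[:, a]) == pytest.approx(1.0, abs=1e-10)
            assert abs(m.w_ @ m.W_o_[:, a]) < 1e-8
            assert abs(m.t_ @ m.T_o_[:, a]) < 1e-6

    def test_sample_permutation_equivariance(self, two_blob_data, rng):
        X, y = two_blob_data
        perm = rng.permutation(len(y))
        m = fit_oplsda(X, y, n_ortho=1, scale="center")
        mp = fit_oplsda(X[perm], y[perm], n_ortho=1, scale="center")
        np.testing.assert_allclose(mp.t_, m.t_[perm], atol=1e-8)
        assert mp.r2y_ == pytest.approx(m.r2y_, abs=1e-10)

    def test_class_coding_swap_negates_scores(self, two_blob_data):
        X, y = two_blob_data
        m_ab = fit_oplsda(X, y, n_ortho=0, scale="center")
        y_swapped = np.where(y == "a", "z", "a")  # reverses the sorted coding
        m_ba = fit_oplsda(X, y_swapped, n_ortho=0, scale="center")
        np.testing.assert_allclose(m_ba.t_, -m_ab.t_, atol=1e-8)
        np.testing.assert_allclose(m_ba.w_, -m_ab.w_, atol=1e-8)
        assert m_ba.r2y_ == pytest.approx(m_ab.r2y_, abs=1e-10)
        np.testing.assert_allclose(vip_scores(m_ba), vip_scores(m_ab), atol=1e-10)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="2 classes"):
            fit_oplsda(X, ["a"] * 10)

    def test_excess_n_ortho_truncates_with_warning(self):
        y = np.array(["a"] * 4 + ["b"] * 4)
        X = np.column_stack([np.where(y == "b", 1.0, -1.0)] * 2)  # rank 1
        with pytest.warns(UserWarning, match="rank|uncorrelated"):
            m = fit_oplsda(X, y, n_ortho=4, scale="center")
        assert m.n_ortho_ < 4

    def test_predict_recovers_training_labels_when_separable(self, two_blob_data):
        X, y = two_blob_data
        m = OPLSDA(n_ortho=1, scale="pareto").fit(X, y)
        assert (m.predict(X) == y).all()

    def test_deflation_strictly_reduces_x_norm(self, rng):
        X = rng.normal(size=(30, 8))
        y = np.array(["a"] * 15 + ["b"] * 15)
        Xc = X - X.mean(0)
        norms = []
        for k in range(0, 4):
            w, t, p, c, W_o, T_o, P_o, got = OPLSDA._decompose(
                Xc, np.where(y == "b", 1.0, -1.0) - 0.0, k)
            resid = Xc.copy()
            for a in range(got):
                resid -= np.outer(T_o[:, a], P_o[:, a])
            norms.append(np.linalg.norm(resid))
        assert all(n2 < n1 + 1e-12 for n1, n2 in zip(norms, norms[1:]))


class TestCrossValidation:
    def test_q2_high_for_separable_blobs(self, two_blob_data):
        X, y = two_blob_data
        q2 = cross_validate(X, y, n_folds=10, n_ortho=1, random_state=0)
        assert q2 > 0.9

    def test_q2_nonpositive_for_pure_noise_on_average(self, rng):
        vals = []
        y = np.array(["a"] * 20 + ["b"] * 20)
        for s in range(50):
            X = rng.normal(size=(40, 10))
            vals.append(cross_validate(X, y, n_folds=5, n_ortho=0, random_state=s))
        assert np.mean(vals) < 0.1

    def test_constant_x_gives_nonpositive_q2(self):
        X = np.ones((20, 4))
        y = ["a"] * 10 + ["b"] * 10
        assert cross_validate(X, y, n_folds=5, n_ortho=0, scale="center") <= 1e-9

    def test_refuses_infeasible_stratification(self, rng):
        X = rng.normal(size=(6, 3))
        y = ["a", "a", "b", "b", "b", "b"]  # smaller class of 2 -> < 3 folds
        with pytest.raises(ValueError, match="folds"):
            cross_validate(X, y, n_folds=10, n_ortho=0)


class TestPermutationTest:
    def test_add_one_rule_and_determinism(self, two_blob_data):
        X, y = two_blob_data
        rep = permutation_test(X, y, n_perm=99, seed=3, n_ortho=1)
        assert rep.p_perm == pytest.approx(1 / 100)  # separable: no perm wins
        rep2 = permutation_test(X, y, n_perm=99, seed=3, n_ortho=1)
        assert rep2.p_perm == rep.p_perm and rep2.q2 == rep.q2

    def test_p_never_zero(self, rng):
        X = rng.normal(size=(20, 5))
        y = ["a"] * 10 + ["b"] * 10
        rep = permutation_test(X, y, n_perm=19, seed=0, n_ortho=0)
        assert rep.p_perm >= 1 / 20

    def test_rejects_too_few_permutations(self, two_blob_data):
        X, y = two_blob_data
        with pytest.raises(ValueError, match="19"):
            permutation_test(X, y, n_perm=5, seed=0)


class TestVipAndSplot:
    def test_single_feature_vip_is_one(self):
        y = np.array(["a"] * 5 + ["b"] * 5)
        X = np.where(y == "b", 2.0, 0.0).reshape(-1, 1)
        m = fit_oplsda(X, y, n_ortho=0, scale="center")
        assert vip_scores(m)[0] == pytest.approx(1.0, abs=1e-10)

    def test_mean_squared_vip_is_one(self, rng):
        for d in (3, 17, 50):
            X = rng.normal(size=(30, d))
            y = ["a"] * 15 + ["b"] * 15
            m = fit_oplsda(X, y, n_ortho=1, scale="pareto")
            assert (vip_scores(m) ** 2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_informative_feature_outranks_noise(self, rng):
        y = np.array(["a"] * 25 + ["b"] * 25)
        X = np.column_stack([
            np.where(y == "b", 1.0, -1.0) + 0.2 * rng.normal(size=50),
            rng.normal(size=50),
        ])
        m = fit_oplsda(X, y, n_ortho=0, scale="center")
        v = vip_scores(m)
        assert v[0] > 1 > v[1]

    def test_splot_feature_equal_to_scores(self, rng):
        y = np.array(["a"] * 15 + ["b"] * 15)
        base = np.where(y == "b", 1.0, -1.0) + 0.1 * rng.normal(size=30)
        X = np.column_stack([base, rng.normal(size=30)])
        m = fit_oplsda(X, y, n_ortho=0, scale="none")
        cov, corr = s_plot(m, X)
        t = m.t_
        # feature 0 is (up to centering) proportional to t
        assert abs(corr[0]) > 0.99
        assert cov[0] == pytest.approx(np.cov(t, X[:, 0])[0, 1], rel=1e-6)

    def test_splot_negating_feature_negates_coordinates(self, two_blob_data):
        X, y = two_blob_data
        m = fit_oplsda(X, y, n_ortho=0, scale="center")
        Xneg = X.copy()
        Xneg[:, 4] *= -1
        m2 = fit_oplsda(Xneg, y, n_ortho=0, scale="center")
        cov1, corr1 = s_plot(m, X)
        cov2, corr2 = s_plot(m2, Xneg)
        assert corr2[4] == pytest.approx(-corr1[4], abs=1e-8)

    def test_splot_noise_correlations_small(self, rng):
        n = 200
        y = np.array(["a"] * 100 + ["b"] * 100)
        X = np.column_stack([np.where(y == "b", 1.0, -1.0)[:, None] + 0.0,
                             rng.normal(size=(n, 100))])
        m = fit_oplsda(X, y, n_ortho=0, scale="center")
        _, corr = s_plot(m, X)
        assert np.mean(np.abs(corr[1:])) < 3 / np.sqrt(n)

    def test_zero_variance_feature_corr_zero(self):
        y = np.array(["a"] * 6 + ["b"] * 6)
        X = np.column_stack([np.where(y == "b", 1.0, 0.0), np.full(12, 7.0)])
        m = fit_oplsda(X, y, n_ortho=0, scale="center")
        _, corr = s_plot(m, X)
        assert corr[1] == 0.0


class TestSelectMarkers:
    def test_strict_thresholds_and_sorting(self):
        ids = ["f1", "f2", "f3"]
        vips = [1.0, 2.0, 1.5]
        ps = [0.01, 0.049, 1.0]
        coords = ([0.0] * 3, [0.0] * 3)
        dstats = ([0.0] * 3, ["negligible"] * 3)
        recs = select_markers(ids, vips, ps, coords, dstats)
        assert [r.feature_id for r in recs] == ["f2", "f3", "f1"]
        flags = {r.feature_id: r.significant for r in recs}
        assert flags == {"f1": False, "f2": True, "f3": False}

    def test_all_p_one_yields_empty_significant_set(self):
        recs = select_markers(["a", "b"], [3.0, 4.0], [1.0, 1.0],
                              ([0, 0], [0, 0]), ([0, 0], ["negligible"] * 2))
        assert not any(r.significant for r in recs)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            select_markers(["a"], [1.0, 2.0], [0.5], ([0], [0]), ([0], ["negligible"]))
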