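"""Normalisation, control regression, change statistic and module scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tfscreen import embed_change as ec


class TestNormalize:
    def test_values_and_zero(self):
        counts = np.array([[100, 9900, 0]])
        X, zero = ec.normalize_log1p(counts)
        assert X[0, 0] == pytest.approx(np.log(101))
        assert X[0, 2] == 0.0
        assert not zero.any()

    def test_scaling_invariance(self):
        rng = np.random.default_rng(0)
        c = rng.integers(0, 50, size=(1, 30))
        a, _ = ec.normalize_log1p(c)
        b, _ = ec.normalize_log1p(2 * c)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_all_zero_cell_flagged(self):
        X, zero = ec.normalize_log1p(np.zeros((2, 5)))
        assert zero.all()


class TestControlRegression:
    def test_control_cell_in_subspace_has_zero_residual(self):
        rng = np.random.default_rng(1)
        basis = rng.normal(size=(2, 20))
        ctrl = rng.normal(size=(30, 2)) @ basis
        X = np.vstack([ctrl, ctrl[:1] + 0.5 * basis[0]])
        is_ctrl = np.array([True] * 30 + [False])
        batch = np.zeros(31, dtype=int)
        res = ec.regress_control_heterogeneity(X, is_ctrl, batch, k_ctrl=2)
        np.testing.assert_allclose(res[:30], 0, atol=1e-10)
        np.testing.assert_allclose(res[30], 0, atol=1e-10)  # also in subspace

    def test_orthogonal_tf_signal_untouched(self):
        # controls vary along the first 2 axes; the TF cell along axis 5
        n_genes = 10
        ctrl = np.zeros((25, n_genes))
        rng = np.random.default_rng(2)
        ctrl[:, :2] = rng.normal(size=(25, 2))
        ctrl -= ctrl.mean(axis=0)
        tf_cell = np.zeros((1, n_genes))
        tf_cell[0, 5] = 3.0
        X = np.vstack([ctrl, tf_cell])
        is_ctrl = np.array([True] * 25 + [False])
        res = ec.regress_control_heterogeneity(X, is_ctrl, np.zeros(26), k_ctrl=2)
        assert res[25, 5] == pytest.approx(3.0, abs=1e-10)

    def test_full_rank_projection_zeroes_controls(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 8))
        is_ctrl = np.ones(15, bool)
        res = ec.regress_control_heterogeneity(X, is_ctrl, np.zeros(15),
                                               k_ctrl=14, min_controls=2)
        np.testing.assert_allclose(res, 0, atol=1e-10)


class TestIntegration:
    def test_single_batch_reduces_to_plain_pca(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 12))
        emb = ec.integrate_batches(X, np.zeros(40), n_pcs=5)
        Xc = X - X.mean(axis=0)
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        np.testing.assert_allclose(np.abs(emb.scores),
                                   np.abs(u[:, :5] * s[:5]), atol=1e-8)
        # orthonormal loadings, scores reproduce the centred data projection
        np.testing.assert_allclose(emb.loadings.T @ emb.loadings,
                                   np.eye(5), atol=1e-10)
        np.testing.assert_allclose(emb.scores, Xc @ emb.loadings, atol=1e-8)

    def test_identical_batches_identical_embeddings(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(25, 10))
        X = np.vstack([A, A])
        batch = np.array([0] * 25 + [1] * 25)
        emb = ec.integrate_batches(X, batch, n_pcs=4)
        np.testing.assert_allclose(emb.scores[:25], emb.scores[25:], atol=1e-8)

    def test_n_pcs_capped_at_rank_bound(self):
        X = np.random.default_rng(6).normal(size=(10, 6))
        emb = ec.integrate_batches(X, np.zeros(10), n_pcs=200)
        assert emb.n_pcs == 5    # min(10, 6) - 1


class TestChange:
    def _toy_embedding(self, profiles):
        n, g = profiles.shape
        return ec.EmbeddingSpace(loadings=np.eye(g), scores=profiles,
                                 variance_explained=np.ones(g),
                                 mean_profile=np.zeros(g))

    def test_control_mean_exactly_zero(self, small_change):
        _, change, is_ctrl = small_change
        assert abs(np.nanmean(change[is_ctrl])) < 1e-12

    def test_cell_at_centroid_formula(self):
        rng = np.random.default_rng(7)
        ctrl = rng.normal(size=(3, 6)) + 5
        centroid = ctrl.mean(axis=0)
        profiles = np.vstack([ctrl, centroid])
        emb = self._toy_embedding(profiles)
        is_ctrl = np.array([True, True, True, False])
        change = ec.transcriptomic_change(emb, is_ctrl)
        # direct formula on the 3-cell toy
        def corr(a, b):
            return np.corrcoef(a, b)[0, 1]
        raw_ctrl = [-corr(c, centroid) for c in ctrl]
        expected = -1.0 - np.mean(raw_ctrl)
        assert change[3] == pytest.approx(expected, abs=1e-12)

    def test_anticorrelated_cell_maximal(self):
        rng = np.random.default_rng(8)
        ctrl = rng.normal(size=(4, 6)) + 3
        centroid = ctrl.mean(axis=0)
        anti = 2 * centroid.mean() - centroid      # corr = -1 with centroid
        profiles = np.vstack([ctrl, anti])
        emb = self._toy_embedding(profiles)
        change = ec.transcriptomic_change(emb, np.array([1, 1, 1, 1, 0], bool))
        assert change[4] == max(change)
        # raw term is exactly +1 (corr = -1); change = 1 - control adjustment
        raw_ctrl = [-np.corrcoef(c, centroid)[0, 1] for c in ctrl]
        assert change[4] == pytest.approx(1.0 - np.mean(raw_ctrl), abs=1e-12)

    def test_too_few_controls_rejected(self):
        emb = self._toy_embedding(np.random.default_rng(9).normal(size=(3, 4)))
        with pytest.raises(ec.ConfigurationError):
            ec.transcriptomic_change(emb, np.array([True, False, False]))


class TestMinimalFunctionalDose:
    def test_never_exceeded_returns_none(self):
        d = np.linspace(0, 8, 30)
        assert ec.minimal_functional_dose(d, np.full(30, 0.1)) is None

    def test_step_function(self):
        d = np.linspace(0, 8, 33)
        c = np.where(d >= 3, 0.5, 0.0)
        assert ec.minimal_functional_dose(d, c) == pytest.approx(3.0, abs=0.3)

    def test_logistic_closed_form_inversion(self):
        # a=0, K=0.5, d50=2, s=4: K/(1+e^{-s(d-d50)}) = 0.23
        # => d* = d50 - ln(K/0.23 - 1)/s
        d = np.linspace(0, 8, 2001)
        c = 0.5 / (1 + np.exp(-4 * (d - 2)))
        expected = 2 - np.log(0.5 / 0.23 - 1) / 4
        got = ec.minimal_functional_dose(d, c)
        assert got == pytest.approx(expected, abs=0.01)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(min_value=0.05, max_value=0.6),
           st.floats(min_value=0.05, max_value=0.6))
    def test_monotone_in_threshold(self, t1, t2):
        rng = np.random.default_rng(10)
        d = np.sort(rng.uniform(0, 8, 60))
        c = 0.8 / (1 + np.exp(-1.5 * (d - 3))) + rng.normal(0, 0.05, 60)
        lo, hi = sorted((t1, t2))
        d_lo = ec.minimal_functional_dose(d, c, threshold=lo)
        d_hi = ec.minimal_functional_dose(d, c, threshold=hi)
        if d_hi is not None:
            assert d_lo is not None and d_lo <= d_hi


class TestHousekeeping:
    def test_hand_computed_ratio(self):
        hk_expr = pd.Series({"hk1": 1.0, "hk2": 3.0, "hk3": 2.0,
                             "hk4": 2.0, "hk5": 2.0})
        out = ec.normalize_to_housekeeping([2, 4, 6], hk_expr, list(hk_expr.index))
        np.testing.assert_allclose(out, [1, 2, 3])

    def test_doubling_leaves_ratios_unchanged(self):
        hk = pd.Series({f"h{i}": v for i, v in enumerate([1, 2, 3, 2, 2])})
        a = ec.normalize_to_housekeeping([4.0], hk, list(hk.index))
        b = ec.normalize_to_housekeeping([8.0], 2 * hk, list(hk.index))
        assert a[0] == pytest.approx(b[0])

    def test_too_few_housekeeping_genes(self):
        hk = pd.Series({"h0": 1.0})
        with pytest.raises(ec.ConfigurationError):
            ec.normalize_to_housekeeping([1.0], hk, ["h0", "h1", "h2", "h3", "h4"])


class TestPhysiological:
    def test_quantile_band_via_order_statistics(self):
        vals = np.arange(1.0, 21.0)     # 20 values; brute-force quantiles
        table = {"top": vals, "low": vals / 10}
        lo, hi = np.quantile(vals, [0.05, 0.95])
        below = ec.compare_physiological(lo - 0.1, table)
        inside = ec.compare_physiological(np.median(vals), table)
        assert below == {"within_range": False, "top_cell_type": "top",
                         "band": (lo, hi)}
        assert inside["within_range"] is True

    def test_absent_tf_returns_none(self):
        assert ec.compare_physiological(1.0, {}) is None
        assert ec.compare_physiological(None, {"a": [1, 2]}) is None


class TestSimilarity:
    def test_matches_direct_pearson_formula(self):
        rng = np.random.default_rng(11)
        S = rng.normal(size=(3, 50))
        C = ec.pairwise_cell_similarity(S)
        for i in range(3):
            for j in range(3):
                x, y = S[i], S[j]
                expected = (np.sum((x - x.mean()) * (y - y.mean()))
                            / np.sqrt(np.sum((x - x.mean()) ** 2)
                                      * np.sum((y - y.mean()) ** 2)))
                assert C[i, j] == pytest.approx(expected, abs=1e-10)
        assert np.allclose(np.diag(C), 1.0)
        assert np.allclose(C, C.T)

    def test_identical_cells_and_zero_variance_flag(self):
        S = np.vstack([np.arange(50.0), np.arange(50.0), np.zeros(50)])
        C = ec.pairwise_cell_similarity(S)
        assert C[0, 1] == pytest.approx(1.0)
        assert np.isnan(C[2, 0]) and np.isnan(C[2, 2])


class TestModuleScore:
    def test_whole_panel_scores_near_zero(self):
        rng = np.random.default_rng(12)
        X = rng.poisson(3.0, size=(30, 40)).astype(float)
        names = [f"g{i}" for i in range(40)]
        s = ec.module_score(X, names, names, n_bins=4, n_ctrl=100, seed=0)
        assert np.abs(s).max() < 0.3

    def test_silent_module_scores_negative(self):
        rng = np.random.default_rng(13)
        X = rng.poisson(5.0, size=(20, 30)).astype(float)
        X[:, :5] = 0.0
        names = [f"g{i}" for i in range(30)]
        s = ec.module_score(X, names, names[:5], n_bins=1, n_ctrl=50, seed=0)
        assert (s < 0).all()

    def test_two_bin_toy_matches_brute_force(self):
        # 10 genes, 2 bins; recompute the bin-matched score independently
        rng = np.random.default_rng(14)
        X = np.sort(rng.uniform(0, 4, size=(6, 10)), axis=1)
        names = [f"g{i}" for i in range(10)]
        gene_set = ["g7", "g9"]
        seed = 3
        got = ec.module_score(X, names, gene_set, n_bins=2, n_ctrl=3, seed=seed)

        mean_expr = X.mean(axis=0)
        order = np.lexsort((np.arange(10), mean_expr))
        bins = np.empty(10, int)
        bins[order] = (np.arange(10) * 2) // 10
        rng2 = np.random.default_rng(seed)
        ctrl_idx = []
        for g in (7, 9):
            pool = np.where(bins == bins[g])[0]
            pool = pool[pool != g]
            ctrl_idx.append(rng2.choice(pool, size=3, replace=False))
        ctrl_idx = np.unique(np.concatenate(ctrl_idx))
        expected = X[:, [7, 9]].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_tiny_set_rejected(self):
        X = np.ones((3, 5))
        with pytest.raises(ec.ConfigurationError):
            ec.module_score(X, list("abcde"), ["a"])


class TestRecoveryProperties:
    def test_planted_signal_survives_control_regression(self):
        """Control variability lives in a known subspace; the planted TF
        direction is recovered after regression with high cosine similarity."""
        rng = np.random.default_rng(15)
        n_genes = 60
        basis = rng.normal(size=(3, n_genes))        # control subspace
        tf_dir = rng.normal(size=n_genes)
        tf_dir -= (basis.T @ np.linalg.lstsq(basis.T, tf_dir, rcond=None)[0])
        tf_dir /= np.linalg.norm(tf_dir)
        ctrl = rng.normal(size=(80, 3)) @ basis
        tf = rng.normal(size=(40, 3)) @ basis + 4.0 * tf_dir
        X = np.vstack([ctrl, tf]) + rng.normal(0, 0.05, size=(120, n_genes))
        is_ctrl = np.array([True] * 80 + [False] * 40)
        res = ec.regress_control_heterogeneity(X, is_ctrl, np.zeros(120),
                                               k_ctrl=3)
        recovered = res[~is_ctrl].mean(axis=0) - res[is_ctrl].mean(axis=0)
        cos = recovered @ tf_dir / np.linalg.norm(recovered)
        assert cos > 0.95
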