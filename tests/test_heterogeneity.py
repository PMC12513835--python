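"""Clustering, heterogeneity-candidate detection and NB-GLM DE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from tfscreen import embed_change as ec
from tfscreen import heterogeneity as het
from tfscreen import simdata as sd


class TestNonfunctional:
    def test_threshold_rule(self):
        flags = het.label_nonfunctional([0.0, 0.5, 0.23, 0.231])
        assert list(flags) == [True, False, True, False]

    def test_nonfunctional_fraction_decreases_with_dose(self, small_exp,
                                                        small_change):
        _, change, is_ctrl = small_change
        truth = small_exp.truth
        gt = small_exp.ground_truth
        high = [n for n in gt.tf_names
                if gt.tf_params[n].tf_class != sd.CLASS_LOW]
        m = truth["tf"].isin(high).values
        nonf = het.label_nonfunctional(change)
        lo = m & (truth["dose"] < 1).values
        hi = m & (truth["dose"] > 5).values
        assert nonf[lo].mean() > nonf[hi].mean()


class TestClustering:
    def _blobs(self, centers, n=60, sd=0.3, seed=0, dim=10):
        rng = np.random.default_rng(seed)
        pts, lab = [], []
        for i, c in enumerate(centers):
            mu = np.zeros(dim)
            mu[: len(c)] = c
            pts.append(rng.normal(0, sd, size=(n, dim)) + mu)
            lab += [i] * n
        return np.vstack(pts), np.array(lab)

    def test_two_separated_blobs_two_clusters(self):
        X, truth = self._blobs([(0, 0), (6, 6)], n=100)
        labels = het.cluster_cells(X, resolution=0.5, seed=0)
        assert len(np.unique(labels)) == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_vanishing_resolution_single_cluster(self):
        # one connected cloud: resolution -> 0 merges everything
        rng = np.random.default_rng(20)
        X = rng.normal(size=(150, 10))
        labels = het.cluster_cells(X, resolution=1e-4, seed=0)
        assert len(np.unique(labels)) == 1

    def test_planted_four_blobs_recovered(self):
        X, truth = self._blobs([(0, 0), (7, 0), (0, 7), (7, 7)], seed=4)
        labels = het.cluster_cells(X, resolution=1.2, seed=0)
        assert adjusted_rand_score(truth, labels) > 0.95

    def test_deterministic_for_fixed_seed(self):
        X, _ = self._blobs([(0, 0), (5, 5), (0, 5)], seed=2)
        a = het.cluster_cells(X, seed=3)
        b = het.cluster_cells(X, seed=3)
        np.testing.assert_array_equal(a, b)


class TestControlClusters:
    def test_pure_control_cluster_flagged(self):
        labels = np.array([0] * 10 + [1] * 10)
        is_focal = np.array([False] * 10 + [True] * 10)
        flags = het.identify_control_clusters(labels, is_focal)
        assert flags == {0: True, 1: False}

    def test_strict_sixty_percent_rule(self):
        # 59% focal -> control cluster; 60% focal -> functional
        labels = np.array([0] * 100 + [1] * 100)
        focal = np.array([True] * 59 + [False] * 41
                         + [True] * 60 + [False] * 40)
        flags = het.identify_control_clusters(labels, focal, control_frac=0.6)
        assert flags == {0: True, 1: False}

    def test_invariant_to_relabeling(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 4, 200)
        focal = rng.random(200) < 0.5
        flags = het.identify_control_clusters(labels, focal)
        perm = {0: 7, 1: 3, 2: 9, 3: 0}
        relabeled = np.array([perm[x] for x in labels])
        flags2 = het.identify_control_clusters(relabeled, focal)
        assert all(flags2[perm[c]] == flags[c] for c in flags)


class TestCandidates:
    def test_even_split_is_candidate(self):
        labels = np.array([0] * 20 + [1] * 20)
        tfs = np.array(["A"] * 40)
        cand = het.find_heterogeneous_tfs(labels, tfs, {0: False, 1: False})
        assert cand.loc[cand["tf"] == "A", "candidate"].item()

    def test_lopsided_split_not_candidate(self):
        labels = np.array([0] * 97 + [1] * 3)
        tfs = np.array(["A"] * 100)
        cand = het.find_heterogeneous_tfs(labels, tfs, {0: False, 1: False})
        assert not cand.loc[cand["tf"] == "A", "candidate"].item()

    def test_small_tf_excluded(self):
        labels = np.array([0] * 15 + [1] * 14)
        tfs = np.array(["A"] * 29)
        cand = het.find_heterogeneous_tfs(labels, tfs, {0: False, 1: False},
                                          min_cells=30)
        row = cand.loc[cand["tf"] == "A"].iloc[0]
        assert row["excluded_small"] and not row["candidate"]

    def test_control_clusters_do_not_count(self):
        labels = np.array([0] * 20 + [1] * 20)
        tfs = np.array(["A"] * 40)
        cand = het.find_heterogeneous_tfs(labels, tfs, {0: True, 1: False})
        assert not cand.loc[cand["tf"] == "A", "candidate"].item()


class TestBranchDetection:
    def test_branch_tf_detected_logistic_tf_not(self):
        """End-to-end: a branching TF spreads over two functional clusters;
        a plain logistic TF and a low-capacity TF do not."""
        cfg = sd.SimConfig(n_tfs=3, n_genes=900, genes_per_module=80,
                           n_branch_tfs=1, n_control_cells_per_batch=100,
                           doublet_rate=0.0, ambient_rate=0.0)
        gt = sd.simulate_ground_truth(cfg, seed=6)
        exp = sd.simulate_experiment(gt, 100, seed=6)
        truth = exp.truth
        is_ctrl = (truth["tf"] == sd.CONTROL_TF).values
        emb = ec.control_referenced_embedding(
            exp.counts, is_ctrl, truth["batch"].values, n_pcs=50)
        change = ec.transcriptomic_change(emb, is_ctrl)
        keep = is_ctrl | (change > 0.23)
        labels = het.cluster_cells(emb.scores[keep], resolution=1.2, seed=0)
        flags = het.identify_control_clusters(labels, ~is_ctrl[keep])
        cand = het.find_heterogeneous_tfs(labels, truth["tf"].values[keep],
                                          flags, min_cells=30)
        cand = cand.set_index("tf")
        branch = [n for n in gt.tf_names
                  if gt.tf_params[n].response_shape == sd.RESPONSE_BRANCH]
        logistic_high = [n for n in gt.tf_names
                         if gt.tf_params[n].response_shape == sd.RESPONSE_LOGISTIC
                         and gt.tf_params[n].tf_class != sd.CLASS_LOW]
        assert cand.loc[branch[0], "candidate"]
        for n in logistic_high:
            if n in cand.index:
                assert not cand.loc[n, "candidate"]


class TestRecluster:
    def test_planted_states_recovered_with_paired_controls(self):
        cfg = sd.SimConfig(n_tfs=3, n_genes=900, genes_per_module=80,
                           n_branch_tfs=1, doublet_rate=0.0, ambient_rate=0.0)
        gt = sd.simulate_ground_truth(cfg, seed=8)
        exp = sd.simulate_experiment(gt, 120, seed=8)
        truth = exp.truth
        branch = [n for n in gt.tf_names
                  if gt.tf_params[n].response_shape == sd.RESPONSE_BRANCH][0]
        cells = pd.DataFrame({
            "assigned_tf": truth["tf"],
            "batch": truth["batch"],
            "is_control": truth["tf"] == sd.CONTROL_TF,
        })
        lognorm, _ = ec.normalize_log1p(exp.counts)

        def scores_fn(subset):
            emb = ec.integrate_batches(lognorm[subset],
                                       truth["batch"].values[subset],
                                       n_pcs=30)
            return emb.scores

        subset, labels, flags = het.recluster_tf_with_controls(
            scores_fn, branch, cells, seed=0)
        functional = [c for c, is_ctrl_c in flags.items() if not is_ctrl_c]
        assert len(functional) >= 2

    def test_missing_controls_rejected(self):
        cells = pd.DataFrame({
            "assigned_tf": ["A"] * 5,
            "batch": [0] * 5,
            "is_control": [False] * 5,
        })
        with pytest.raises(ValueError):
            het.recluster_tf_with_controls(lambda s: None, "A", cells)


class TestDifferentialExpression:
    def _nb_counts(self, rng, mu, alpha, size):
        lam = rng.gamma(1 / alpha, scale=mu * alpha, size=size)
        return rng.poisson(lam)

    def test_planted_fourfold_gene_detected(self):
        rng = np.random.default_rng(30)
        n = 100
        mu = np.full(60, 5.0)
        A = self._nb_counts(rng, 5.0, 0.1, (n, 60))
        B = self._nb_counts(rng, 5.0, 0.1, (n, 60))
        B[:, 0] = self._nb_counts(rng, 20.0, 0.1, n)    # 4-fold up
        counts = np.vstack([A, B])
        group = np.array(["a"] * n + ["b"] * n)
        res = het.differential_expression(counts, group)
        assert res.loc[0, "fdr"] < 0.05
        assert res.loc[0, "log2fc"] == pytest.approx(2.0, abs=0.5)

    def test_batch_confounded_null_is_calibrated(self):
        """Batch shifts only; the batch covariate must absorb them."""
        rng = np.random.default_rng(31)
        n = 60
        n_genes = 300
        mu = rng.uniform(2, 10, n_genes)
        batch_factor = np.exp(rng.normal(0, 0.3, n_genes))
        counts = np.empty((2 * n, n_genes))
        for j in range(n_genes):
            counts[:n, j] = self._nb_counts(rng, mu[j], 0.1, n)
            counts[n:, j] = self._nb_counts(rng, mu[j] * batch_factor[j], 0.1, n)
        # group is partially confounded with batch (70/30 vs 30/70)
        group = np.array(["a"] * 42 + ["b"] * 18 + ["a"] * 18 + ["b"] * 42)
        batch = np.array([0] * n + [1] * n)
        res = het.differential_expression(counts, group, batch=batch)
        assert (res["pval"] < 0.05).mean() <= 0.075

    def test_degenerate_gene_flagged_p_one(self):
        counts = np.ones((20, 3))
        counts[:, 2] = 0.0
        group = np.array(["a"] * 10 + ["b"] * 10)
        res = het.differential_expression(counts, group)
        assert res.loc[2, "flagged"]
        assert res.loc[2, "pval"] == 1.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            het.differential_expression(np.ones((4, 2)),
                                        np.array(["a", "a", "b", "b"])[:4][:4])


class TestBH:
    def test_matches_brute_force_reference(self):
        rng = np.random.default_rng(32)
        p = rng.uniform(size=1000)
        got = het.benjamini_hochberg(p)
        # independent reference: sort, adjust, enforce monotonicity
        order = np.argsort(p)
        adj = np.empty(1000)
        prev = 1.0
        for rank in range(1000, 0, -1):
            i = order[rank - 1]
            val = min(prev, p[i] * 1000 / rank)
            adj[i] = val
            prev = val
        np.testing.assert_allclose(got, adj, atol=1e-12)
        # agreement with statsmodels' implementation
        from statsmodels.stats.multitest import multipletests
        np.testing.assert_allclose(got, multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)


class TestDoseModuleCurves:
    def test_constant_score_flat_curve(self):
        rng = np.random.default_rng(33)
        d = rng.uniform(0, 8, 80)
        curve = het.dose_module_curves(np.full(80, 0.4), d, n_boot=20, seed=0)
        np.testing.assert_allclose(curve["fit"], 0.4, atol=1e-9)

    def test_monotone_signal_monotone_fit(self):
        d = np.linspace(0, 8, 100)
        curve = het.dose_module_curves(0.1 * d, d, n_boot=20, seed=0)
        assert (np.diff(curve["fit"]) > -1e-9).all()

    def test_interior_peak_recovered(self):
        rng = np.random.default_rng(34)
        d = rng.uniform(0, 8, 300)
        score = np.exp(-0.5 * (d - 4) ** 2) + rng.normal(0, 0.1, 300)
        curve = het.dose_module_curves(score, d, n_boot=20, seed=0)
        peak = curve.loc[curve["fit"].idxmax(), "dose"]
        assert 3.0 < peak < 5.0
        assert curve["fit"].iloc[0] < curve["fit"].max() - 0.3
        assert curve["fit"].iloc[-1] < curve["fit"].max() - 0.3

    def test_too_few_cells_refused(self):
        with pytest.raises(ValueError):
            het.dose_module_curves(np.zeros(10), np.arange(10))
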