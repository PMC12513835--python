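"""Reprogramming heterogeneity: clustering, candidate TFs and NB-GLM DE.

A TF that drives distinct cell states leaves its cells spread over at least
two *functional* clusters (clusters not dominated by controls).  The
procedure: cluster control + functional TF cells in a PC embedding
(shared-nearest-neighbour graph, modularity community detection at
resolution 1.2), flag control clusters by a 60% composition rule, and call a
TF a heterogeneity candidate when two or more functional clusters each hold
between 5% and 95% of that TF's cells (TFs with fewer than 30 cells are
excluded).  Differential expression uses per-gene negative-binomial GLMs
with a batch covariate, dispersion estimated from Pearson residuals and
shrunk toward a mean-dispersion trend, and a likelihood-ratio test on the
group term with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy import stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

from .embed_change import DEFAULT_CHANGE_THRESHOLD

logger = logging.getLogger(__name__)


def label_nonfunctional(changes, threshold: float = DEFAULT_CHANGE_THRESHOLD):
    """Non-functional iff overall transcriptomic change <= threshold."""
    return np.asarray(changes, float) <= threshold


# ---------------------------------------------------------------------------
# SNN clustering
# ---------------------------------------------------------------------------

def _snn_graph(scores, k_nn: int, prune: float = 1 / 15):
    """Shared-nearest-neighbour graph with Jaccard weights."""
    n = scores.shape[0]
    k = min(k_nn, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scores)
    _, idx = nn.kneighbors(scores)
    neighbor_sets = [set(row) for row in idx]      # includes self, Seurat-style
    rows, cols, weights = [], [], []
    for i in range(n):
        for j in idx[i]:
            if j <= i:
                continue
            shared = len(neighbor_sets[i] & neighbor_sets[int(j)])
            jac = shared / (2 * (k + 1) - shared)
            if jac >= prune:
                rows.append(i)
                cols.append(int(j))
                weights.append(jac)
    g = ig.Graph(n=n, edges=list(zip(rows, cols)))
    g.es["weight"] = weights
    return g


def cluster_cells(scores, resolution: float = 1.2, k_nn: int = 20,
                  seed: int = 0) -> np.ndarray:
    """SNN graph + modularity community detection at a given resolution.

    Deterministic for fixed seed.  ``k_nn`` is reduced (with a warning)
    when there are fewer cells than neighbours requested.
    """
    scores = np.asarray(scores, float)
    n = scores.shape[0]
    if n <= k_nn:
        logger.warning("only %d cells; reducing k_nn from %d", n, k_nn)
        k_nn = max(2, n - 1)
    g = _snn_graph(scores, k_nn)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed,
        n_iterations=2)
    return np.asarray(part.membership)


def identify_control_clusters(labels, is_focal, control_frac: float = 0.6):
    """Flag clusters where the focal group holds < ``control_frac`` of cells.

    Mirrors the composition rule "control clusters are those in which fewer
    than 60% of cells originate from the focal TF".  Returns a dict
    cluster -> bool (True = control cluster); invariant to relabeling.
    """
    labels = np.asarray(labels)
    is_focal = np.asarray(is_focal, bool)
    out = {}
    for c in np.unique(labels):
        in_c = labels == c
        out[int(c)] = bool(is_focal[in_c].mean() < control_frac)
    return out


def find_heterogeneous_tfs(labels, tf_per_cell, control_cluster_flags,
                           min_cells: int = 30, band=(0.05, 0.95)):
    """Candidate heterogeneity-driving TFs.

    A TF is a candidate iff at least two functional (non-control) clusters
    each hold a fraction of that TF's cells inside ``band``; TFs with fewer
    than ``min_cells`` cells in the clustering are excluded.  Returns a
    DataFrame with per-TF diagnostics.
    """
    labels = np.asarray(labels)
    tf_per_cell = np.asarray(tf_per_cell, dtype=object)
    rows = []
    for tf in pd.unique(tf_per_cell):
        in_tf = tf_per_cell == tf
        n = int(in_tf.sum())
        if n < min_cells:
            rows.append({"tf": tf, "n_cells": n, "n_spread_clusters": 0,
                         "candidate": False, "excluded_small": True})
            continue
        n_spread = 0
        for c in np.unique(labels):
            if control_cluster_flags.get(int(c), False):
                continue
            frac = (labels[in_tf] == c).mean()
            if band[0] <= frac <= band[1]:
                n_spread += 1
        rows.append({"tf": tf, "n_cells": n, "n_spread_clusters": n_spread,
                     "candidate": n_spread >= 2, "excluded_small": False})
    return pd.DataFrame(rows)


def recluster_tf_with_controls(scores_fn, tf: str, cells: pd.DataFrame,
                               resolution: float = 1.2, k_nn: int = 20,
                               seed: int = 0, control_frac: float = 0.6):
    """Pool one TF's cells with batch-paired controls and recluster.

    ``scores_fn(subset_index)`` must return an embedding (cells x PCs) for
    the given positional cell subset (e.g. a PCA recomputed on the pooled
    cells).  ``cells`` needs columns ``assigned_tf``, ``batch`` and
    ``is_control``.  Returns (subset_index, labels, control_cluster_flags).
    """
    in_tf = (cells["assigned_tf"] == tf).values
    if not in_tf.any():
        raise ValueError(f"no cells assigned to {tf!r}")
    tf_batches = set(cells.loc[in_tf, "batch"])
    paired_ctrl = cells["is_control"].values & cells["batch"].isin(tf_batches).values
    if not paired_ctrl.any():
        raise ValueError(f"no batch-paired controls for {tf!r}")
    subset = np.where(in_tf | paired_ctrl)[0]
    scores = scores_fn(subset)
    labels = cluster_cells(scores, resolution=resolution, k_nn=k_nn, seed=seed)
    flags = identify_control_clusters(labels, in_tf[subset], control_frac)
    return subset, labels, flags


# ---------------------------------------------------------------------------
# Negative-binomial differential expression
# ---------------------------------------------------------------------------

@dataclass
class DEOptions:
    dispersion_floor: float = 1e-4
    shrink_weight: float = 0.5        # toward the mean-dispersion trend
    lowess_frac: float = 0.4


def _estimate_dispersions(Y, design, offset, opts: DEOptions):
    """Per-gene moment dispersion from Poisson fits, shrunk to a trend."""
    n_genes = Y.shape[1]
    alpha_raw = np.full(n_genes, np.nan)
    mean_expr = Y.mean(axis=0)
    for j in range(n_genes):
        y = Y[:, j]
        if y.sum() == 0:
            continue
        try:
            fit = sm.GLM(y, design, family=sm.families.Poisson(),
                         offset=offset).fit()
            mu = fit.mu
            num = np.sum((y - mu) ** 2 - mu)
            den = np.sum(mu ** 2)
            alpha_raw[j] = num / den if den > 0 else np.nan
        except Exception:
            continue
    alpha = np.clip(alpha_raw, opts.dispersion_floor, 10.0)
    ok = np.isfinite(alpha) & (mean_expr > 0)
    if ok.sum() >= 10:
        trend = lowess(np.log(alpha[ok]), np.log(mean_expr[ok] + 1e-8),
                       frac=opts.lowess_frac, return_sorted=False)
        shrunk = np.exp((1 - opts.shrink_weight) * np.log(alpha[ok])
                        + opts.shrink_weight * trend)
        alpha[ok] = shrunk
    alpha[~np.isfinite(alpha)] = opts.dispersion_floor
    return np.clip(alpha, opts.dispersion_floor, 10.0)


def differential_expression(counts, group, batch=None, gene_names=None,
                            opts: DEOptions | None = None) -> pd.DataFrame:
    """NB GLM per gene with a batch covariate and a group LRT.

    ``group`` is a two-level label array; ``batch`` an optional label array.
    Library size enters as a log-total offset.  Per-gene dispersion is
    estimated from Poisson Pearson moments and shrunk toward a lowess
    mean-dispersion trend, then held fixed in full (group + batch) and
    reduced (batch) NB fits; the group effect is tested by a 1-df
    likelihood-ratio test with BH correction.  All-zero genes get p = 1 and
    are flagged.  ``log2fc`` is the group coefficient on the log2 scale.
    """
    if opts is None:
        opts = DEOptions()
    Y = counts.toarray() if sp.issparse(counts) else np.asarray(counts)
    Y = np.asarray(Y, float)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError(f"group must have 2 levels, got {list(levels)}")
    for lv in levels:
        if (group == lv).sum() < 3:
            raise ValueError(f"group {lv!r} has fewer than 3 cells")
    g = (group == levels[1]).astype(float)

    n = len(g)
    cols = [np.ones(n), g]
    names = ["intercept", "group"]
    if batch is not None:
        batch = np.asarray(batch)
        for b in pd.unique(batch)[1:]:
            cols.append((batch == b).astype(float))
            names.append(f"batch_{b}")
    design = np.column_stack(cols)
    design_red = np.delete(design, 1, axis=1)

    total = Y.sum(axis=1)
    offset = np.log(np.maximum(total, 1.0) / np.median(np.maximum(total, 1.0)))

    alpha = _estimate_dispersions(Y, design, offset, opts)

    n_genes = Y.shape[1]
    pvals = np.ones(n_genes)
    lfc = np.zeros(n_genes)
    flagged = np.zeros(n_genes, bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(n_genes):
            y = Y[:, j]
            if y.sum() == 0:
                flagged[j] = True
                continue
            fam = sm.families.NegativeBinomial(alpha=float(alpha[j]))
            try:
                full = sm.GLM(y, design, family=fam, offset=offset).fit(maxiter=100)
                red = sm.GLM(y, design_red, family=fam, offset=offset).fit(maxiter=100)
                lr = 2.0 * (full.llf - red.llf)
                pvals[j] = stats.chi2.sf(max(lr, 0.0), df=1)
                lfc[j] = full.params[1] / np.log(2)
            except Exception:
                flagged[j] = True
                pvals[j] = 1.0
    fdr = benjamini_hochberg(pvals)
    out = pd.DataFrame({
        "gene": gene_names if gene_names is not None else np.arange(n_genes),
        "log2fc": lfc,
        "pval": pvals,
        "fdr": fdr,
        "dispersion": alpha,
        "flagged": flagged,
        "n_a": int((group == levels[0]).sum()),
        "n_b": int((group == levels[1]).sum()),
    })
    return out


def benjamini_hochberg(pvals):
    """BH-adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Dose-module response curves
# ---------------------------------------------------------------------------

def dose_module_curves(scores, doses, frac: float = 0.4, grid=None,
                       n_boot: int = 200, seed: int = 0, ci: float = 0.95):
    """Local-regression (lowess) curve of module score vs dose with a
    bootstrap confidence band.  Requires >= 20 cells."""
    scores = np.asarray(scores, float)
    doses = np.asarray(doses, float)
    if len(scores) < 20:
        raise ValueError(f"need >= 20 cells for a dose-module curve, got {len(scores)}")
    if grid is None:
        grid = np.linspace(doses.min(), doses.max(), 50)
    fit = lowess(scores, doses, frac=frac, xvals=grid)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(grid)))
    n = len(scores)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = lowess(scores[idx], doses[idx], frac=frac, xvals=grid)
    a = (1 - ci) / 2
    lo = np.nanquantile(boots, a, axis=0)
    hi = np.nanquantile(boots, 1 - a, axis=0)
    return pd.DataFrame({"dose": grid, "fit": fit, "lo": lo, "hi": hi})
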