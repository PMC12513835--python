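"""Cell-cycle scoring, phase assignment and TF x dose x phase summaries.

S and G2/M programs are scored with bin-matched module scores.  The raw
phase call is G1 when both scores are non-positive, otherwise the phase of
the larger score.  The *adjusted* phase re-thresholds both scores against
the control population (95th percentile of each score among controls,
floored at zero so the adjustment can only reassign cells toward G1):
controls define the cycling baseline, and only cells exceeding it are
called S or G2/M.  Per-TF phase-composition shifts are tested against a
reference control group with an exact test on the 2 x 3 phase table
(full enumeration for small tables, seeded Monte-Carlo otherwise),
BH-corrected across TFs.
"""

from __future__ import annotations

import logging
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats

from .embed_change import module_score
from .heterogeneity import benjamini_hochberg

logger = logging.getLogger(__name__)

PHASES = ("G1", "S", "G2M")


def cc_scores(X, gene_names, s_genes, g2m_genes, n_bins: int = 24,
              n_ctrl: int = 100, seed: int = 0) -> pd.DataFrame:
    """S and G2/M module scores (shared seed for the control-gene draw)."""
    if len(list(s_genes)) == 0 or len(list(g2m_genes)) == 0:
        raise ValueError("S and G2/M gene lists must be non-empty")
    s = module_score(X, gene_names, s_genes, n_bins=n_bins, n_ctrl=n_ctrl,
                     seed=seed)
    g = module_score(X, gene_names, g2m_genes, n_bins=n_bins, n_ctrl=n_ctrl,
                     seed=seed)
    return pd.DataFrame({"s_score": s, "g2m_score": g})


def assign_phase(scores: pd.DataFrame) -> np.ndarray:
    """Raw phase: G1 if both scores <= 0, else argmax(S, G2M)."""
    s = scores["s_score"].values
    g = scores["g2m_score"].values
    return np.where((s <= 0) & (g <= 0), "G1", np.where(s >= g, "S", "G2M"))


def adjust_phase(scores: pd.DataFrame, control_scores: pd.DataFrame,
                 quantile: float = 0.95) -> np.ndarray:
    """Control-referenced phase: thresholds at the control populations'
    ``quantile`` of each score (floored at 0); cells below both thresholds
    are G1, others take the phase of the larger score excess."""
    s_thr = max(0.0, float(np.quantile(control_scores["s_score"], quantile)))
    g_thr = max(0.0, float(np.quantile(control_scores["g2m_score"], quantile)))
    s = scores["s_score"].values - s_thr
    g = scores["g2m_score"].values - g_thr
    return np.where((s <= 0) & (g <= 0), "G1", np.where(s >= g, "S", "G2M"))


# ---------------------------------------------------------------------------
# Exact test on the 2 x K phase table
# ---------------------------------------------------------------------------

def _log_comb(n, k):
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def _table_logp(ks, col_sums, n1, N):
    lp = -_log_comb(N, n1)
    for k, m in zip(ks, col_sums):
        lp += _log_comb(m, k)
    return lp


def exact_phase_table_test(table, max_total: int = 300, n_mc: int = 100000,
                           seed: int = 0) -> float:
    """Exact (Fisher-type) test of independence on a 2 x K table.

    Full enumeration of tables with the observed margins when the total is
    <= ``max_total`` (probability mass from the multivariate hypergeometric;
    p = sum of probabilities <= that of the observed table).  Larger tables
    fall back to seeded Monte-Carlo sampling of the null.  A 2 x 2 table
    reproduces the hypergeometric two-sided Fisher p-value.
    """
    T = np.asarray(table, dtype=int)
    if T.ndim != 2 or T.shape[0] != 2:
        raise ValueError("table must be 2 x K")
    T = T[:, T.sum(axis=0) > 0]      # collapse empty phase columns
    if T.shape[1] < 2:
        return 1.0
    col_sums = T.sum(axis=0)
    n1 = int(T[0].sum())
    N = int(T.sum())
    obs_lp = _table_logp(T[0], col_sums, n1, N)
    eps = 1e-9

    if N <= max_total:
        def rec(col, remaining, lp_acc, acc):
            if col == len(col_sums) - 1:
                if remaining <= col_sums[col]:
                    lp = lp_acc + _log_comb(col_sums[col], remaining) \
                        - _log_comb(N, n1)
                    if lp <= obs_lp + eps:
                        acc[0] += np.exp(lp)
                return
            for k in range(0, min(col_sums[col], remaining) + 1):
                rec(col + 1, remaining - k,
                    lp_acc + _log_comb(col_sums[col], k), acc)
        acc = [0.0]
        rec(0, n1, 0.0, acc)
        return float(min(acc[0], 1.0))

    # Monte-Carlo: sample row-1 allocations from the multivariate
    # hypergeometric null and compare table probabilities
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(col_sums, n1, size=n_mc)
    lps = np.array([_table_logp(d, col_sums, n1, N) for d in draws])
    return float((np.sum(lps <= obs_lp + eps) + 1) / (n_mc + 1))


def phase_fraction_test(cells: pd.DataFrame, ref_group: str = "control",
                        group_col: str = "assigned_tf",
                        phase_col: str = "adjusted_phase",
                        seed: int = 0) -> pd.DataFrame:
    """Per-TF exact test of phase composition against a reference group.

    Builds the 2 x 3 table (reference vs TF across G1/S/G2M) for every
    non-reference group and BH-corrects across TFs.
    """
    ref = cells[cells[group_col] == ref_group]
    if len(ref) == 0:
        raise ValueError(f"reference group {ref_group!r} empty")
    ref_counts = np.array([(ref[phase_col] == p).sum() for p in PHASES])
    rows = []
    for tf in pd.unique(cells[group_col]):
        if tf == ref_group:
            continue
        sub = cells[cells[group_col] == tf]
        tf_counts = np.array([(sub[phase_col] == p).sum() for p in PHASES])
        table = np.vstack([tf_counts, ref_counts])
        p = exact_phase_table_test(table, seed=seed)
        fr = tf_counts / max(tf_counts.sum(), 1)
        rows.append({"tf": tf, "n_cells": int(tf_counts.sum()),
                     "frac_g1": fr[0], "frac_s": fr[1], "frac_g2m": fr[2],
                     "pval": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = benjamini_hochberg(out["pval"].values)
    return out


# ---------------------------------------------------------------------------
# Score densities and dose x phase binning
# ---------------------------------------------------------------------------

def score_density(scores, grid, bandwidth=None):
    """Gaussian-kernel density on a fixed grid, normalised to integrate to 1.

    1-D: ``scores`` shape (n,), ``grid`` shape (m,).  2-D: ``scores``
    (n, 2), ``grid`` a pair of axes; returns the density matrix.
    Degenerate (zero-variance) inputs yield a delta-like density at the
    mean, flagged with a warning.
    """
    scores = np.asarray(scores, float)
    if scores.ndim == 1:
        grid = np.asarray(grid, float)
        if len(scores) < 20:
            raise ValueError("need >= 20 cells for a density estimate")
        if np.std(scores) == 0:
            logger.warning("degenerate variance; returning delta-like density")
            dens = np.zeros_like(grid)
            dens[np.argmin(np.abs(grid - scores[0]))] = 1.0
            return dens / np.trapezoid(dens, grid)
        kde = stats.gaussian_kde(scores, bw_method=bandwidth)
        dens = kde(grid)
        return dens / np.trapezoid(dens, grid)
    gx, gy = (np.asarray(g, float) for g in grid)
    if scores.shape[0] < 20:
        raise ValueError("need >= 20 cells for a density estimate")
    kde = stats.gaussian_kde(scores.T, bw_method=bandwidth)
    mx, my = np.meshgrid(gx, gy, indexing="ij")
    dens = kde(np.vstack([mx.ravel(), my.ravel()])).reshape(mx.shape)
    area = np.trapezoid(np.trapezoid(dens, gy, axis=1), gx)
    return dens / area


def bin_by_dose_phase(cells: pd.DataFrame, value_column: str,
                      n_dose_bins: int = 4, min_cells: int = 3,
                      dose_col: str = "dose", phase_col: str = "adjusted_phase"):
    """Mean of ``value_column`` per (phase, dose bin); sparse bins masked.

    Dose bins are uniform over [0, max dose]; bins holding fewer than
    ``min_cells`` cells are NaN-masked.  Returns ``(means, counts)`` as
    phase x bin DataFrames.
    """
    doses = cells[dose_col].values.astype(float)
    edges = np.linspace(0.0, max(doses.max(), 1e-9), n_dose_bins + 1)
    bins = np.clip(np.digitize(doses, edges[1:-1]), 0, n_dose_bins - 1)
    labels = [f"({edges[i]:.2f},{edges[i+1]:.2f}]" for i in range(n_dose_bins)]
    phases = [p for p in PHASES if (cells[phase_col] == p).any()]
    means = pd.DataFrame(index=phases, columns=labels, dtype=float)
    counts = pd.DataFrame(0, index=phases, columns=labels, dtype=int)
    for p in phases:
        for b in range(n_dose_bins):
            sel = (cells[phase_col].values == p) & (bins == b)
            counts.loc[p, labels[b]] = int(sel.sum())
            if sel.sum() >= min_cells:
                means.loc[p, labels[b]] = float(cells.loc[sel, value_column].mean())
            else:
                means.loc[p, labels[b]] = np.nan
    return means, counts
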