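"""Normalisation, control-referenced embedding and overall transcriptomic change.

The central statistic here is the per-cell *overall transcriptomic change*:
after removing control-cell heterogeneity (projection onto a PCA subspace fit
on control cells, per batch) and a simple per-gene per-batch centring
integration, cells are embedded with a top-``n_pcs`` PCA.  The change of a
cell is the negative Pearson correlation between its rank-limited
(PCA-denoised) expression profile and the centroid of control profiles,
baseline-adjusted so that controls average exactly zero.  Reprogrammed cells
decorrelate from the control centroid and score high; control-like cells
score near zero.

Also provided: minimal functional dose (smallest dose at which a monotone
smoother of change versus dose exceeds a threshold, 0.23 by default),
housekeeping normalisation, comparison with physiological expression ranges,
pairwise cell similarity in PC space, and bin-matched module scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger(__name__)

DEFAULT_CHANGE_THRESHOLD = 0.23


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def normalize_log1p(counts, target_sum: float = 1e4):
    """Library-size normalise to ``target_sum`` per cell, then log1p.

    Returns ``(matrix, zero_cell_mask)``; all-zero cells are flagged and
    left at zero (callers should exclude them).
    """
    X = counts.toarray() if sp.issparse(counts) else np.asarray(counts, dtype=float)
    total = X.sum(axis=1)
    zero = total == 0
    if zero.any():
        logger.warning("%d all-zero cells flagged during normalisation", zero.sum())
    scale = np.where(zero, 1.0, target_sum / np.where(zero, 1.0, total))
    return np.log1p(X * scale[:, None]), zero


# ---------------------------------------------------------------------------
# Control-heterogeneity regression and integration
# ---------------------------------------------------------------------------

def regress_control_heterogeneity(X, is_control, batch, k_ctrl: int = 20,
                                  min_controls: int = 20):
    """Remove control-cell structured variation.

    One PCA basis is fit on the pooled control cells (each batch's controls
    centred on their own batch control mean, so the basis captures control
    heterogeneity rather than batch offsets).  Every cell is then centred on
    its batch's control mean and its reconstruction within the
    ``k_ctrl``-dimensional control subspace is subtracted.  A shared basis
    keeps the projection identical across batches; batch-specific offsets
    are handled by the centring (and by the later per-batch integration).
    Batches with fewer than ``min_controls`` controls are centred only
    (with a warning).  Returns the residual matrix (cells x genes, dense).
    """
    X = np.asarray(X, dtype=float)
    is_control = np.asarray(is_control, dtype=bool)
    batch = np.asarray(batch)
    residuals = np.empty_like(X)

    # pooled, batch-centred control matrix -> shared control subspace
    blocks = []
    for b in np.unique(batch):
        ctrl = (batch == b) & is_control
        if ctrl.sum() >= 2:
            blocks.append(X[ctrl] - X[ctrl].mean(axis=0))
    V = None
    if blocks:
        C = np.vstack(blocks)
        k = min(k_ctrl, C.shape[0] - 1, X.shape[1])
        if k >= 1:
            _, _, vt = np.linalg.svd(C, full_matrices=False)
            V = vt[:k]

    for b in np.unique(batch):
        in_b = batch == b
        ctrl = in_b & is_control
        n_ctrl = int(ctrl.sum())
        if n_ctrl < 2:
            logger.warning("batch %r has %d controls; centring on batch mean",
                           b, n_ctrl)
            residuals[in_b] = X[in_b] - X[in_b].mean(axis=0)
            continue
        centred = X[in_b] - X[ctrl].mean(axis=0)
        if n_ctrl < min_controls or V is None:
            logger.warning(
                "batch %r has %d < %d controls; skipping subspace projection",
                b, n_ctrl, min_controls)
            residuals[in_b] = centred
            continue
        residuals[in_b] = centred - (centred @ V.T) @ V
    return residuals


@dataclass
class EmbeddingSpace:
    """A PCA embedding: orthonormal loadings and per-cell scores."""

    loadings: np.ndarray          # genes x PCs
    scores: np.ndarray            # cells x PCs
    variance_explained: np.ndarray
    mean_profile: np.ndarray      # per-gene anchor used for change profiles
    fitted_on: str = "integrated"

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[1]


def _svd_flip(u, vt):
    """Deterministic sign convention (largest |loading| positive)."""
    max_idx = np.argmax(np.abs(vt), axis=1)
    signs = np.sign(vt[np.arange(vt.shape[0]), max_idx])
    signs[signs == 0] = 1.0
    return u * signs[None, :], vt * signs[:, None]


def integrate_batches(residuals, batch, n_pcs: int = 200,
                      mean_profile=None) -> EmbeddingSpace:
    """Per-gene per-batch centring followed by joint PCA.

    ``n_pcs`` is capped at min(n_cells, n_genes) - 1.  ``mean_profile`` is
    the per-gene anchor added back when reconstructing denoised profiles for
    the change statistic (defaults to zero; pass the global mean of the
    log-normalised data for correlation on expression scale).
    """
    X = np.asarray(residuals, dtype=float)
    batch = np.asarray(batch)
    Xc = X.copy()
    for b in np.unique(batch):
        in_b = batch == b
        Xc[in_b] -= Xc[in_b].mean(axis=0)
    k = min(n_pcs, min(Xc.shape) - 1)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    u, vt = _svd_flip(u, vt)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    var = s ** 2 / max(Xc.shape[0] - 1, 1)
    if mean_profile is None:
        mean_profile = np.zeros(X.shape[1])
    return EmbeddingSpace(
        loadings=vt.T, scores=u * s[None, :],
        variance_explained=var, mean_profile=np.asarray(mean_profile, float),
    )


# ---------------------------------------------------------------------------
# Overall transcriptomic change
# ---------------------------------------------------------------------------

def transcriptomic_change(embedding: EmbeddingSpace, is_control):
    """Per-cell overall transcriptomic change.

    Each cell's rank-limited profile is reconstructed from its PC scores
    (scores @ loadings.T + mean_profile); the raw statistic is the negative
    Pearson correlation with the centroid of control profiles, and the
    reported change subtracts the control mean of the raw statistic so that
    controls average exactly zero.  Cells with zero-variance profiles get
    NaN and are flagged.
    """
    is_control = np.asarray(is_control, dtype=bool)
    if is_control.sum() < 2:
        raise ConfigurationError("need at least 2 control cells")
    profiles = embedding.scores @ embedding.loadings.T + embedding.mean_profile
    centroid = profiles[is_control].mean(axis=0)

    pc = profiles - profiles.mean(axis=1, keepdims=True)
    cc = centroid - centroid.mean()
    denom_c = np.linalg.norm(cc)
    denom_p = np.linalg.norm(pc, axis=1)
    bad = (denom_p == 0) | (denom_c == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (pc @ cc) / (denom_p * denom_c)
    corr[bad] = np.nan
    raw = -corr
    adjust = np.nanmean(raw[is_control])
    change = raw - adjust
    if bad.any():
        logger.warning("%d cells with zero-variance profiles flagged", bad.sum())
    return change


def minimal_functional_dose(doses, changes,
                            threshold: float = DEFAULT_CHANGE_THRESHOLD):
    """Smallest dose at which a monotone smoother of change first exceeds
    ``threshold``; ``None`` if the fitted curve never does.

    The smoother is isotonic (non-decreasing) regression of change on dose,
    evaluated at the observed doses.
    """
    doses = np.asarray(doses, float)
    changes = np.asarray(changes, float)
    ok = np.isfinite(doses) & np.isfinite(changes)
    doses, changes = doses[ok], changes[ok]
    if len(doses) < 10:
        raise ConfigurationError("need at least 10 cells")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(doses, changes)
    order = np.argsort(doses, kind="stable")
    above = fitted[order] > threshold
    if not above.any():
        return None
    return float(doses[order][np.argmax(above)])


# ---------------------------------------------------------------------------
# Housekeeping normalisation and physiological comparison
# ---------------------------------------------------------------------------

def normalize_to_housekeeping(values, hk_expression: pd.Series, hk_genes,
                              min_present: int = 5):
    """Divide ``values`` by the mean expression of a housekeeping gene set.

    ``hk_expression`` maps gene name -> expression level in the same context
    as ``values``.  Missing housekeeping genes are reported; at least
    ``min_present`` must remain.
    """
    hk_expression = pd.Series(hk_expression)
    present = [g for g in hk_genes if g in hk_expression.index]
    missing = [g for g in hk_genes if g not in hk_expression.index]
    if missing:
        logger.warning("housekeeping genes missing: %s", missing)
    if len(present) < min_present:
        raise ConfigurationError(
            f"only {len(present)} housekeeping genes present (< {min_present})")
    denom = float(hk_expression[present].mean())
    if denom == 0:
        raise ConfigurationError("housekeeping mean expression is zero")
    return np.asarray(values, float) / denom


def compare_physiological(min_dose, physio_table: dict,
                          quantile_band=(0.05, 0.95)):
    """Compare a TF's minimal functional dose with physiological levels.

    ``physio_table`` maps cell type -> array of (housekeeping-normalised)
    physiological expression values for the TF.  The comparison uses the
    5-95% quantile band of the top-expressing cell type (highest mean).
    Returns ``{"within_range", "top_cell_type", "band"}``; ``None`` when the
    table is empty or ``min_dose`` is None.
    """
    if min_dose is None or not physio_table:
        return None
    means = {ct: float(np.mean(v)) for ct, v in physio_table.items()}
    top = max(means, key=means.get)
    vals = np.asarray(physio_table[top], float)
    lo, hi = np.quantile(vals, quantile_band)
    return {
        "within_range": bool(lo <= min_dose <= hi),
        "top_cell_type": top,
        "band": (float(lo), float(hi)),
    }


# ---------------------------------------------------------------------------
# Cellular similarity and module scores
# ---------------------------------------------------------------------------

def pairwise_cell_similarity(scores, n_pcs: int = 50):
    """Pairwise Pearson correlation between cells in PC-score space.

    Returns a symmetric matrix with unit diagonal; rows with zero variance
    are NaN-flagged.
    """
    S = np.asarray(scores, float)[:, :n_pcs]
    if S.shape[0] < 2:
        raise ConfigurationError("need at least 2 cells")
    sd = S.std(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        C = np.corrcoef(S)
    C[sd == 0, :] = np.nan
    C[:, sd == 0] = np.nan
    np.fill_diagonal(C, np.where(sd == 0, np.nan, 1.0))
    return C


def module_score(X, gene_names, gene_set, n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0):
    """Bin-matched module score (mean of set minus matched random controls).

    Genes are binned by mean expression (``n_bins`` equal-size rank bins,
    ties broken by gene index); for each set gene, ``n_ctrl`` control genes
    are sampled without replacement from its bin (the whole bin if smaller).
    The per-cell score is mean(set) - mean(controls).
    """
    X = X.toarray() if sp.issparse(X) else np.asarray(X, float)
    gene_names = list(gene_names)
    gene_set = [g for g in gene_set]
    idx_of = {g: i for i, g in enumerate(gene_names)}
    missing = [g for g in gene_set if g not in idx_of]
    if missing:
        raise ConfigurationError(f"module genes absent from panel: {missing[:5]}")
    set_idx = np.array([idx_of[g] for g in gene_set])
    if set_idx.size < 2:
        raise ConfigurationError("module needs at least 2 genes")

    mean_expr = X.mean(axis=0)
    order = np.lexsort((np.arange(len(gene_names)), mean_expr))
    bins = np.empty(len(gene_names), dtype=int)
    bins[order] = (np.arange(len(gene_names)) * n_bins) // len(gene_names)

    rng = np.random.default_rng(seed)
    ctrl_idx = []
    for g in set_idx:
        pool = np.where(bins == bins[g])[0]
        pool = pool[pool != g]
        take = min(n_ctrl, pool.size)
        ctrl_idx.append(rng.choice(pool, size=take, replace=False))
    ctrl_idx = np.unique(np.concatenate(ctrl_idx))
    return X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)


# ---------------------------------------------------------------------------
# Convenience: full embedding pipeline
# ---------------------------------------------------------------------------

def control_referenced_embedding(counts, is_control, batch, n_pcs: int = 200,
                                 k_ctrl: int = 20) -> EmbeddingSpace:
    """normalise -> regress control heterogeneity -> integrate -> PCA.

    The global mean of the log-normalised matrix is retained as the anchor
    profile for the change statistic.
    """
    X, zero = normalize_log1p(counts)
    if zero.any():
        # flagged cells stay in the matrix but carry zero profiles
        pass
    resid = regress_control_heterogeneity(X, is_control, batch, k_ctrl=k_ctrl)
    return integrate_batches(resid, batch, n_pcs=n_pcs,
                             mean_profile=X.mean(axis=0))
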