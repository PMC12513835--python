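"""Dose-dependent dominance, unique states and synergy for TF pairs.

Dual-TF cells are compared with single-TF and control cells in a PC
embedding (first 20 dimensions): for each dual-TF cell the five nearest
neighbours are found and the neighbour-group composition recorded.  A TF
dominates its partner when dual cells sit mostly next to its single-TF
cells.  Dual cells whose neighbourhoods are mostly dual cells define a
candidate unique combinatorial state; genes distinguishing them from their
closest single-TF matches at FDR < 0.05 and |fold change| > 1.5 are the
unique-state genes.  Doses of both TFs are binned (four uniform bins plus a
zero bin) to resolve how dominance and module scores shift across the dose
plane, and per-bin synergy/antagonism is called by comparing the dual-cell
mean with the matched single-TF bins via a bootstrap confidence interval.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .heterogeneity import differential_expression

logger = logging.getLogger(__name__)

GROUP_COMBO = "TF1+TF2"
GROUP_TF1 = "TF1"
GROUP_TF2 = "TF2"
GROUP_CONTROL = "control"
GROUPS = (GROUP_TF1, GROUP_TF2, GROUP_COMBO, GROUP_CONTROL)


# ---------------------------------------------------------------------------
# Nearest-neighbour group composition
# ---------------------------------------------------------------------------

def _knn_indices(scores, query_idx, candidate_mask=None, k: int = 5):
    """k nearest candidates for each query cell (self excluded), exhaustive
    distances with stable index tie-breaking."""
    scores = np.asarray(scores, float)
    n = scores.shape[0]
    cand = np.arange(n) if candidate_mask is None else np.where(candidate_mask)[0]
    D = cdist(scores[query_idx], scores[cand])
    out = np.empty((len(query_idx), k), dtype=int)
    for r, qi in enumerate(query_idx):
        d = D[r].copy()
        self_pos = np.where(cand == qi)[0]
        if self_pos.size:
            d[self_pos[0]] = np.inf
        order = np.argsort(d, kind="stable")[:k]
        out[r] = cand[order]
    return out


def knn_group_fractions(scores, groups, k: int = 5,
                        query_group: str = GROUP_COMBO):
    """Neighbour-group fractions for each dual-TF cell.

    For every cell of ``query_group``, its ``k`` nearest neighbours among
    all cells (excluding itself; 20-PC Euclidean distances, ties broken by
    cell index) are tallied by group.  Returns ``(per_cell, mean)``: a
    DataFrame of per-cell fractions over groups (rows sum to 1) and the
    mean fraction per group.
    """
    scores = np.asarray(scores, float)[:, :20]
    groups = np.asarray(groups, dtype=object)
    n = len(groups)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} cells")
    q_idx = np.where(groups == query_group)[0]
    if q_idx.size == 0:
        raise ValueError(f"no cells in query group {query_group!r}")
    nn = _knn_indices(scores, q_idx, k=k)
    labels = sorted(pd.unique(groups), key=list(GROUPS).index) \
        if set(groups) <= set(GROUPS) else sorted(pd.unique(groups))
    fracs = pd.DataFrame(0.0, index=q_idx, columns=labels)
    for r, qi in enumerate(q_idx):
        for j in nn[r]:
            fracs.loc[qi, groups[j]] += 1.0 / k
    return fracs, fracs.mean(axis=0)


def dominance_network(pair_fractions: dict, dominance_margin: float = 0.5):
    """Directed dominance edges from per-pair mean neighbour fractions.

    ``pair_fractions`` maps (tf1, tf2) -> mean fraction Series over groups.
    An edge tfA -> tfB (tfA dominates) is drawn when the mean fraction of
    dual cells closest to tfA's singles exceeds ``dominance_margin`` and
    exceeds tfB's fraction; strength is the fraction difference.
    """
    rows = []
    for (tf1, tf2), frac in pair_fractions.items():
        f1 = float(frac.get(GROUP_TF1, 0.0))
        f2 = float(frac.get(GROUP_TF2, 0.0))
        if f1 > dominance_margin and f1 > f2:
            rows.append({"winner": tf1, "loser": tf2, "strength": f1 - f2,
                         "winner_frac": f1, "loser_frac": f2})
        elif f2 > dominance_margin and f2 > f1:
            rows.append({"winner": tf2, "loser": tf1, "strength": f2 - f1,
                         "winner_frac": f2, "loser_frac": f1})
    return pd.DataFrame(rows, columns=["winner", "loser", "strength",
                                       "winner_frac", "loser_frac"])


# ---------------------------------------------------------------------------
# Dose binning
# ---------------------------------------------------------------------------

def dose_bin(doses, max_dose: float, n_bins: int = 4) -> np.ndarray:
    """Bin doses into a zero bin plus ``n_bins`` uniform half-open intervals.

    Label 0 for dose exactly 0; labels 1..n for (0, M/n], (M/n, 2M/n], ...,
    ((n-1)M/n, M].  Doses above ``max_dose`` are clamped with a warning.
    """
    d = np.asarray(doses, float)
    if (d < 0).any():
        raise ValueError("doses must be non-negative")
    if (d > max_dose).any():
        logger.warning("%d doses above max_dose clamped", int((d > max_dose).sum()))
        d = np.minimum(d, max_dose)
    width = max_dose / n_bins
    bins = np.where(d == 0, 0, np.ceil(d / width).astype(int))
    return np.clip(bins, 0, n_bins).astype(int)


def binned_dominance(per_cell_fracs: pd.DataFrame, bins1, bins2,
                     min_cells: int = 3):
    """Mean neighbour fractions per (bin1, bin2) dose-bin pair.

    ``per_cell_fracs`` is the per-dual-cell fraction table; ``bins1``/
    ``bins2`` are that table's cells' dose bins for TF1 and TF2.  Bin pairs
    with fewer than ``min_cells`` cells are masked (NaN).  Returns a long
    DataFrame with one row per populated bin pair.
    """
    bins1 = np.asarray(bins1, int)
    bins2 = np.asarray(bins2, int)
    rows = []
    for b1 in np.unique(bins1):
        for b2 in np.unique(bins2):
            sel = (bins1 == b1) & (bins2 == b2)
            n = int(sel.sum())
            rec = {"bin1": int(b1), "bin2": int(b2), "n": n}
            sub = per_cell_fracs.iloc[sel]
            for col in per_cell_fracs.columns:
                rec[f"frac_{col}"] = float(sub[col].mean()) if n >= min_cells else np.nan
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Unique combinatorial states
# ---------------------------------------------------------------------------

def unique_state_genes(counts, groups, scores, batch=None, gene_names=None,
                       k: int = 5, self_frac_min: float = 0.5,
                       fdr_cutoff: float = 0.05, fc_cutoff: float = 1.5):
    """Genes unique to the dual-TF state.

    Qualifying dual cells have at least ``self_frac_min`` dual-cell
    neighbours among their ``k`` nearest (all-group search).  Their closest
    matches within the TF1 and TF2 groups (k-NN restricted to those groups)
    form the comparator; genes with FDR < ``fdr_cutoff`` and |fold change| >
    ``fc_cutoff`` in dual vs comparator are returned.
    Returns ``(de_table, unique_genes, info)``; empty when no cells qualify.
    """
    scores = np.asarray(scores, float)[:, :20]
    groups = np.asarray(groups, dtype=object)
    q_idx = np.where(groups == GROUP_COMBO)[0]
    per_cell, _ = knn_group_fractions(scores, groups, k=k)
    qualifying = per_cell.index[per_cell[GROUP_COMBO] >= self_frac_min].values
    info = {"n_combo": int(q_idx.size), "n_qualifying": int(len(qualifying))}
    if len(qualifying) < 3:
        info["reason"] = "fewer than 3 qualifying dual-TF cells"
        return pd.DataFrame(), [], info

    single_mask = (groups == GROUP_TF1) | (groups == GROUP_TF2)
    matches = _knn_indices(scores, qualifying, candidate_mask=single_mask, k=k)
    comparator = np.unique(matches.ravel())
    info["n_comparator"] = int(comparator.size)

    sel = np.concatenate([qualifying, comparator])
    lab = np.array(["comparator"] * len(sel), dtype=object)
    lab[: len(qualifying)] = "combo"
    sub_counts = counts[sel] if not hasattr(counts, "iloc") else counts.iloc[sel]
    sub_batch = np.asarray(batch)[sel] if batch is not None else None
    de = differential_expression(sub_counts, lab, batch=sub_batch,
                                 gene_names=gene_names)
    lfc_cut = np.log2(fc_cutoff)
    hit = (de["fdr"] < fdr_cutoff) & (de["log2fc"].abs() > lfc_cut) & ~de["flagged"]
    return de, list(de.loc[hit, "gene"]), info


# ---------------------------------------------------------------------------
# Per-bin synergy calls
# ---------------------------------------------------------------------------

def gene_synergy(values, groups, bins1, bins2, n_boot: int = 1000,
                 seed: int = 0, min_cells: int = 3, ci: float = 0.95):
    """Per dose-bin synergy/antagonism of a gene or module value.

    For each (bin1, bin2) pair with >= ``min_cells`` dual cells, the dual
    mean is compared with single-TF cells in the matched marginal bins:
    synergy when the bootstrap CI of the dual mean lies above the larger
    single mean, antagonism when below the smaller, otherwise additive;
    missing single-TF cells give "indeterminate".
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups, dtype=object)
    bins1 = np.asarray(bins1, int)
    bins2 = np.asarray(bins2, int)
    rng = np.random.default_rng(seed)
    a = (1 - ci) / 2
    combo = groups == GROUP_COMBO
    rows = []
    for b1 in np.unique(bins1[combo]):
        for b2 in np.unique(bins2[combo]):
            sel = combo & (bins1 == b1) & (bins2 == b2)
            n = int(sel.sum())
            if n < min_cells:
                continue
            v = values[sel]
            s1 = values[(groups == GROUP_TF1) & (bins1 == b1)]
            s2 = values[(groups == GROUP_TF2) & (bins2 == b2)]
            rec = {"bin1": int(b1), "bin2": int(b2), "n": n,
                   "combo_mean": float(v.mean()),
                   "tf1_mean": float(s1.mean()) if s1.size >= min_cells else np.nan,
                   "tf2_mean": float(s2.mean()) if s2.size >= min_cells else np.nan}
            if s1.size < min_cells or s2.size < min_cells:
                rec["call"] = "indeterminate"
            else:
                boots = np.array([
                    v[rng.integers(0, n, size=n)].mean() for _ in range(n_boot)])
                lo, hi = np.quantile(boots, [a, 1 - a])
                upper = max(rec["tf1_mean"], rec["tf2_mean"])
                lower = min(rec["tf1_mean"], rec["tf2_mean"])
                if lo > upper:
                    rec["call"] = "synergy"
                elif hi < lower:
                    rec["call"] = "antagonism"
                else:
                    rec["call"] = "additive"
                rec["ci_lo"], rec["ci_hi"] = float(lo), float(hi)
            rows.append(rec)
    return pd.DataFrame(rows)
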