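"""TF-ID library validation, cell-to-TF assignment, dose and QC filtering.

The enrichment library yields a TF-ID x cell UMI matrix.  Within one
experiment all retained TF-ID barcodes must be separated by Hamming distance
greater than 2; each cell is then assigned to its dominant TF-ID (or called a
doublet / left unassigned), and the exogenous TF dose is defined as
ln(1 + UMIs of the assigned TF-ID).  Quality control removes cells with
excessive mitochondrial or ribosomal content, too few protein-coding genes,
or outlying low total counts (median - nmads * MAD on the log scale, lower
tail only), and drops TFs left with fewer than ``min_cells_per_tf`` cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .simdata import CONTROL_TF

ASSIGN_DOUBLET = "doublet"
ASSIGN_UNASSIGNED = "unassigned"


class FormatError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Library validation
# ---------------------------------------------------------------------------

def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise FormatError(f"barcode lengths differ: {a!r} vs {b!r}")
    return sum(x != y for x, y in zip(a, b))


def validate_tfid_library(tfids: pd.DataFrame, min_distance: int = 3) -> dict:
    """Check pairwise Hamming distances of TF-ID barcodes.

    Returns a report with flagged pairs (distance <= ``min_distance - 1``)
    and the retained set: a barcode is retained iff it is not involved in
    any flagged pair.
    """
    seqs = list(tfids["barcode"])
    names = list(tfids["name"]) if "name" in tfids else seqs
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise FormatError(f"barcodes of unequal length: {sorted(lengths)}")
    flagged = []
    bad = set()
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            d = hamming(seqs[i], seqs[j])
            if d < min_distance:
                flagged.append((names[i], names[j], d))
                bad.add(names[i])
                bad.add(names[j])
    retained = [n for n in names if n not in bad]
    return {"flagged_pairs": flagged, "retained": retained,
            "n_total": len(names), "n_retained": len(retained)}


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

@dataclass
class AssignParams:
    """TF-ID assignment thresholds.

    ``min_umi``: minimum UMIs of the top TF-ID for any assignment.
    ``ratio_max``: a cell is a doublet when the second TF-ID also reaches
    ``min_umi`` and second/first >= ``ratio_max``.
    """

    min_umi: int = 2
    ratio_max: float = 0.2


def assign_tf(tfid_counts, tfid_names, params: AssignParams | None = None,
              cell_ids=None) -> pd.DataFrame:
    """Assign each cell to a TF, control, doublet or unassigned.

    ``tfid_counts`` is cells x TF-IDs (dense or sparse, non-negative ints).
    Returns a cell table fragment with ``assigned_tf`` and ``dose``
    (ln(1 + UMIs of the assigned TF-ID); NaN for doublets/unassigned).
    """
    if params is None:
        params = AssignParams()
    X = tfid_counts.toarray() if sp.issparse(tfid_counts) else np.asarray(tfid_counts)
    if X.size == 0:
        raise FormatError("empty TF-ID count matrix")
    if (X < 0).any():
        raise FormatError("negative TF-ID counts")
    n_cells = X.shape[0]
    order = np.argsort(-X, axis=1, kind="stable")
    top = order[:, 0]
    first = X[np.arange(n_cells), top]
    second = X[np.arange(n_cells), order[:, 1]] if X.shape[1] > 1 else np.zeros(n_cells)

    names = np.asarray(tfid_names, dtype=object)
    assigned = names[top].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(first > 0, second / np.maximum(first, 1), 0.0)
    is_doublet = (first >= params.min_umi) & (second >= params.min_umi) & \
        (ratio >= params.ratio_max)
    is_unassigned = first < params.min_umi
    assigned[is_doublet] = ASSIGN_DOUBLET
    assigned[is_unassigned] = ASSIGN_UNASSIGNED
    dose = np.log1p(first.astype(float))
    dose[is_doublet | is_unassigned] = np.nan

    out = pd.DataFrame({
        "assigned_tf": assigned,
        "dose": dose,
        "tfid_umi": first,
        "second_umi": second,
    })
    if cell_ids is not None:
        out.insert(0, "cell_id", list(cell_ids))
    return out


def assign_pair_groups(tfid_counts, tfid_names, tf1: str, tf2: str,
                       umi_min: int = 4) -> np.ndarray:
    """Group cells of a TF-pair experiment by the strict >4-UMI rule.

    Returns one of {"TF1+TF2", "TF1", "TF2", "control"} per cell:
    both TF-IDs > ``umi_min`` UMIs -> "TF1+TF2"; only one -> that TF;
    neither -> "control".
    """
    if tf1 == tf2:
        raise ConfigurationError("tf1 and tf2 must differ")
    names = list(tfid_names)
    for t in (tf1, tf2):
        if t not in names:
            raise ConfigurationError(f"TF {t!r} absent from TF-ID library")
    X = tfid_counts.toarray() if sp.issparse(tfid_counts) else np.asarray(tfid_counts)
    c1 = X[:, names.index(tf1)]
    c2 = X[:, names.index(tf2)]
    g1, g2 = c1 > umi_min, c2 > umi_min
    out = np.where(g1 & g2, "TF1+TF2",
                   np.where(g1, "TF1", np.where(g2, "TF2", "control")))
    return out.astype(object)


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

@dataclass
class QCThresholds:
    mito_max: float = 0.15
    ribo_max: float = 0.60
    coding_min: float = 0.75
    nmads: float = 4.0
    min_cells_per_tf: int = 8


def qc_filter(counts, gene_flags: pd.DataFrame, cells: pd.DataFrame,
              thresholds: QCThresholds | None = None):
    """Per-cell QC mask with per-rule attribution.

    ``counts`` is cells x genes; ``gene_flags`` must provide boolean columns
    ``is_mito``, ``is_ribo``, ``is_coding``; ``cells`` must provide
    ``assigned_tf``.  A cell passes iff it passes the mito/ribo/coding
    fraction rules, is not a lower-tail outlier on log total counts
    (median - nmads * MAD), and its assigned TF retains at least
    ``min_cells_per_tf`` cells after the per-cell rules.
    Returns ``(mask_df, report)``.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    for col in ("is_mito", "is_ribo", "is_coding"):
        if col not in gene_flags:
            raise ConfigurationError(f"gene flag column {col!r} missing")
    X = counts.tocsr() if sp.issparse(counts) else sp.csr_matrix(counts)
    total = np.asarray(X.sum(axis=1)).ravel()
    if (total == 0).any():
        # all-zero cells fail every fraction rule by convention
        total_safe = np.maximum(total, 1)
    else:
        total_safe = total

    def frac(flag):
        idx = np.where(gene_flags[flag].values)[0]
        return np.asarray(X[:, idx].sum(axis=1)).ravel() / total_safe

    mito_frac = frac("is_mito")
    ribo_frac = frac("is_ribo")
    coding_frac = frac("is_coding")

    fail_mito = mito_frac > thresholds.mito_max
    fail_ribo = ribo_frac > thresholds.ribo_max
    fail_coding = coding_frac < thresholds.coding_min

    log_total = np.log1p(total)
    med = np.median(log_total)
    mad = np.median(np.abs(log_total - med))
    cutoff = med - thresholds.nmads * mad
    fail_outlier = log_total < cutoff

    pass_cell = ~(fail_mito | fail_ribo | fail_coding | fail_outlier)

    # TF-level minimum-cell rule on survivors of the per-cell rules
    tf_labels = cells["assigned_tf"].values
    surviving = pd.Series(tf_labels[pass_cell])
    counts_per_tf = surviving.value_counts()
    small_tfs = {
        t for t, n in counts_per_tf.items()
        if n < thresholds.min_cells_per_tf
        and t not in (CONTROL_TF, ASSIGN_DOUBLET, ASSIGN_UNASSIGNED)
    }
    # TFs with no surviving cells at all are also below the minimum
    for t in set(tf_labels):
        if t not in counts_per_tf.index and t not in (
                CONTROL_TF, ASSIGN_DOUBLET, ASSIGN_UNASSIGNED):
            small_tfs.add(t)
    fail_min_cells = np.array([t in small_tfs for t in tf_labels])
    qc_pass = pass_cell & ~fail_min_cells

    mask = pd.DataFrame({
        "qc_pass": qc_pass,
        "fail_mito": fail_mito,
        "fail_ribo": fail_ribo,
        "fail_coding": fail_coding,
        "fail_outlier": fail_outlier,
        "fail_min_cells": fail_min_cells,
        "mito_frac": mito_frac,
        "ribo_frac": ribo_frac,
        "coding_frac": coding_frac,
        "total_counts": total,
    })
    if "cell_id" in cells:
        mask.insert(0, "cell_id", cells["cell_id"].values)
    report = {
        "n_cells": int(len(mask)),
        "n_pass": int(qc_pass.sum()),
        "n_fail_mito": int(fail_mito.sum()),
        "n_fail_ribo": int(fail_ribo.sum()),
        "n_fail_coding": int(fail_coding.sum()),
        "n_fail_outlier": int(fail_outlier.sum()),
        "n_fail_min_cells": int(fail_min_cells.sum()),
        "dropped_tfs": sorted(small_tfs),
        "log_total_cutoff": float(cutoff),
        "thresholds": vars(thresholds),
    }
    return mask, report
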