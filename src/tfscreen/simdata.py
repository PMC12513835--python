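"""Synthetic TF-overexpression screen generator with known ground truth.

Emulates a pooled single-cell TF overexpression experiment: each cell carries
one barcoded TF construct (its "TF-ID") detected in a dedicated enrichment
library, and the exogenous TF dose -- ln(1 + TF-ID UMIs) -- spans a wide range
from silenced (~0) to strong overexpression (~8 ln-UMI units).  Gene counts
follow a negative-binomial model whose per-module log-mean shifts with dose
according to a TF-specific response curve (logistic, non-monotonic, or
branching into mutually exclusive programs).  mCherry control cells carry a
dose but no transcriptomic effect.  Batch effects, doublets, ambient TF-ID
UMIs, and dose-coupled cell-cycle programs are simulated so that every
downstream stage of the pipeline can be tested against known truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

CONTROL_TF = "mCherry"

#: TF capacity/sensitivity classes used throughout.
CLASS_HIGH_SENSITIVE = "high_capacity_high_sensitivity"
CLASS_HIGH_INSENSITIVE = "high_capacity_low_sensitivity"
CLASS_LOW = "low_capacity"
TF_CLASSES = (CLASS_HIGH_SENSITIVE, CLASS_HIGH_INSENSITIVE, CLASS_LOW)

RESPONSE_LOGISTIC = "logistic"
RESPONSE_NON_MONOTONIC = "non_monotonic"
RESPONSE_BRANCH = "branch"

CC_NONE = "none"
CC_MONOTONIC = "monotonic"
CC_NON_MONOTONIC = "non_monotonic"

PHASES = ("G1", "S", "G2M")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of the simulated screen.

    Defaults are desk-scale study conditions: ~120 cells per TF, doses on the
    ln(1+UMI) scale spanning 0 to ~8, negative-binomial counts with
    gene-specific dispersion, two batches with mild multiplicative batch
    effects, a small doublet fraction and a low ambient TF-ID rate.
    """

    n_tfs: int = 9
    class_proportions: tuple = (1 / 3, 1 / 3, 1 / 3)
    n_genes: int = 1800
    genes_per_module: int = 120
    n_batches: int = 2
    n_control_cells_per_batch: int = 150

    # dose model: point mass near zero (uninfected/silenced) + log-normal UMI
    dose_max: float = 8.0
    zero_dose_frac: float = 0.12
    dose_log_mean: float = 3.2
    dose_log_sd: float = 1.5

    # counts
    mean_total_umis: float = 4000.0
    size_factor_sd: float = 0.25
    dispersion_log_mean: float = float(np.log(0.1))
    dispersion_log_sd: float = 0.5
    batch_effect_sd: float = 0.15

    # artefacts
    doublet_rate: float = 0.03
    ambient_rate: float = 0.01

    # control-cell structured heterogeneity (confluence-like latent factors)
    n_latent_factors: int = 3
    latent_scale: float = 0.35

    # expression amplitude: rms log-fold-change at plateau per unit of
    # planted capacity K (K is on the overall-transcriptomic-change scale)
    expr_gain: float = 6.0

    # response-shape composition among the high-capacity TFs
    n_branch_tfs: int = 0
    n_nonmono_tfs: int = 0
    branch_prob: float = 0.5

    # cell cycle
    cc_genes_per_program: int = 40
    cc_base_cycling: float = 0.25
    cc_amp: float = 1.6
    n_cc_monotonic_tfs: int = 0
    n_cc_nonmono_tfs: int = 0

    barcode_length: int = 10

    def validate(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class_proportions must sum to 1, got {self.class_proportions}"
            )
        for name in ("zero_dose_frac", "doublet_rate", "ambient_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ConfigurationError("branch_prob must be in [0, 1]")
        n_special = self.n_branch_tfs + self.n_nonmono_tfs
        n_high = round(self.n_tfs * (self.class_proportions[0] + self.class_proportions[1]))
        if n_special > n_high:
            raise ConfigurationError(
                "n_branch_tfs + n_nonmono_tfs exceeds the number of high-capacity TFs"
            )
        n_module_genes = self.n_tfs * self.genes_per_module + self.n_branch_tfs * self.genes_per_module
        n_module_genes += 2 * self.cc_genes_per_program
        if n_module_genes > 0.85 * self.n_genes:
            raise ConfigurationError(
                f"gene panel too small: {n_module_genes} module genes for "
                f"{self.n_genes} genes; increase n_genes or shrink modules"
            )


@dataclass
class TFParams:
    name: str
    tf_class: str
    baseline: float          # a, change units
    plateau: float           # K, change units
    midpoint: float          # d50, ln-UMI units
    slope: float             # s, per ln-UMI unit
    response_shape: str = RESPONSE_LOGISTIC
    cc_coupling: str = CC_NONE


@dataclass
class GroundTruth:
    """Generative parameters of one simulated screen."""

    config: SimConfig
    seed: int
    tf_params: dict                 # name -> TFParams
    modules: dict                   # name -> list of gene-index arrays (1 or 2)
    module_weights: dict            # name -> list of per-gene plateau log-FCs
    gene_names: list
    gene_baseline: np.ndarray       # relative expression, sums to 1
    gene_dispersion: np.ndarray
    batch_factors: np.ndarray       # (n_batches, n_genes) multiplicative
    latent_loadings: np.ndarray     # (n_factors, n_genes)
    s_genes: np.ndarray             # indices
    g2m_genes: np.ndarray
    gene_flags: pd.DataFrame        # is_mito / is_ribo / is_coding
    barcodes: dict                  # tf name -> barcode sequence
    doublet_rate: float = 0.0
    ambient_rate: float = 0.0
    combo_params: dict = field(default_factory=dict)   # (tf1, tf2) -> rule dict

    @property
    def tf_names(self):
        return [n for n in self.tf_params if n != CONTROL_TF]


@dataclass
class SimulatedExperiment:
    """A simulated screen: expression + TF-ID enrichment + per-cell truth."""

    counts: sp.csr_matrix           # cells x genes, raw UMIs
    genes: pd.DataFrame             # name + flags
    tfid_counts: sp.csr_matrix      # cells x TF-IDs (post-ambient)
    tfids: pd.DataFrame             # name + barcode
    truth: pd.DataFrame             # per-cell ground truth
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# Response curves
# ---------------------------------------------------------------------------

def logistic_response(dose, plateau, midpoint, slope, baseline=0.0):
    """Four-parameter logistic a + K / (1 + exp(-s (d - d50)))."""
    dose = np.asarray(dose, dtype=float)
    return baseline + plateau / (1.0 + np.exp(-slope * (dose - midpoint)))


def _unit_response(tf: TFParams, dose):
    """Response normalised to [0, 1] at plateau (shape only, no K)."""
    d = np.asarray(dose, dtype=float)
    rise = 1.0 / (1.0 + np.exp(-tf.slope * (d - tf.midpoint)))
    if tf.response_shape == RESPONSE_NON_MONOTONIC:
        # difference of two logistics: peak near d50, decline at high dose
        fall = 1.0 / (1.0 + np.exp(-tf.slope * (d - (tf.midpoint + 2.5))))
        return rise - 0.85 * fall
    return rise


def true_effect(tf: TFParams, dose):
    """Planted effect magnitude on the transcriptomic-change scale."""
    return tf.baseline + tf.plateau * _unit_response(tf, dose)


# ---------------------------------------------------------------------------
# Ground-truth construction
# ---------------------------------------------------------------------------

def _random_barcodes(rng, n, length):
    """Random DNA barcodes with pairwise Hamming distance > 2."""
    alphabet = np.array(list("ACGT"))
    chosen = []
    while len(chosen) < n:
        cand = "".join(rng.choice(alphabet, size=length))
        ok = all(sum(a != b for a, b in zip(cand, prev)) > 2 for prev in chosen)
        if ok:
            chosen.append(cand)
    return chosen


def simulate_ground_truth(config: SimConfig, seed: int) -> GroundTruth:
    """Draw the generative parameters of a screen.

    Deterministic for fixed ``(config, seed)``.  Class counts follow
    ``config.class_proportions`` exactly (largest-remainder rounding); every
    TF carries one class label consistent with its (K, d50).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))

    # --- class sizes by largest remainder so proportions are exact
    raw = np.array(config.class_proportions) * config.n_tfs
    sizes = np.floor(raw).astype(int)
    remainder = config.n_tfs - sizes.sum()
    order = np.argsort(-(raw - sizes))
    sizes[order[:remainder]] += 1

    tf_params = {}
    classes = (
        [CLASS_HIGH_SENSITIVE] * sizes[0]
        + [CLASS_HIGH_INSENSITIVE] * sizes[1]
        + [CLASS_LOW] * sizes[2]
    )
    for i, cls in enumerate(classes):
        name = f"TF{i + 1:03d}"
        if cls == CLASS_HIGH_SENSITIVE:
            K = rng.uniform(0.6, 1.0)
            d50 = rng.uniform(0.8, 2.0)
            s = rng.uniform(1.5, 4.0)
        elif cls == CLASS_HIGH_INSENSITIVE:
            K = rng.uniform(0.6, 1.0)
            d50 = rng.uniform(3.5, 5.0)
            s = rng.uniform(1.5, 4.0)
        else:
            K = rng.uniform(0.0, 0.12)
            d50 = rng.uniform(1.0, 5.0)
            s = rng.uniform(0.5, 3.0)
        a = rng.uniform(-0.02, 0.02)
        tf_params[name] = TFParams(name, cls, a, K, d50, s)

    # response shapes among high-capacity TFs (branch / non-monotonic);
    # high-sensitivity TFs first so branching falls inside the attainable
    # dose range (their functional cells dominate the per-TF population)
    high_names = [n for n, p in tf_params.items() if p.tf_class != CLASS_LOW]
    high_names.sort(key=lambda n: (tf_params[n].tf_class != CLASS_HIGH_SENSITIVE,
                                   tf_params[n].midpoint))
    n_special = config.n_branch_tfs + config.n_nonmono_tfs
    special = high_names[:n_special]
    for n in special[: config.n_branch_tfs]:
        tf_params[n].response_shape = RESPONSE_BRANCH
    for n in special[config.n_branch_tfs:]:
        tf_params[n].response_shape = RESPONSE_NON_MONOTONIC

    # cell-cycle coupling
    couple_pool = [n for n in high_names if n not in special[: config.n_branch_tfs]]
    n_cc = config.n_cc_monotonic_tfs + config.n_cc_nonmono_tfs
    cc_pick = rng.choice(couple_pool, size=min(n_cc, len(couple_pool)), replace=False) if n_cc else []
    for n in cc_pick[: config.n_cc_monotonic_tfs]:
        tf_params[n].cc_coupling = CC_MONOTONIC
    for n in cc_pick[config.n_cc_monotonic_tfs:]:
        tf_params[n].cc_coupling = CC_NON_MONOTONIC

    tf_params[CONTROL_TF] = TFParams(CONTROL_TF, CLASS_LOW, 0.0, 0.0, 1.0, 1.0)

    # --- gene panel: per-TF modules (disjoint), cell-cycle programs, nulls
    gene_names = [f"Gene{j + 1:05d}" for j in range(config.n_genes)]
    cursor = 0
    modules, module_weights = {}, {}
    gpm = config.genes_per_module
    for name in tf_params:
        if name == CONTROL_TF:
            modules[name], module_weights[name] = [], []
            continue
        n_mod = 2 if tf_params[name].response_shape == RESPONSE_BRANCH else 1
        idx_list, w_list = [], []
        for _ in range(n_mod):
            idx = np.arange(cursor, cursor + gpm)
            cursor += gpm
            # mixed-sign plateau log-FCs, rms 1: mostly activation of a
            # silent program plus some repression of expressed genes
            sign = np.where(rng.random(gpm) < 0.75, 1.0, -1.0)
            w = sign * rng.uniform(0.5, 1.5, size=gpm)
            w /= np.sqrt(np.mean(w ** 2))
            idx_list.append(idx)
            w_list.append(w)
        modules[name] = idx_list
        module_weights[name] = w_list

    s_genes = np.arange(cursor, cursor + config.cc_genes_per_program)
    cursor += config.cc_genes_per_program
    g2m_genes = np.arange(cursor, cursor + config.cc_genes_per_program)
    cursor += config.cc_genes_per_program

    # --- baselines, dispersions, batch factors, latent factors
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    # activated program genes start low (silent before reprogramming)
    for name, idx_list in modules.items():
        for idx, w in zip(idx_list, module_weights[name]):
            up = idx[w > 0]
            base[up] = rng.lognormal(mean=-1.2, sigma=0.6, size=up.size)
    base /= base.sum()

    dispersion = rng.lognormal(config.dispersion_log_mean, config.dispersion_log_sd,
                               size=config.n_genes)
    batch_factors = np.exp(rng.normal(0.0, config.batch_effect_sd,
                                      size=(config.n_batches, config.n_genes)))

    latent = np.zeros((config.n_latent_factors, config.n_genes))
    null_start = cursor
    null_idx = np.arange(null_start, config.n_genes)
    for f in range(config.n_latent_factors):
        pick = rng.choice(null_idx, size=min(120, null_idx.size), replace=False)
        latent[f, pick] = rng.normal(0.0, config.latent_scale, size=pick.size)

    # --- gene flags: mito / ribo among null genes, ~3% non-coding
    flags = pd.DataFrame(
        {"name": gene_names, "is_mito": False, "is_ribo": False, "is_coding": True}
    )
    n_mito, n_ribo = 13, 60
    mito_idx = null_idx[:n_mito]
    ribo_idx = null_idx[n_mito:n_mito + n_ribo]
    flags.loc[mito_idx, "is_mito"] = True
    flags.loc[ribo_idx, "is_ribo"] = True
    noncoding = rng.choice(
        null_idx[n_mito + n_ribo:], size=max(1, config.n_genes // 33), replace=False
    )
    flags.loc[noncoding, "is_coding"] = False
    # give mito/ribo genes realistic expression shares (~5% / ~15%)
    base[mito_idx] = 0.05 / n_mito
    base[ribo_idx] = 0.15 / n_ribo
    base /= base.sum()

    barcodes = dict(zip(tf_params, _random_barcodes(rng, len(tf_params),
                                                    config.barcode_length)))

    return GroundTruth(
        config=config, seed=seed, tf_params=tf_params, modules=modules,
        module_weights=module_weights, gene_names=gene_names,
        gene_baseline=base, gene_dispersion=dispersion,
        batch_factors=batch_factors, latent_loadings=latent,
        s_genes=s_genes, g2m_genes=g2m_genes, gene_flags=flags,
        barcodes=barcodes, doublet_rate=config.doublet_rate,
        ambient_rate=config.ambient_rate,
    )


# ---------------------------------------------------------------------------
# Experiment simulation
# ---------------------------------------------------------------------------

def _draw_umis(rng, n, config: SimConfig):
    """TF-ID UMI counts: point mass near 0 + log-normal tail, capped at
    exp(dose_max) - 1 so doses live on [0, dose_max]."""
    silenced = rng.random(n) < config.zero_dose_frac
    umis = np.round(rng.lognormal(config.dose_log_mean, config.dose_log_sd, size=n))
    umis = np.minimum(umis, np.expm1(config.dose_max))
    umis[silenced] = rng.poisson(0.3, size=silenced.sum())
    return umis.astype(np.int64)


def _draw_phases(rng, tf: TFParams, doses, config: SimConfig):
    base = config.cc_base_cycling
    unit = _unit_response(dataclasses.replace(tf, response_shape=RESPONSE_LOGISTIC), doses)
    if tf.cc_coupling == CC_MONOTONIC:
        p_cyc = base + (0.85 - base) * unit
    elif tf.cc_coupling == CC_NON_MONOTONIC:
        d = np.asarray(doses, float)
        bump = np.exp(-0.5 * ((d - tf.midpoint) / 1.0) ** 2)
        p_cyc = base + (0.85 - base) * bump
    else:
        p_cyc = np.full(len(doses), base)
    u = rng.random(len(doses))
    phases = np.where(u < p_cyc / 2, "S",
                      np.where(u < p_cyc, "G2M", "G1"))
    return phases


def _module_eta(gt: GroundTruth, tf: TFParams, doses, branch_draw, eta):
    """Add this TF's module log-fold-changes into eta (cells x genes)."""
    cfg = gt.config
    amp = cfg.expr_gain * tf.plateau
    unit = _unit_response(tf, doses)
    idx_list = gt.modules[tf.name]
    w_list = gt.module_weights[tf.name]
    if tf.response_shape == RESPONSE_BRANCH:
        for m, (idx, w) in enumerate(zip(idx_list, w_list)):
            mask = branch_draw == m
            if mask.any():
                eta[np.ix_(mask, idx)] += amp * unit[mask, None] * w[None, :]
    else:
        for idx, w in zip(idx_list, w_list):
            eta[:, idx] += amp * unit[:, None] * w[None, :]
    return eta


def _nb_counts(rng, mu, dispersion):
    """Gamma-Poisson draw: var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape[None, :], scale=mu / shape[None, :])
    return rng.poisson(lam)


def _simulate_cells(gt: GroundTruth, tf: TFParams, n_cells, batches, rng,
                    doses=None):
    """Expression + truth for one TF's cells (vectorised per TF)."""
    cfg = gt.config
    if doses is None:
        umis = _draw_umis(rng, n_cells, cfg)
    else:
        umis = np.round(np.expm1(doses)).astype(np.int64)
    doses = np.log1p(umis)

    # branch choice: Bernoulli per cell, independent of dose, drawn for all
    # cells but only consequential inside the branching window (dose > d50)
    branch_draw = (rng.random(n_cells) < (1 - cfg.branch_prob)).astype(int)

    phases = _draw_phases(rng, tf, doses, cfg)

    eta = np.zeros((n_cells, cfg.n_genes))
    if tf.name != CONTROL_TF:
        _module_eta(gt, tf, doses, branch_draw, eta)

    # cell-cycle programs
    s_mask, g_mask = phases == "S", phases == "G2M"
    if s_mask.any():
        eta[np.ix_(s_mask, gt.s_genes)] += cfg.cc_amp
    if g_mask.any():
        eta[np.ix_(g_mask, gt.g2m_genes)] += cfg.cc_amp

    # shared latent heterogeneity (confluence-like), present in all cells
    z = rng.normal(0.0, 1.0, size=(n_cells, cfg.n_latent_factors))
    eta += z @ gt.latent_loadings

    size = rng.lognormal(0.0, cfg.size_factor_sd, size=n_cells)
    mu = (cfg.mean_total_umis * size[:, None]
          * gt.gene_baseline[None, :]
          * gt.batch_factors[batches, :]
          * np.exp(np.clip(eta, -10.0, 8.0)))
    counts = _nb_counts(rng, mu, gt.gene_dispersion)

    truth = pd.DataFrame({
        "tf": tf.name,
        "batch": batches,
        "dose": doses,
        "umi": umis,
        "branch": np.where(tf.response_shape == RESPONSE_BRANCH,
                           branch_draw, -1),
        "phase": phases,
        "effect": true_effect(tf, doses) if tf.name != CONTROL_TF else 0.0,
        "tf2": "",
        "dose2": 0.0,
        "umi2": 0,
        "is_doublet": False,
    })
    return counts, truth


def _assemble(gt: GroundTruth, all_counts, all_truth, rng) -> SimulatedExperiment:
    cfg = gt.config
    counts = np.vstack(all_counts)
    truth = pd.concat(all_truth, ignore_index=True)
    n_cells = len(truth)
    truth.insert(0, "cell_id", [f"cell{i + 1:06d}" for i in range(n_cells)])

    # TF-ID enrichment matrix
    tf_index = {name: i for i, name in enumerate(gt.tf_params)}
    tfid = np.zeros((n_cells, len(tf_index)), dtype=np.int64)
    tfid[np.arange(n_cells), [tf_index[t] for t in truth["tf"]]] = truth["umi"]
    has2 = truth["tf2"].values != ""
    if has2.any():
        rows = np.where(has2)[0]
        cols = [tf_index[t] for t in truth.loc[has2, "tf2"]]
        tfid[rows, cols] += truth.loc[has2, "umi2"].astype(np.int64).values

    # ambient TF-ID UMIs: low-count molecules landing in the wrong cells
    if gt.ambient_rate > 0:
        n_amb = rng.poisson(gt.ambient_rate * 3.0, size=n_cells)
        for i in np.where(n_amb > 0)[0]:
            cols = rng.integers(0, len(tf_index), size=n_amb[i])
            np.add.at(tfid[i], cols, 1)

    tfids = pd.DataFrame({
        "name": list(gt.tf_params),
        "barcode": [gt.barcodes[t] for t in gt.tf_params],
    })
    genes = gt.gene_flags.copy()
    return SimulatedExperiment(
        counts=sp.csr_matrix(counts),
        genes=genes,
        tfid_counts=sp.csr_matrix(tfid),
        tfids=tfids,
        truth=truth,
        ground_truth=gt,
    )


def simulate_experiment(gt: GroundTruth, n_cells_per_tf: int,
                        seed: int) -> SimulatedExperiment:
    """Simulate a full single-TF screen.

    Each TF receives ``n_cells_per_tf`` cells spread uniformly over batches;
    controls receive ``n_control_cells_per_batch`` per batch.  A
    ``doublet_rate`` fraction of TF cells receives a second TF-ID (and the
    second TF's expression effect).  Deterministic for fixed ``(gt, seed)``;
    per-TF substreams allow partial re-simulation.
    """
    if n_cells_per_tf < 1:
        raise ConfigurationError("n_cells_per_tf must be >= 1")
    cfg = gt.config
    ss = np.random.SeedSequence(gt.seed, spawn_key=(1, seed))
    streams = ss.spawn(len(gt.tf_params) + 2)

    all_counts, all_truth = [], []
    names = list(gt.tf_params)
    for k, name in enumerate(names):
        tf = gt.tf_params[name]
        rng = np.random.default_rng(streams[k])
        n = (cfg.n_control_cells_per_batch * cfg.n_batches
             if name == CONTROL_TF else n_cells_per_tf)
        batches = np.arange(n) % cfg.n_batches
        counts, truth = _simulate_cells(gt, tf, n, batches, rng)
        all_counts.append(counts)
        all_truth.append(truth)

    exp = _assemble(gt, all_counts, all_truth,
                    np.random.default_rng(streams[-2]))

    # doublets: overwrite a random subset of TF cells with a second TF-ID
    # and add the second TF's expression program
    if gt.doublet_rate > 0:
        rng = np.random.default_rng(streams[-1])
        tf_cells = np.where(exp.truth["tf"] != CONTROL_TF)[0]
        n_dbl = rng.binomial(len(tf_cells), gt.doublet_rate)
        pick = rng.choice(tf_cells, size=n_dbl, replace=False)
        tf_index = {name: i for i, name in enumerate(exp.tfids["name"])}
        tfid = exp.tfid_counts.tolil()
        dense = exp.counts.toarray()
        for i in pick:
            own = exp.truth.at[i, "tf"]
            others = [n for n in gt.tf_names if n != own]
            second = others[rng.integers(len(others))]
            umi2 = int(_draw_umis(rng, 1, cfg)[0])
            exp.truth.at[i, "tf2"] = second
            exp.truth.at[i, "umi2"] = umi2
            exp.truth.at[i, "dose2"] = np.log1p(umi2)
            exp.truth.at[i, "is_doublet"] = True
            tfid[i, tf_index[second]] += umi2
            # second program's expression effect
            tf2 = gt.tf_params[second]
            eta2 = np.zeros((1, cfg.n_genes))
            _module_eta(gt, tf2, np.array([np.log1p(umi2)]),
                        np.zeros(1, dtype=int), eta2)
            row = dense[i].astype(float)
            extra = np.expm1(np.clip(eta2.ravel(), 0, None)) * np.maximum(row, 0.5)
            dense[i] = row + rng.poisson(np.clip(extra, 0, 1e4))
        exp.counts = sp.csr_matrix(dense)
        exp.tfid_counts = tfid.tocsr()
    return exp


# ---------------------------------------------------------------------------
# TF-pair (combinatorial) simulation
# ---------------------------------------------------------------------------

INTERACTION_DOMINANCE = "dominance"
INTERACTION_UNIQUE_STATE = "unique_state"
INTERACTION_SYNERGY = "synergy"
INTERACTION_ANTAGONISM = "antagonism"


def register_combo(gt: GroundTruth, tf1: str, tf2: str, interaction: str,
                   winner: Optional[str] = None, factor: float = 2.0,
                   seed: int = 0) -> None:
    """Register a TF-pair interaction rule in the ground truth.

    ``dominance`` requires a ``winner``; ``unique_state`` reserves a dedicated
    gene module activated only when both doses exceed their midpoints;
    ``synergy``/``antagonism`` scale the joint effect of a shared module by
    ``factor`` (>1 up, <1 down).
    """
    for t in (tf1, tf2):
        if t not in gt.tf_params or t == CONTROL_TF:
            raise ConfigurationError(f"unknown TF {t!r}")
    if tf1 == tf2:
        raise ConfigurationError("tf1 and tf2 must differ")
    rule = {"interaction": interaction, "factor": factor}
    if interaction == INTERACTION_DOMINANCE:
        if winner not in (tf1, tf2):
            raise ConfigurationError("dominance requires winner in (tf1, tf2)")
        rule["winner"] = winner
    if interaction == INTERACTION_UNIQUE_STATE:
        # dedicated module drawn from the null-gene tail
        rng = np.random.default_rng(np.random.SeedSequence(gt.seed, spawn_key=(7, seed)))
        cfg = gt.config
        used = set()
        for lst in gt.modules.values():
            for idx in lst:
                used.update(idx.tolist())
        used.update(gt.s_genes.tolist())
        used.update(gt.g2m_genes.tolist())
        free = np.array([j for j in range(cfg.n_genes) if j not in used])
        idx = rng.choice(free, size=min(cfg.genes_per_module, free.size), replace=False)
        w = rng.uniform(0.5, 1.5, size=idx.size)
        w /= np.sqrt(np.mean(w ** 2))
        rule["module"] = np.sort(idx)
        rule["weights"] = w
    gt.combo_params[(tf1, tf2)] = rule


def simulate_combination(gt: GroundTruth, tf1: str, tf2: str, seed: int,
                         n_combo: int = 150, n_single: int = 150,
                         n_control: int = 150) -> SimulatedExperiment:
    """Simulate a TF-pair experiment: combo, single-TF and control cells.

    Combo cells draw independent doses d1, d2; their expression effect is
    composed per the registered interaction rule.  Single-TF and control
    cells follow the single-TF generative model.
    """
    if (tf1, tf2) not in gt.combo_params:
        raise ConfigurationError(f"pair ({tf1}, {tf2}) not registered")
    rule = gt.combo_params[(tf1, tf2)]
    cfg = gt.config
    ss = np.random.SeedSequence(gt.seed, spawn_key=(2, seed))
    streams = ss.spawn(5)
    p1, p2 = gt.tf_params[tf1], gt.tf_params[tf2]

    all_counts, all_truth = [], []
    # single-TF and control cells
    for k, tf in enumerate((p1, p2, gt.tf_params[CONTROL_TF])):
        rng = np.random.default_rng(streams[k])
        n = n_control if tf.name == CONTROL_TF else n_single
        batches = np.arange(n) % cfg.n_batches
        counts, truth = _simulate_cells(gt, tf, n, batches, rng)
        all_counts.append(counts)
        all_truth.append(truth)

    # combo cells
    rng = np.random.default_rng(streams[3])
    d1_umi = _draw_umis(rng, n_combo, cfg)
    d2_umi = _draw_umis(rng, n_combo, cfg)
    d1, d2 = np.log1p(d1_umi), np.log1p(d2_umi)
    batches = np.arange(n_combo) % cfg.n_batches
    eta = np.zeros((n_combo, cfg.n_genes))
    zeros = np.zeros(n_combo, dtype=int)

    inter = rule["interaction"]
    if inter == INTERACTION_DOMINANCE:
        winner = rule["winner"]
        wtf = gt.tf_params[winner]
        ltf = p2 if winner == tf1 else p1
        dw = d1 if winner == tf1 else d2
        dl = d2 if winner == tf1 else d1
        # winner's program whenever it is expressed; loser's only in cells
        # where the winner is silenced
        win_on = dw > 0
        eta_w = np.zeros_like(eta)
        _module_eta(gt, wtf, dw, zeros, eta_w)
        eta_l = np.zeros_like(eta)
        _module_eta(gt, ltf, dl, zeros, eta_l)
        eta += np.where(win_on[:, None], eta_w, eta_l)
    elif inter == INTERACTION_UNIQUE_STATE:
        # the switch needs both programs detectably on: above the response
        # midpoint and above the enrichment-library detection floor
        # (> 4 UMIs), so state labels stay consistent with dose grouping
        thr1 = max(p1.midpoint, np.log(6.0))
        thr2 = max(p2.midpoint, np.log(6.0))
        both_high = (d1 > thr1) & (d2 > thr2)
        amp = cfg.expr_gain * 0.5 * (p1.plateau + p2.plateau)
        idx, w = rule["module"], rule["weights"]
        eta[np.ix_(both_high, idx)] += amp * w[None, :]
        # outside the joint-high regime: additive single effects
        rest = ~both_high
        if rest.any():
            eta_1 = np.zeros_like(eta)
            _module_eta(gt, p1, d1, zeros, eta_1)
            eta_2 = np.zeros_like(eta)
            _module_eta(gt, p2, d2, zeros, eta_2)
            eta[rest] += eta_1[rest] + eta_2[rest]
    else:   # synergy / antagonism on the shared module scale
        factor = rule["factor"]
        eta_1 = np.zeros_like(eta)
        _module_eta(gt, p1, d1, zeros, eta_1)
        eta_2 = np.zeros_like(eta)
        _module_eta(gt, p2, d2, zeros, eta_2)
        eta += factor * _abs_max(eta_1, eta_2)

    phases = _draw_phases(rng, gt.tf_params[CONTROL_TF], d1, cfg)
    s_mask, g_mask = phases == "S", phases == "G2M"
    if s_mask.any():
        eta[np.ix_(s_mask, gt.s_genes)] += cfg.cc_amp
    if g_mask.any():
        eta[np.ix_(g_mask, gt.g2m_genes)] += cfg.cc_amp
    z = rng.normal(0.0, 1.0, size=(n_combo, cfg.n_latent_factors))
    eta += z @ gt.latent_loadings
    size = rng.lognormal(0.0, cfg.size_factor_sd, size=n_combo)
    mu = (cfg.mean_total_umis * size[:, None] * gt.gene_baseline[None, :]
          * gt.batch_factors[batches, :] * np.exp(np.clip(eta, -10.0, 8.0)))
    counts = _nb_counts(rng, mu, gt.gene_dispersion)
    truth = pd.DataFrame({
        "tf": tf1, "batch": batches, "dose": d1, "umi": d1_umi,
        "branch": -1, "phase": phases, "effect": 0.0,
        "tf2": tf2, "dose2": d2, "umi2": d2_umi, "is_doublet": False,
    })
    all_counts.append(counts)
    all_truth.append(truth)

    return _assemble(gt, all_counts, all_truth,
                     np.random.default_rng(streams[4]))


def _abs_max(a, b):
    """Elementwise value of larger magnitude (signed)."""
    return np.where(np.abs(a) >= np.abs(b), a, b)


# ---------------------------------------------------------------------------
# Summary-level dose-response cohort
# ---------------------------------------------------------------------------

def simulate_dose_response_cohort(gt: GroundTruth, n_cells_per_tf: int,
                                  seed: int, noise_sd: float = 0.08) -> dict:
    """Per-TF (dose, change) observations drawn from the planted curves.

    Doses follow the screen's dose model; observed changes are the planted
    response curve plus Gaussian measurement noise with standard deviation
    ``noise_sd`` (the typical spread of the correlation-based change
    statistic around its dose trend).  This generator feeds the
    dose-response fitting and truncation power analyses directly at the
    summary-statistic level; the count-level generator exercises the full
    expression-to-change path.  Returns ``{tf: (doses, changes)}``.
    """
    cfg = gt.config
    ss = np.random.SeedSequence(gt.seed, spawn_key=(3, seed))
    streams = ss.spawn(len(gt.tf_names))
    out = {}
    for name, stream in zip(gt.tf_names, streams):
        rng = np.random.default_rng(stream)
        tf = gt.tf_params[name]
        doses = np.log1p(_draw_umis(rng, n_cells_per_tf, cfg))
        changes = true_effect(tf, doses) + rng.normal(0.0, noise_sd,
                                                      size=n_cells_per_tf)
        out[name] = (doses, changes)
    return out
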