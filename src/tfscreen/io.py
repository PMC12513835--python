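"""Readers/writers, configuration and the end-to-end pipeline driver.

Matrices travel as Matrix Market (.mtx, optionally gzipped) with TSV
sidecars (features/rows and barcodes/columns, 10x-style, genes x cells on
disk).  Tabular outputs are TSV with a header comment carrying the tool
version and config hash.  The pipeline driver executes
simulate -> demux -> qc -> change -> cellcycle -> fitdose -> power ->
hetero -> (combo) with per-stage provenance JSON; finished stages are
skipped on resume.
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from . import __version__
from . import cellcycle as cc_mod
from . import combo as combo_mod
from . import demux as demux_mod
from . import dose_response as dr_mod
from . import embed_change as ec_mod
from . import heterogeneity as het_mod
from . import simdata as sim_mod
from .simdata import CONTROL_TF

logger = logging.getLogger("tfscreen")


class FormatError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


def setup_logging(level=logging.INFO, logfile=None):
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level, handlers=handlers, force=True,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s")


# ---------------------------------------------------------------------------
# Matrix Market + TSV sidecars
# ---------------------------------------------------------------------------

def write_matrix(matrix, rows: pd.DataFrame, cols, outdir, name="matrix"):
    """Write a genes x cells (or TF-IDs x cells) matrix as .mtx + sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    M = sp.coo_matrix(matrix)
    scipy.io.mmwrite(str(outdir / f"{name}.mtx"), M)
    rows.to_csv(outdir / f"{name}.rows.tsv", sep="\t", index=False)
    pd.DataFrame({"barcode": list(cols)}).to_csv(
        outdir / f"{name}.cols.tsv", sep="\t", index=False)


def read_matrix(outdir, name="matrix"):
    """Read a matrix written by :func:`write_matrix` (gzipped .mtx accepted).

    Returns ``(csr_matrix, rows_df, cols_list)`` and validates sidecar
    dimensions against the matrix header.
    """
    outdir = Path(outdir)
    mtx_path = outdir / f"{name}.mtx"
    if not mtx_path.exists() and (outdir / f"{name}.mtx.gz").exists():
        mtx_path = outdir / f"{name}.mtx.gz"
    if not mtx_path.exists():
        raise FormatError(f"no matrix file {name}.mtx(.gz) in {outdir}")
    if mtx_path.suffix == ".gz":
        with gzip.open(mtx_path, "rb") as fh:
            M = scipy.io.mmread(fh)
    else:
        M = scipy.io.mmread(str(mtx_path))
    M = sp.csr_matrix(M)
    rows = pd.read_csv(outdir / f"{name}.rows.tsv", sep="\t")
    cols = pd.read_csv(outdir / f"{name}.cols.tsv", sep="\t")["barcode"].tolist()
    if M.shape[0] != len(rows):
        raise FormatError(
            f"{name}: matrix has {M.shape[0]} rows but sidecar "
            f"{name}.rows.tsv lists {len(rows)} (line {len(rows) + 1})")
    if M.shape[1] != len(cols):
        raise FormatError(
            f"{name}: matrix has {M.shape[1]} columns but sidecar "
            f"{name}.cols.tsv lists {len(cols)} (line {len(cols) + 1})")
    return M, rows, cols


def write_table(df: pd.DataFrame, path, config_hash=""):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# tfscreen {__version__} config={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {f.name: f.default for f in dataclasses.fields(sim_mod.SimConfig)
                 if not isinstance(f.default, dataclasses._MISSING_TYPE)}
    | {"class_proportions": [1 / 3, 1 / 3, 1 / 3], "n_cells_per_tf": 120},
    "demux": {"min_umi": 2, "ratio_max": 0.2},
    "qc": {"mito_max": 0.15, "ribo_max": 0.60, "coding_min": 0.75,
           "nmads": 4.0, "min_cells_per_tf": 8},
    "change": {"n_pcs": 200, "k_ctrl": 20, "threshold": 0.23},
    "fitdose": {"capacity_threshold": 0.23, "sensitivity_threshold_d50": None,
                "min_cells": 20},
    "power": {"step": 0.25, "min_threshold": 2.0},
    "hetero": {"resolution": 1.2, "k_nn": 20, "control_frac": 0.6,
               "min_cells": 30, "n_pcs": 50},
    "cellcycle": {"n_bins": 24, "n_ctrl": 100, "quantile": 0.95},
    "combo": {"enabled": False, "tf1": None, "tf2": None,
              "interaction": "dominance", "winner": None, "factor": 2.0,
              "k": 5, "n_pcs": 20, "n_bins": 4},
}


def load_config(path=None, overrides=None) -> dict:
    """Load a YAML config, rejecting unknown keys, merging over defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))   # deep copy
    user = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    if overrides:
        for section, vals in overrides.items():
            user.setdefault(section, {})
            if isinstance(vals, dict):
                user[section].update(vals)
            else:
                user[section] = vals
    for section, vals in user.items():
        if section not in cfg:
            raise ConfigurationError(f"unknown config section {section!r}")
        if isinstance(cfg[section], dict):
            if not isinstance(vals, dict):
                raise ConfigurationError(f"section {section!r} must be a mapping")
            for k, v in vals.items():
                if k not in cfg[section]:
                    raise ConfigurationError(
                        f"unknown config key {section}.{k}")
                cfg[section][k] = v
        else:
            cfg[section] = vals
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.md5(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

STAGES = ["simulate", "demux", "qc", "change", "cellcycle", "fitdose",
          "power", "hetero", "combo"]


def _hash_file(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _provenance(outdir, stage, cfg, inputs, outputs):
    rec = {
        "stage": stage,
        "version": __version__,
        "seed": cfg["seed"],
        "params": cfg.get(stage, {}),
        "config_hash": config_hash(cfg),
        "inputs": {str(p): _hash_file(p) for p in inputs if Path(p).exists()},
        "outputs": [str(p) for p in outputs],
        "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(Path(outdir) / f"provenance_{stage}.json", "w") as fh:
        json.dump(rec, fh, indent=2, default=str)


def _stage_done(outdir, stage, outputs):
    return (Path(outdir) / f"provenance_{stage}.json").exists() and \
        all(Path(p).exists() for p in outputs)


class Pipeline:
    """End-to-end driver over a working directory of TSV/MTX artifacts."""

    def __init__(self, cfg: dict, outdir):
        self.cfg = cfg
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.hash = config_hash(cfg)
        with open(self.outdir / "config_resolved.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)

    # -- helpers ----------------------------------------------------------
    def _cells_path(self):
        return self.outdir / "cells.tsv"

    def _read_cells(self):
        return read_table(self._cells_path())

    def _write_cells(self, cells):
        write_table(cells, self._cells_path(), self.hash)

    def _expr(self):
        M, rows, cols = read_matrix(self.outdir / "expr")
        return M.T.tocsr(), rows, cols      # cells x genes internally

    # -- stages -----------------------------------------------------------
    def stage_simulate(self):
        cfg = self.cfg
        sim_kwargs = dict(cfg["simulate"])
        n_cells_per_tf = sim_kwargs.pop("n_cells_per_tf")
        sim_kwargs["class_proportions"] = tuple(sim_kwargs["class_proportions"])
        sc = sim_mod.SimConfig(**sim_kwargs)
        gt = sim_mod.simulate_ground_truth(sc, cfg["seed"])
        exp = sim_mod.simulate_experiment(gt, n_cells_per_tf, cfg["seed"])

        genes = exp.genes.copy()
        genes["is_s_gene"] = False
        genes["is_g2m_gene"] = False
        genes.loc[gt.s_genes, "is_s_gene"] = True
        genes.loc[gt.g2m_genes, "is_g2m_gene"] = True
        write_matrix(exp.counts.T, genes, exp.truth["cell_id"],
                     self.outdir / "expr")
        write_matrix(exp.tfid_counts.T, exp.tfids, exp.truth["cell_id"],
                     self.outdir / "tfid")
        write_table(exp.truth, self.outdir / "truth.tsv", self.hash)
        meta = exp.truth[["cell_id", "batch"]]
        write_table(meta, self.outdir / "cells_meta.tsv", self.hash)
        params = pd.DataFrame([{
            "tf": p.name, "class": p.tf_class, "baseline": p.baseline,
            "plateau": p.plateau, "midpoint": p.midpoint, "slope": p.slope,
            "response_shape": p.response_shape, "cc_coupling": p.cc_coupling,
        } for p in gt.tf_params.values()])
        write_table(params, self.outdir / "truth_tf_params.tsv", self.hash)
        return ["expr/matrix.mtx", "tfid/matrix.mtx", "truth.tsv",
                "cells_meta.tsv", "truth_tf_params.tsv"]

    def stage_demux(self):
        M, tfids, cells_bc = read_matrix(self.outdir / "tfid")
        meta = read_table(self.outdir / "cells_meta.tsv")
        params = demux_mod.AssignParams(**self.cfg["demux"])
        frag = demux_mod.assign_tf(M.T, tfids["name"], params, cell_ids=cells_bc)
        cells = meta.merge(frag, on="cell_id")
        cells["is_control"] = cells["assigned_tf"] == CONTROL_TF
        self._write_cells(cells)
        return ["cells.tsv"]

    def stage_qc(self):
        X, genes, _ = self._expr()
        cells = self._read_cells()
        qc_cfg = dict(self.cfg["qc"])
        thr = demux_mod.QCThresholds(**qc_cfg)
        mask, report = demux_mod.qc_filter(X, genes, cells, thr)
        cells = pd.concat([cells, mask.drop(columns=["cell_id"])], axis=1)
        self._write_cells(cells)
        with open(self.outdir / "qc_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        return ["cells.tsv", "qc_report.json"]

    def stage_change(self):
        X, genes, _ = self._expr()
        cells = self._read_cells()
        keep = cells["qc_pass"].values & cells["assigned_tf"].isin(
            list(pd.unique(cells["assigned_tf"]))).values
        keep &= ~cells["assigned_tf"].isin(["doublet", "unassigned"]).values
        ccfg = self.cfg["change"]
        sub = np.where(keep)[0]
        emb = ec_mod.control_referenced_embedding(
            X[sub], cells["is_control"].values[sub],
            cells["batch"].values[sub], n_pcs=ccfg["n_pcs"],
            k_ctrl=ccfg["k_ctrl"])
        change = ec_mod.transcriptomic_change(emb, cells["is_control"].values[sub])
        cells["change"] = np.nan
        cells.loc[sub, "change"] = change
        cells["nonfunctional"] = cells["change"] <= ccfg["threshold"]
        self._write_cells(cells)
        np.savetxt(self.outdir / "pca_scores.tsv", emb.scores[:, :50],
                   delimiter="\t")
        pd.DataFrame({"cell_id": cells["cell_id"].values[sub]}).to_csv(
            self.outdir / "pca_cells.tsv", sep="\t", index=False)
        # minimal functional dose per TF
        rows = []
        for tf in pd.unique(cells["assigned_tf"]):
            if tf in (CONTROL_TF, "doublet", "unassigned"):
                continue
            sel = (cells["assigned_tf"] == tf) & cells["change"].notna()
            if sel.sum() < 10:
                continue
            mfd = ec_mod.minimal_functional_dose(
                cells.loc[sel, "dose"], cells.loc[sel, "change"],
                threshold=ccfg["threshold"])
            rows.append({"tf": tf, "minimal_functional_dose": mfd})
        write_table(pd.DataFrame(rows), self.outdir / "minimal_dose.tsv",
                    self.hash)
        return ["cells.tsv", "minimal_dose.tsv", "pca_scores.tsv"]

    def stage_cellcycle(self):
        X, genes, _ = self._expr()
        cells = self._read_cells()
        ccfg = self.cfg["cellcycle"]
        lognorm, _ = ec_mod.normalize_log1p(X)
        s_genes = genes.loc[genes["is_s_gene"], "name"].tolist()
        g2m_genes = genes.loc[genes["is_g2m_gene"], "name"].tolist()
        scores = cc_mod.cc_scores(lognorm, genes["name"], s_genes, g2m_genes,
                                  n_bins=ccfg["n_bins"], n_ctrl=ccfg["n_ctrl"],
                                  seed=self.cfg["seed"])
        cells["s_score"] = scores["s_score"].values
        cells["g2m_score"] = scores["g2m_score"].values
        cells["phase"] = cc_mod.assign_phase(scores)
        ctrl = scores[cells["is_control"].values]
        cells["adjusted_phase"] = cc_mod.adjust_phase(scores, ctrl,
                                                      quantile=ccfg["quantile"])
        self._write_cells(cells)
        tested = cells[cells["qc_pass"]] if "qc_pass" in cells else cells
        tests = cc_mod.phase_fraction_test(
            tested, ref_group=CONTROL_TF, seed=self.cfg["seed"])
        write_table(tests, self.outdir / "phase_tests.tsv", self.hash)
        return ["cells.tsv", "phase_tests.tsv"]

    def stage_fitdose(self):
        cells = self._read_cells()
        fcfg = self.cfg["fitdose"]
        fits, data = [], {}
        for tf in pd.unique(cells["assigned_tf"]):
            if tf in (CONTROL_TF, "doublet", "unassigned"):
                continue
            sel = (cells["assigned_tf"] == tf) & cells["change"].notna()
            d = cells.loc[sel, "dose"].values
            c = cells.loc[sel, "change"].values
            data[tf] = (d, c)
            fits.append(dr_mod.fit_logistic(d, c, tf=tf,
                                            min_cells=fcfg["min_cells"]))
        dr_mod.classify_cohort(fits, fcfg["capacity_threshold"],
                               fcfg["sensitivity_threshold_d50"])
        write_table(dr_mod.fits_to_frame(fits), self.outdir / "fits.tsv",
                    self.hash)
        self._fit_data = data
        return ["fits.tsv"]

    def stage_power(self):
        cells = self._read_cells()
        fits_df = read_table(self.outdir / "fits.tsv")
        fits = [dr_mod.DoseResponseFit(
            tf=r.tf, baseline=r.baseline, plateau=r.plateau,
            midpoint=r.midpoint, slope=r.slope, rmse=r.rmse,
            n_cells=r.n_cells, max_dose=r.max_dose, converged=r.converged,
            capacity_class=r.capacity_class if isinstance(r.capacity_class, str) else "",
            sensitivity_class=r.sensitivity_class if isinstance(r.sensitivity_class, str) else "",
        ) for r in fits_df.itertuples()]
        data = {}
        for tf in (f.tf for f in fits):
            sel = (cells["assigned_tf"] == tf) & cells["change"].notna()
            data[tf] = (cells.loc[sel, "dose"].values,
                        cells.loc[sel, "change"].values)
        pcfg = self.cfg["power"]
        n_high = sum(f.capacity_class == dr_mod.CAPACITY_HIGH for f in fits)
        if n_high < 5:
            logger.warning("only %d high-capacity TFs; skipping power analysis",
                           n_high)
            write_table(pd.DataFrame(), self.outdir / "power_records.tsv",
                        self.hash)
            return ["power_records.tsv"]
        res = dr_mod.power_analysis(data, fits, step=pcfg["step"],
                                    min_threshold=pcfg["min_threshold"])
        write_table(res.records, self.outdir / "power_records.tsv", self.hash)
        write_table(res.curve, self.outdir / "power_curve.tsv", self.hash)
        pfl = pd.DataFrame([{"tf": t, "p_false_low": v}
                            for t, v in res.p_false_low.items()])
        write_table(pfl, self.outdir / "p_false_low.tsv", self.hash)
        return ["power_records.tsv"]

    def stage_hetero(self):
        X, genes, _ = self._expr()
        cells = self._read_cells()
        hcfg = self.cfg["hetero"]
        keep = (cells["qc_pass"].values
                & (cells["adjusted_phase"] == "G1").values
                & (cells["is_control"].values
                   | (cells["change"] > self.cfg["change"]["threshold"]).values))
        sub = np.where(keep)[0]
        if sub.size < hcfg["k_nn"] + 2:
            logger.warning("too few cells for heterogeneity clustering")
            write_table(pd.DataFrame(), self.outdir / "hetero_candidates.tsv",
                        self.hash)
            return ["hetero_candidates.tsv"]
        emb = ec_mod.control_referenced_embedding(
            X[sub], cells["is_control"].values[sub],
            cells["batch"].values[sub], n_pcs=hcfg["n_pcs"],
            k_ctrl=self.cfg["change"]["k_ctrl"])
        labels = het_mod.cluster_cells(emb.scores, resolution=hcfg["resolution"],
                                       k_nn=hcfg["k_nn"], seed=self.cfg["seed"])
        flags = het_mod.identify_control_clusters(
            labels, ~cells["is_control"].values[sub], hcfg["control_frac"])
        tf_labels = cells["assigned_tf"].values[sub]
        cand = het_mod.find_heterogeneous_tfs(
            labels, tf_labels, flags, min_cells=hcfg["min_cells"])
        cand = cand[cand["tf"] != CONTROL_TF]
        write_table(cand, self.outdir / "hetero_candidates.tsv", self.hash)
        clus = pd.DataFrame({"cell_id": cells["cell_id"].values[sub],
                             "cluster": labels,
                             "is_control_cluster": [flags[int(c)] for c in labels]})
        write_table(clus, self.outdir / "clusters.tsv", self.hash)
        return ["hetero_candidates.tsv", "clusters.tsv"]

    def stage_combo(self):
        ccfg = self.cfg["combo"]
        if not ccfg["enabled"]:
            return []
        cfg = self.cfg
        sim_kwargs = dict(cfg["simulate"])
        sim_kwargs.pop("n_cells_per_tf")
        sim_kwargs["class_proportions"] = tuple(sim_kwargs["class_proportions"])
        sc = sim_mod.SimConfig(**sim_kwargs)
        gt = sim_mod.simulate_ground_truth(sc, cfg["seed"])
        tf1, tf2 = ccfg["tf1"], ccfg["tf2"]
        sim_mod.register_combo(gt, tf1, tf2, ccfg["interaction"],
                               winner=ccfg["winner"], factor=ccfg["factor"])
        exp = sim_mod.simulate_combination(gt, tf1, tf2, cfg["seed"])
        groups = demux_mod.assign_pair_groups(exp.tfid_counts,
                                              exp.tfids["name"], tf1, tf2)
        lognorm, _ = ec_mod.normalize_log1p(exp.counts)
        emb = ec_mod.integrate_batches(lognorm, exp.truth["batch"].values,
                                       n_pcs=ccfg["n_pcs"])
        per_cell, mean_frac = combo_mod.knn_group_fractions(
            emb.scores, groups, k=ccfg["k"])
        edges = combo_mod.dominance_network({(tf1, tf2): mean_frac})
        names = list(exp.tfids["name"])
        u1 = np.asarray(exp.tfid_counts[:, names.index(tf1)].todense()).ravel()
        u2 = np.asarray(exp.tfid_counts[:, names.index(tf2)].todense()).ravel()
        d1, d2 = np.log1p(u1), np.log1p(u2)
        M = float(max(d1.max(), d2.max()))
        bins1 = combo_mod.dose_bin(d1, M, ccfg["n_bins"])
        bins2 = combo_mod.dose_bin(d2, M, ccfg["n_bins"])
        q = per_cell.index.values
        grid = combo_mod.binned_dominance(per_cell, bins1[q], bins2[q])
        write_table(grid, self.outdir / "combo_grid.tsv", self.hash)
        write_table(edges, self.outdir / "combo_edges.tsv", self.hash)
        return ["combo_grid.tsv", "combo_edges.tsv"]

    # -- driver -----------------------------------------------------------
    def run(self, stages=None, resume=True):
        stages = stages or [s for s in STAGES
                            if s != "combo" or self.cfg["combo"]["enabled"]]
        for stage in stages:
            fn = getattr(self, f"stage_{stage}")
            marker = self.outdir / f"provenance_{stage}.json"
            if resume and marker.exists():
                logger.info("stage %s already complete; skipping", stage)
                continue
            logger.info("running stage %s", stage)
            try:
                outputs = fn()
            except Exception as e:
                err = {"stage": stage, "error": str(e),
                       "type": type(e).__name__}
                with open(self.outdir / "pipeline_error.json", "w") as fh:
                    json.dump(err, fh, indent=2)
                raise
            _provenance(self.outdir, stage, self.cfg,
                        [], [self.outdir / o for o in outputs])
        return self.outdir


def run_pipeline(config: dict, outdir, stages=None, resume=True) -> Path:
    """Execute the pipeline into ``outdir``; see :class:`Pipeline`."""
    return Pipeline(config, outdir).run(stages=stages, resume=resume)
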