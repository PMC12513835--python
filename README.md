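# tfscreen

Analysis of pooled single-cell TF-overexpression screens, for groups running
barcoded gain-of-function experiments in cell lines (for example,
multipotent stromal cells screened for lineage-reprogramming TFs).  Each
cell carries one doxycycline-inducible TF construct tagged with a DNA
barcode (TF-ID) read out in a dedicated enrichment library alongside the
regular gene-expression library.  From those two matrices, `tfscreen`:

- validates the TF-ID library (pairwise Hamming distance > 2) and assigns
  each cell to a TF, a doublet, or leaves it unassigned;
- quantifies the per-cell exogenous **TF dose**, d = ln(1 + TF-ID UMIs);
- measures each cell's **overall transcriptomic change** — the adjusted
  negative Pearson correlation to the control-cell centroid in a 200-PC,
  control-heterogeneity-regressed embedding (controls average exactly 0);
- fits a logistic dose–response per TF,
  `change(d) = a + K / (1 + exp(-s (d - d50)))`, and classifies TFs by
  **reprogramming capacity** (upper asymptote a + K above the functional
  threshold 0.23, supported by the observed dose range) and **dose
  sensitivity** (midpoint d50), plus a truncation power analysis giving
  each low-capacity TF its probability of being a masked high-capacity TF;
- detects TFs that split their cells over multiple functional clusters
  (stochastic / branching reprogramming) via SNN-graph clustering,
  a 60% control-cluster rule, and NB-GLM differential expression with a
  batch covariate;
- scores cell-cycle programs, assigns control-adjusted phases, and tests
  TF effects on phase composition with an exact 2x3 test;
- resolves TF-pair dominance, unique combinatorial states and
  dose-binned synergy/antagonism with 5-nearest-neighbour composition in
  20-PC space.

A synthetic-data generator with complete ground truth (dose distributions,
response curves, branching, batch effects, doublets, cell-cycle coupling,
pair interactions) stands in for a deposited dataset, so every stage is
testable end to end.

## Worked example

```python
import numpy as np
from tfscreen import simdata as sd, demux, embed_change as ec, dose_response as dr

cfg = sd.SimConfig(n_tfs=6, n_genes=900, genes_per_module=80)
gt = sd.simulate_ground_truth(cfg, seed=0)
exp = sd.simulate_experiment(gt, n_cells_per_tf=120, seed=0)

cells = demux.assign_tf(exp.tfid_counts, exp.tfids["name"],
                        cell_ids=exp.truth["cell_id"])
cells["batch"] = exp.truth["batch"].values
mask, report = demux.qc_filter(exp.counts, exp.genes, cells)
print(f"{report['n_pass']}/{report['n_cells']} cells pass QC")

keep = (mask["qc_pass"]
        & ~cells["assigned_tf"].isin(["doublet", "unassigned"])).values
is_ctrl = (cells["assigned_tf"] == "mCherry").values[keep]
emb = ec.control_referenced_embedding(exp.counts[np.where(keep)[0]],
                                      is_ctrl, cells["batch"].values[keep],
                                      n_pcs=200)
change = ec.transcriptomic_change(emb, is_ctrl)
print(f"control change: mean {change[is_ctrl].mean():+.2e}, "
      f"95th pct |.| {np.quantile(np.abs(change[is_ctrl]), 0.95):.3f}")

fits = []
for tf in gt.tf_names:
    sel = cells["assigned_tf"].values[keep] == tf
    fits.append(dr.fit_logistic(cells["dose"].values[keep][sel],
                                change[sel], tf=tf))
dr.classify_cohort(fits)
for f in fits:
    print(f"{f.tf}: plateau {f.asymptote:.2f}  d50 {f.midpoint:.2f}  "
          f"-> {f.capacity_class}-capacity/{f.sensitivity_class}-sensitivity "
          f"(planted: {gt.tf_params[f.tf].tf_class})")
```

prints

```
1020/1020 cells pass QC
control change: mean +3.56e-17, 95th pct |.| 0.042
TF001: plateau 0.74  d50 1.52  -> high-capacity/high-sensitivity (planted: high_capacity_high_sensitivity)
TF002: plateau 0.50  d50 2.04  -> high-capacity/high-sensitivity (planted: high_capacity_high_sensitivity)
TF003: plateau 0.42  d50 4.73  -> high-capacity/low-sensitivity (planted: high_capacity_low_sensitivity)
TF004: plateau 0.80  d50 5.36  -> high-capacity/low-sensitivity (planted: high_capacity_low_sensitivity)
TF005: plateau 0.04  d50 3.19  -> low-capacity/NA-sensitivity (planted: low_capacity)
TF006: plateau 0.03  d50 5.47  -> low-capacity/NA-sensitivity (planted: low_capacity)
```

Reading the output: controls centre exactly on zero change with a tight
spread, so the 0.23 functional threshold is meaningful; the two planted
high-sensitivity TFs are recovered with small midpoints (d50 ~1.5–2 ln-UMI
units), the low-sensitivity ones need doses near 5, and the two planted
low-capacity TFs show plateaus indistinguishable from the control band.

A command-line pipeline wraps the same stages over TSV/Matrix-Market
artifacts:

```
tfscreen run --seed 1 --out results/screen        # simulate -> ... -> hetero
tfscreen simulate --config cfg.yaml --seed 1 --out results/screen
tfscreen fitdose --out results/screen             # rerun one stage
```

Every stage writes a provenance JSON (parameters, seed, config hash) and
finished stages are skipped on resume.

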