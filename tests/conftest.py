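"""Shared fixtures: small simulated screens reused across test modules."""

import numpy as np
import pytest

from tfscreen import simdata as sd


@pytest.fixture(scope="session")
def small_cfg():
    return sd.SimConfig(
        n_tfs=6,
        n_genes=900,
        genes_per_module=80,
        n_control_cells_per_batch=100,
    )


@pytest.fixture(scope="session")
def small_gt(small_cfg):
    return sd.simulate_ground_truth(small_cfg, seed=1)


@pytest.fixture(scope="session")
def small_exp(small_gt):
    return sd.simulate_experiment(small_gt, n_cells_per_tf=80, seed=1)


@pytest.fixture(scope="session")
def small_change(small_exp):
    """Embedding + per-cell change for the small screen."""
    from tfscreen import embed_change as ec

    truth = small_exp.truth
    is_ctrl = (truth["tf"] == sd.CONTROL_TF).values
    emb = ec.control_referenced_embedding(
        small_exp.counts, is_ctrl, truth["batch"].values, n_pcs=200)
    change = ec.transcriptomic_change(emb, is_ctrl)
    return emb, change, is_ctrl
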