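"""Shared fixtures: one small simulated complex reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from catrace.ca_cluster import candidates_from_predictions
from catrace.simulator import (SimConfig, generate_toy_complex,
                               oracle_predictions, perturb_structure,
                               simulate_density)
from catrace.struct_codec import make_label_masks


@pytest.fixture(scope="session")
def sim_bundle():
    """Deterministic 2x60-residue complex with map, masks, oracle volumes,
    candidates, and a perturbed prior (seed 3)."""
    cfg = SimConfig(seed=3)
    struct, seqs = generate_toy_complex(cfg)
    dmap = simulate_density(struct, cfg)
    masks = make_label_masks(struct, dmap)
    pred = oracle_predictions(masks, corruption=0.0, seed=17)
    cands = candidates_from_predictions(pred, dmap)
    prior = perturb_structure(struct, cfg)
    return {
        "config": cfg,
        "struct": struct,
        "seqs": seqs,
        "dmap": dmap,
        "masks": masks,
        "pred": pred,
        "cands": cands,
        "prior": prior,
    }


@pytest.fixture(scope="session")
def small_bundle():
    """Single 30-residue chain bundle for cheaper tests (seed 11)."""
    cfg = SimConfig(n_chains=1, residues_per_chain=30, seed=11)
    struct, seqs = generate_toy_complex(cfg)
    dmap = simulate_density(struct, cfg)
    masks = make_label_masks(struct, dmap)
    pred = oracle_predictions(masks, corruption=0.0, seed=5)
    cands = candidates_from_predictions(pred, dmap)
    return {"config": cfg, "struct": struct, "seqs": seqs, "dmap": dmap,
            "masks": masks, "pred": pred, "cands": cands}
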