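"""End-to-end orchestration: preprocess -> encode prior -> predict (or
oracle) -> cluster -> trace -> write model -> evaluate.

All stage randomness flows from one root seed through stable per-stage
derived seeds, recorded in the provenance file next to the outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .ca_cluster import ClusterConfig, candidates_from_predictions, write_candidate_table
from .map_io import DensityMap, read_map, resample_map, normalize_map
from .metrics import evaluate, write_report
from .network import PredictionVolumes, load_checkpoint, predict_full_map
from .simulator import oracle_predictions
from .struct_codec import (StructureModel, encode_structure, make_label_masks,
                           read_fasta, read_structure)
from .tracer import TracerConfig, trace, write_model

log = logging.getLogger("catrace")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the failing stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


_STAGE_OFFSETS = {"simulate": 1, "train": 2, "predict": 3, "cluster": 4,
                  "trace": 5, "oracle": 6}


def derive_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (root_seed * 1000003 + _STAGE_OFFSETS[stage]) % (2 ** 31)


@dataclass
class PipelineConfig:
    map_path: str | None = None
    prior_path: str | None = None          # predicted-structure PDB, optional
    sequence_path: str | None = None       # FASTA of chain sequences
    truth_path: str | None = None          # ground-truth PDB for metrics, optional
    checkpoint_path: str | None = None     # trained network weights
    oracle_truth_path: str | None = None   # truth PDB for oracle-mode predictions
    out_dir: str = "catrace_out"
    oracle_corruption: float = 0.0
    seed: int = 0
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    tracer: TracerConfig = field(default_factory=TracerConfig)

    def validate(self) -> None:
        if self.map_path is None:
            raise PipelineError("config", "map_path is required")
        if self.sequence_path is None:
            raise PipelineError("config", "sequence_path is required")
        if self.checkpoint_path is None and self.oracle_truth_path is None:
            raise PipelineError(
                "config", "either checkpoint_path or oracle_truth_path is required")


def preprocess(dmap: DensityMap) -> DensityMap:
    """Resample to 1 A voxels and normalize to [0, 1]."""
    return normalize_map(resample_map(dmap, 1.0))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns a manifest of outputs.

    Outputs in ``out_dir``: ``model.pdb``, ``candidates.tsv``,
    ``metrics.tsv`` (when truth given), and ``provenance.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"out_dir": str(out)}

    try:
        dmap = preprocess(read_map(config.map_path))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("preprocess", str(exc)) from exc
    log.info("preprocess: map %s voxels", dmap.shape)

    try:
        sequences = read_fasta(config.sequence_path)
        prior = (read_structure(config.prior_path)
                 if config.prior_path else None)
        if prior is not None and not prior.chains:
            log.warning("prior structure is empty; running density-only")
            prior = None
    except Exception as exc:
        raise PipelineError("inputs", str(exc)) from exc

    try:
        if config.checkpoint_path:
            model, _ = load_checkpoint(config.checkpoint_path)
            enc = encode_structure(prior, dmap) if prior is not None else None
            pred = predict_full_map(model, dmap, enc)
        else:
            truth_for_oracle = read_structure(config.oracle_truth_path)
            masks = make_label_masks(truth_for_oracle, dmap)
            pred = oracle_predictions(masks, corruption=config.oracle_corruption,
                                      seed=derive_seed(config.seed, "oracle"))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("predict", str(exc)) from exc
    log.info("predict: volumes ready")

    try:
        cands = candidates_from_predictions(pred, dmap, config.cluster)
    except Exception as exc:
        raise PipelineError("cluster", str(exc)) from exc
    log.info("cluster: %d candidates", len(cands))
    cand_path = out / "candidates.tsv"
    write_candidate_table(cands, cand_path)
    manifest["candidates"] = str(cand_path)

    try:
        bm = trace(cands, sequences, prior=prior, config=config.tracer)
    except Exception as exc:
        raise PipelineError("trace", str(exc)) from exc
    model_path = out / "model.pdb"
    write_model(bm, model_path)
    manifest["model"] = str(model_path)
    manifest["placed_residues"] = bm.placed_count()
    log.info("trace: %d residues placed", bm.placed_count())

    if config.truth_path:
        try:
            truth = read_structure(config.truth_path)
            report = evaluate(bm, truth)
        except Exception as exc:
            raise PipelineError("evaluate", str(exc)) from exc
        metrics_path = out / "metrics.tsv"
        write_report(report, metrics_path)
        manifest["metrics"] = str(metrics_path)
        manifest["report"] = report

    prov = {
        "version": __version__,
        "seed": config.seed,
        "derived_seeds": {s: derive_seed(config.seed, s) for s in _STAGE_OFFSETS},
        "config": {
            "map_path": config.map_path,
            "prior_path": config.prior_path,
            "sequence_path": config.sequence_path,
            "truth_path": config.truth_path,
            "checkpoint_path": config.checkpoint_path,
            "oracle_truth_path": config.oracle_truth_path,
            "oracle_corruption": config.oracle_corruption,
        },
    }
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")
    manifest["provenance"] = str(prov_path)
    return manifest
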