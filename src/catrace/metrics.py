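"""In-frame model-vs-truth evaluation metrics.

All metrics assume the predicted and true models share the density map's
coordinate frame, so no superposition search is performed.  Matching is
greedy one-to-one by ascending pairwise distance under a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .struct_codec import StructureModel


@dataclass
class MatchResult:
    """One-to-one Calpha pairing between predicted and true residues.

    ``pairs`` holds (pred_index, true_index, distance) triples indexing
    the flattened residue lists of each model; ``flags`` records
    degenerate conditions (empty prediction, no pairs).
    """

    pairs: list[tuple[int, int, float]]
    n_pred: int
    n_true: int
    flags: list[str]


def _ca_table(model) -> tuple[np.ndarray, list[str]]:
    """Flattened Calpha coordinates and residue types of a model.

    Accepts a StructureModel or anything with ``to_structure()`` (e.g. a
    traced BackboneModel).
    """
    if not isinstance(model, StructureModel):
        model = model.to_structure()
    coords, types = [], []
    for ch in model.chains:
        for r in ch.residues:
            if "CA" in r.atoms:
                coords.append(np.asarray(r.atoms["CA"], dtype=np.float64))
                types.append(r.aa_type)
    return (np.array(coords) if coords else np.zeros((0, 3))), types


def match_ca(pred, truth, cutoff: float = 3.0) -> MatchResult:
    """Greedy one-to-one matching by ascending distance, pairs <= cutoff."""
    P, _ = _ca_table(pred)
    T, _ = _ca_table(truth)
    if len(T) == 0:
        raise ValueError("truth model has no Calpha atoms")
    flags = []
    if len(P) == 0:
        flags.append("empty_prediction")
        return MatchResult([], 0, len(T), flags)
    D = cdist(P, T)
    order = np.argsort(D, axis=None)
    used_p = np.zeros(len(P), dtype=bool)
    used_t = np.zeros(len(T), dtype=bool)
    pairs = []
    for flat in order:
        i, j = np.unravel_index(flat, D.shape)
        if D[i, j] > cutoff:
            break
        if used_p[i] or used_t[j]:
            continue
        used_p[i] = used_t[j] = True
        pairs.append((int(i), int(j), float(D[i, j])))
    if not pairs:
        flags.append("no_pairs")
    return MatchResult(pairs, len(P), len(T), flags)


def ca_match_score(m: MatchResult) -> float:
    """100 x matched predicted residues / predicted residues."""
    if m.n_pred == 0:
        return 0.0
    return 100.0 * len(m.pairs) / m.n_pred


def ca_quality_score(m: MatchResult) -> float:
    """Precision (Calpha match %) x coverage, coverage = min(1, n_pred/n_true)."""
    if m.n_pred == 0:
        return 0.0
    return ca_match_score(m) * min(1.0, m.n_pred / m.n_true)


def sequence_match_score(m: MatchResult, pred, truth) -> float:
    """100 x identically typed pairs / pairs (0 with a flag when no pairs)."""
    if not m.pairs:
        return 0.0
    _, pt = _ca_table(pred)
    _, tt = _ca_table(truth)
    same = sum(1 for i, j, _ in m.pairs if pt[i] == tt[j])
    return 100.0 * same / len(m.pairs)


def inframe_tm_score(pred, truth, cutoff: float = 8.0) -> float:
    """TM-score over the in-frame pairing, normalized by the true length.

    TM = (1/n_true) * sum_pairs 1 / (1 + (d_i/d0)^2) with
    d0 = max(1.24*(n_true-15)^(1/3) - 1.8, 0.5); pairing from match_ca at
    a permissive cutoff (default 8 A).
    """
    _, tt = _ca_table(truth)
    n_true = len(tt)
    if n_true < 3:
        raise ValueError("truth must have at least 3 residues for a TM-score")
    m = match_ca(pred, truth, cutoff=cutoff)
    d0 = max(1.24 * np.cbrt(n_true - 15.0) - 1.8, 0.5)
    total = sum(1.0 / (1.0 + (d / d0) ** 2) for _, _, d in m.pairs)
    return float(total / n_true)


def evaluate(pred, truth, cutoff: float = 3.0) -> dict:
    """All metrics as a flat report dictionary."""
    m = match_ca(pred, truth, cutoff=cutoff)
    return {
        "n_pred": m.n_pred,
        "n_true": m.n_true,
        "n_matched": len(m.pairs),
        "ca_match": ca_match_score(m),
        "ca_quality": ca_quality_score(m),
        "sequence_match": sequence_match_score(m, pred, truth),
        "tm_score": inframe_tm_score(pred, truth),
        "flags": m.flags,
    }


def write_report(report: dict, path) -> None:
    """Tab-separated key/value metric report."""
    with open(path, "w") as f:
        for k, v in report.items():
            if isinstance(v, float):
                f.write(f"{k}\t{v:.4f}\n")
            elif isinstance(v, list):
                f.write(f"{k}\t{','.join(map(str, v))}\n")
            else:
                f.write(f"{k}\t{v}\n")
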