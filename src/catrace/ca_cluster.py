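"""Convert Calpha probability volumes into refined point candidates.

Voxels whose Calpha probability exceeds 0.3 are grouped by density-based
clustering (DBSCAN, eps 1.8 A, min_samples 1) on their world coordinates,
weak clusters are filtered against the best cluster's mean backbone
probability, and each surviving cluster is reduced to a candidate point:
a probability-weighted centroid with an aggregated 20-way amino-acid
profile.  Non-maximum suppression removes near-duplicate candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import DBSCAN

from .constants import N_AA
from .map_io import DensityMap
from .network import PredictionVolumes
from .struct_codec import index_to_coord


@dataclass
class ClusterConfig:
    ca_threshold: float = 0.3   # minimum calpha probability per voxel
    eps: float = 1.8            # DBSCAN linkage radius, A
    min_samples: int = 1
    bb_keep_fraction: float = 0.5  # keep clusters >= fraction of best mean bb prob
    nms_radius: float = 2.0     # suppression radius, A
    link_min: float = 2.0       # candidate neighbor range, A
    link_max: float = 6.0


@dataclass
class CaCandidate:
    """A refined Calpha point candidate."""

    position: np.ndarray        # world (x, y, z) coordinate, A
    ca_score: float             # aggregated calpha probability
    bb_score: float             # aggregated backbone probability
    aa_profile: np.ndarray      # 20-vector, sums to 1
    neighbors: list[int] = field(default_factory=list)  # candidate ids in link range


def cluster_ca_voxels(pred: PredictionVolumes, geom: DensityMap,
                      config: ClusterConfig | None = None) -> list[np.ndarray]:
    """Group above-threshold Calpha voxels into clusters of voxel indices.

    Returns a list of (m, 3) integer index arrays; every voxel with
    ``calpha_p`` above the threshold belongs to exactly one cluster.  An
    empty list is valid when no voxel passes the threshold.
    """
    cfg = config or ClusterConfig()
    idx = np.argwhere(pred.calpha_p > cfg.ca_threshold)
    if len(idx) == 0:
        return []
    coords = index_to_coord(idx, geom.origin, geom.voxel)
    labels = DBSCAN(eps=cfg.eps, min_samples=cfg.min_samples).fit_predict(coords)
    clusters = []
    for lab in np.unique(labels):
        clusters.append(idx[labels == lab])
    return clusters


def filter_clusters(clusters: list[np.ndarray], pred: PredictionVolumes,
                    config: ClusterConfig | None = None) -> list[np.ndarray]:
    """Retain clusters whose mean backbone probability is at least the
    configured fraction (default 50%) of the best cluster's mean."""
    cfg = config or ClusterConfig()
    if not clusters:
        return []
    means = np.array([
        float(np.mean(pred.backbone_p[tuple(c.T)])) for c in clusters])
    cut = cfg.bb_keep_fraction * means.max()
    return [c for c, m in zip(clusters, means) if m >= cut]


def build_candidates(clusters: list[np.ndarray], pred: PredictionVolumes,
                     geom: DensityMap,
                     config: ClusterConfig | None = None) -> list[CaCandidate]:
    """Reduce clusters to candidate points.

    Position and amino-acid profile are calpha_p-weighted aggregates over
    the member voxels; candidates closer than the NMS radius are resolved
    in favor of the higher ca_score; surviving candidates get neighbor
    lists within the 2-6 A link range.
    """
    cfg = config or ClusterConfig()
    cands: list[CaCandidate] = []
    for c in clusters:
        sel = tuple(c.T)
        w = pred.calpha_p[sel].astype(np.float64)
        w = w / w.sum()
        centers = index_to_coord(c, geom.origin, geom.voxel)
        pos = (w[:, None] * centers).sum(axis=0)
        profile = (pred.amino_p[(slice(None),) + sel] * w).sum(axis=1)
        s = profile.sum()
        profile = profile / s if s > 0 else np.full(N_AA, 1.0 / N_AA)
        cands.append(CaCandidate(
            position=pos,
            ca_score=float(pred.calpha_p[sel].max()),
            bb_score=float(np.mean(pred.backbone_p[sel])),
            aa_profile=profile.astype(np.float64)))
    # non-maximum suppression: process by descending ca_score
    order = sorted(range(len(cands)), key=lambda i: -cands[i].ca_score)
    kept: list[CaCandidate] = []
    for i in order:
        c = cands[i]
        if all(np.linalg.norm(c.position - k.position) >= cfg.nms_radius
               for k in kept):
            kept.append(c)
    if kept:
        pos = np.array([c.position for c in kept])
        d = cdist(pos, pos)
        for i, c in enumerate(kept):
            near = np.nonzero((d[i] >= cfg.link_min) & (d[i] <= cfg.link_max))[0]
            c.neighbors = [int(j) for j in near if j != i]
    return kept


def candidates_from_predictions(pred: PredictionVolumes, geom: DensityMap,
                                config: ClusterConfig | None = None) -> list[CaCandidate]:
    """Full clustering stage: threshold, cluster, filter, refine, suppress."""
    cfg = config or ClusterConfig()
    clusters = cluster_ca_voxels(pred, geom, cfg)
    clusters = filter_clusters(clusters, pred, cfg)
    return build_candidates(clusters, pred, geom, cfg)


def write_candidate_table(cands: list[CaCandidate], path) -> None:
    """Tab-separated candidate table: id, x, y, z, ca_score, bb_score, 20 aa."""
    from .constants import AA_ORDER

    with open(path, "w") as f:
        f.write("id\tx\ty\tz\tca_score\tbb_score\t" +
                "\t".join(AA_ORDER) + "\n")
        for i, c in enumerate(cands):
            row = [str(i)] + [f"{v:.3f}" for v in c.position]
            row += [f"{c.ca_score:.4f}", f"{c.bb_score:.4f}"]
            row += [f"{p:.4f}" for p in c.aa_profile]
            f.write("\t".join(row) + "\n")
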