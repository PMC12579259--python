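"""Desk-scale synthetic fixtures for the whole pipeline.

Generates toy multi-chain protein complexes with realistic Calpha spacing,
renders Gaussian-kernel density maps at a nominal resolution with additive
noise, produces "predicted-structure surrogates" by per-domain rigid
perturbation plus per-atom jitter (with optional domain dropout, emulating
partial docking), and builds oracle probability volumes from ground-truth
label masks so that clustering and tracing can be exercised without a
trained network.

The defaults describe the study conditions used throughout the test suite:
2 chains of 60 residues, a 3.0 Angstrom nominal resolution, 5% additive
noise, and mild prior perturbation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import map_io, struct_codec
from .constants import AA_ORDER, N_AA
from .map_io import DensityMap
from .network import PredictionVolumes
from .struct_codec import Chain, LabelMasks, Residue, StructureModel


class GenerationError(RuntimeError):
    """Raised when a toy complex cannot be packed without clashes."""


@dataclass
class PerturbConfig:
    """Per-domain rigid perturbation magnitudes for the prior surrogate."""

    rot_deg: float = 5.0          # rotation angle per pseudo-domain
    trans_ang: float = 2.0        # translation magnitude per pseudo-domain, A
    jitter_sd: float = 0.3        # per-atom Gaussian jitter sigma, A
    domain_drop_prob: float = 0.0 # probability a pseudo-domain is dropped


@dataclass
class SimConfig:
    n_chains: int = 2
    residues_per_chain: int = 60
    resolution: float = 3.0       # nominal resolution in A (Gaussian FWHM)
    noise_sd: float = 0.05        # additive noise sigma relative to map peak
    perturb: PerturbConfig = field(default_factory=PerturbConfig)
    corruption: float = 0.0       # label-flip rate for oracle volumes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for p in (self.perturb.domain_drop_prob, self.corruption):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


# ---------------------------------------------------------------------------
# toy complex generation
# ---------------------------------------------------------------------------

_CA_STEP = 3.8            # consecutive Calpha spacing, A
_MIN_NONCONSEC = 3.2      # minimum allowed non-consecutive Calpha distance, A
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TURN = np.deg2rad(99.1)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _helix_points(n: int) -> np.ndarray:
    """Ideal alpha-helical Calpha positions along +z in a local frame."""
    t = np.arange(n)
    return np.stack([
        _HELIX_RADIUS * np.cos(t * _HELIX_TURN),
        _HELIX_RADIUS * np.sin(t * _HELIX_TURN),
        _HELIX_RISE * t,
    ], axis=1)


def _grow_chain(rng: np.random.Generator, n_res: int, start: np.ndarray,
                existing: list[np.ndarray], max_tries: int = 60) -> np.ndarray:
    """Grow a chain as connected helix segments with clash rejection."""
    coords: list[np.ndarray] = []
    pos = start.copy()
    remaining = n_res
    while remaining > 0:
        seg_len = int(min(remaining, rng.integers(8, 16)))
        placed = None
        for _ in range(max_tries):
            R = _random_rotation(rng)
            local = _helix_points(seg_len + 1)
            pts = (local - local[0]) @ R.T
            # continue 3.8 A from the previous residue along the segment start
            if coords:
                step = pts[1] - pts[0]
                anchor = coords[-1] + step / np.linalg.norm(step) * _CA_STEP
                seg = pts[1:] - pts[1] + anchor
            else:
                seg = pts[:seg_len] + pos
            ok = True
            prior = coords[:-1] if coords else []
            check_against = ([np.array(prior)] if prior else []) + existing
            for arr in check_against:
                if arr.size and np.min(
                    np.linalg.norm(arr[:, None, :] - seg[None, :, :], axis=2)
                ) < _MIN_NONCONSEC:
                    ok = False
                    break
            # junction: the connecting residue is consecutive with seg[0] but
            # must stay clear of the rest of the new segment
            if ok and coords and len(seg) > 1:
                if np.min(np.linalg.norm(seg[1:] - coords[-1], axis=1)) < _MIN_NONCONSEC:
                    ok = False
            if ok and len(seg) > 1:
                d_in = np.linalg.norm(seg[:, None] - seg[None, :], axis=2)
                iu = np.triu_indices(len(seg), 2)
                if iu[0].size and d_in[iu].min() < _MIN_NONCONSEC:
                    ok = False
            if ok:
                placed = seg
                break
        if placed is None:
            raise GenerationError("could not place a clash-free helix segment")
        coords.extend(placed)
        remaining -= len(placed)
    return np.array(coords[:n_res])


def _backbone_atoms(ca: np.ndarray, i: int, n: int) -> dict[str, np.ndarray]:
    """Idealized N, C, O offsets from a Calpha given the local chain direction."""
    prev_ca = ca[max(i - 1, 0)]
    next_ca = ca[min(i + 1, n - 1)]
    t = next_ca - prev_ca
    nt = np.linalg.norm(t)
    t = t / nt if nt > 1e-9 else np.array([1.0, 0.0, 0.0])
    ref = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(t, ref)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    c = ca[i]
    n_at = c - 1.2 * t + 0.8 * u
    c_at = c + 1.2 * t + 0.8 * v
    o_at = c_at + 1.23 * v
    return {"CA": c.copy(), "N": n_at, "C": c_at, "O": o_at}


def generate_toy_complex(config: SimConfig, seed: int | None = None):
    """Build a seeded toy complex.

    Returns ``(structure, sequences)`` where ``sequences`` maps chain id to
    one-letter sequence.  Chains are connected ideal-helix segments with
    consecutive Calpha spacing 3.8 +/- 0.1 A, backbone N/C/O at fixed ideal
    offsets, uniformly drawn amino-acid types, and no steric overlap.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    chains = []
    seqs: dict[str, str] = {}
    existing: list[np.ndarray] = []
    for c in range(config.n_chains):
        chain_id = chr(ord("A") + c)
        start = rng.uniform(-1, 1, 3) * 5 + np.array([22.0 * c, 0.0, 0.0])
        for attempt in range(8):
            try:
                ca = _grow_chain(rng, config.residues_per_chain, start, existing)
                break
            except GenerationError:
                start = rng.uniform(-1, 1, 3) * 10 + np.array([22.0 * c, 0.0, 0.0])
        else:
            raise GenerationError(f"failed to pack chain {chain_id}")
        existing.append(ca)
        aa_idx = rng.integers(0, N_AA, config.residues_per_chain)
        residues = [
            Residue(i + 1, AA_ORDER[aa_idx[i]],
                    _backbone_atoms(ca, i, config.residues_per_chain))
            for i in range(config.residues_per_chain)
        ]
        chain = Chain(chain_id, residues)
        chains.append(chain)
        seqs[chain_id] = chain.sequence
    return StructureModel(chains), seqs


# ---------------------------------------------------------------------------
# density simulation
# ---------------------------------------------------------------------------

def simulate_density(struct: StructureModel, config: SimConfig,
                     seed: int | None = None) -> DensityMap:
    """Render a normalized synthetic density map on a 1 A grid.

    Each atom contributes an isotropic Gaussian ``exp(-|v - x|^2 / 2 sigma^2)``
    with ``sigma = resolution / 2.355`` (FWHM equal to the nominal
    resolution).  Seeded Gaussian noise of ``noise_sd`` times the peak is
    added before normalization.  The grid has 10 A margins on every side.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    coords = np.array([c for _, _, _, c in struct.iter_atoms()])
    lo = np.floor(coords.min(axis=0)) - 10.0   # (x, y, z)
    hi = np.ceil(coords.max(axis=0)) + 10.0
    origin = tuple(lo)
    shape = tuple(int(h - l) + 1 for l, h in zip(lo, hi))[::-1]  # (nz, ny, nx)
    sigma = config.resolution / 2.355
    r = int(np.ceil(3.5 * sigma))
    data = np.zeros(shape, dtype=np.float64)
    for x, y, z in coords:
        (ci, cj, ck), _ = struct_codec.coord_to_index((x, y, z), origin, (1, 1, 1))
        i0, i1 = max(ci - r, 0), min(ci + r + 1, shape[0])
        j0, j1 = max(cj - r, 0), min(cj + r + 1, shape[1])
        k0, k1 = max(ck - r, 0), min(ck + r + 1, shape[2])
        zi = origin[2] + np.arange(i0, i1)
        yj = origin[1] + np.arange(j0, j1)
        xk = origin[0] + np.arange(k0, k1)
        d2 = ((zi - z)[:, None, None] ** 2
              + (yj - y)[None, :, None] ** 2
              + (xk - x)[None, None, :] ** 2)
        data[i0:i1, j0:j1, k0:k1] += np.exp(-d2 / (2 * sigma ** 2))
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd * data.max(), shape)
    raw = DensityMap(data.astype(np.float32), voxel=(1.0, 1.0, 1.0), origin=origin)
    return map_io.normalize_map(raw)


# ---------------------------------------------------------------------------
# prior surrogate
# ---------------------------------------------------------------------------

def _pseudo_domains(n_res: int) -> list[slice]:
    """Contiguous thirds of a chain, standing in for domain parsing."""
    cut1, cut2 = n_res // 3, 2 * n_res // 3
    return [s for s in (slice(0, cut1), slice(cut1, cut2), slice(cut2, n_res))
            if s.stop > s.start]


def perturb_structure(struct: StructureModel, config: SimConfig,
                      seed: int | None = None) -> StructureModel:
    """Emulate predicted-structure error and partial docking.

    Chains are split into contiguous thirds; each pseudo-domain receives a
    seeded rigid rotation (about its centroid) and translation at the
    configured magnitudes plus per-atom Gaussian jitter, and is dropped
    entirely with probability ``domain_drop_prob``.
    """
    p = config.perturb
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    chains = []
    for ch in struct.chains:
        residues: list[Residue] = []
        for dom in _pseudo_domains(len(ch.residues)):
            dom_res = ch.residues[dom]
            if rng.random() < p.domain_drop_prob:
                continue
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = np.deg2rad(p.rot_deg) * rng.normal()
            K = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
            tdir = rng.normal(size=3)
            tdir /= np.linalg.norm(tdir)
            t = tdir * p.trans_ang * abs(rng.normal())
            centroid = np.mean([r.ca for r in dom_res], axis=0)
            for r in dom_res:
                atoms = {}
                for name, c in r.atoms.items():
                    c2 = R @ (c - centroid) + centroid + t
                    if p.jitter_sd > 0:
                        c2 = c2 + rng.normal(0.0, p.jitter_sd, 3)
                    atoms[name] = c2
                residues.append(Residue(r.seq_index, r.aa_type, atoms))
        if residues:
            chains.append(Chain(ch.chain_id, residues))
    return StructureModel(chains)


# ---------------------------------------------------------------------------
# oracle prediction volumes
# ---------------------------------------------------------------------------

def oracle_predictions(masks: LabelMasks, corruption: float = 0.0,
                       seed: int = 0) -> PredictionVolumes:
    """Probability volumes derived directly from ground-truth masks.

    Target-class voxels (label 3) get probability 0.95, other-atom and
    neighbour voxels 0.3, background 0.01; the amino-acid profile is one-hot
    at 0.9 with the remaining 0.1 spread over the other 19 types.  With
    corruption rate ``c``, a seeded fraction ``c`` of Calpha voxels have
    their amino-acid label shuffled to a wrong type, and half of those are
    additionally suppressed in the Calpha probability (emulating missed
    detections).
    """
    if not 0.0 <= corruption <= 1.0:
        raise ValueError("corruption must be in [0, 1]")
    rng = np.random.default_rng(seed)

    def class_prob(mask: np.ndarray) -> np.ndarray:
        p = np.full(mask.shape, 0.01, dtype=np.float32)
        p[mask == 1] = 0.3
        p[mask == 2] = 0.3
        p[mask == 3] = 0.95
        return p

    backbone_p = class_prob(masks.backbone)
    calpha_p = class_prob(masks.calpha)
    amino = masks.amino.copy()

    ca_idx = np.argwhere(masks.calpha == 3)
    if corruption > 0 and len(ca_idx):
        pick = rng.random(len(ca_idx)) < corruption
        for m, (i, j, k) in enumerate(ca_idx):
            if not pick[m]:
                continue
            true_label = amino[i, j, k]
            wrong = int(rng.integers(1, N_AA))  # 1..19 offset guarantees a change
            amino[i, j, k] = (true_label - 1 + wrong) % N_AA + 1
            if rng.random() < 0.5:
                calpha_p[i, j, k] = 0.1
    amino_p = np.full((N_AA,) + masks.amino.shape, 1.0 / N_AA, dtype=np.float32)
    labeled = amino > 0
    if labeled.any():
        spread = 0.1 / (N_AA - 1)
        amino_p[:, labeled] = spread
        lab = amino[labeled] - 1
        amino_p[lab, *np.nonzero(labeled)] = 0.9
    return PredictionVolumes(backbone_p=backbone_p, calpha_p=calpha_p, amino_p=amino_p)


# ---------------------------------------------------------------------------
# fixture bundles
# ---------------------------------------------------------------------------

def write_fixture_bundle(config: SimConfig, outdir) -> dict:
    """Simulate a complex and write MRC + PDB + FASTA files plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    struct, seqs = generate_toy_complex(config)
    dmap = simulate_density(struct, config)
    prior = perturb_structure(struct, config)
    map_io.write_map(dmap, outdir / "map.mrc")
    struct_codec.write_structure(struct, outdir / "truth.pdb")
    struct_codec.write_structure(prior, outdir / "prior.pdb")
    struct_codec.write_fasta(seqs, outdir / "sequences.fasta")
    manifest = {
        "config": dataclasses.asdict(config),
        "files": {"map": "map.mrc", "truth": "truth.pdb",
                  "prior": "prior.pdb", "sequences": "sequences.fasta"},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
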