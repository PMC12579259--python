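"""Structures, sequences, voxelization and label generation.

This module owns the world-to-grid index mapping, the 24-channel binary
prior encoding of a placed predicted structure, and the three ground-truth
label masks (backbone / Calpha / amino-acid type) used to train the voxel
classifier.  It also provides the length-based domain splitter and the
known-transform placement used in place of a density-guided docking search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .constants import (
    AA_INDEX,
    AA_ORDER,
    BACKBONE_ATOMS,
    N_ENCODE_CHANNELS,
    ONE_TO_THREE,
    THREE_TO_ONE,
)
from .map_io import DensityMap

log = logging.getLogger(__name__)


@dataclass
class Residue:
    seq_index: int                      # 1-based position in the chain
    aa_type: str                        # three-letter code, one of the 20
    atoms: dict[str, np.ndarray]        # atom name -> world (x, y, z) in A

    def __post_init__(self) -> None:
        if self.aa_type not in AA_INDEX:
            raise ValueError(f"unknown amino-acid type {self.aa_type!r}")
        self.atoms = {k: np.asarray(v, dtype=float) for k, v in self.atoms.items()}

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        idx = [r.seq_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"chain {self.chain_id}: residue indices not strictly increasing")

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE[r.aa_type] for r in self.residues)


@dataclass
class StructureModel:
    chains: list[Chain] = field(default_factory=list)

    def iter_residues(self):
        for ch in self.chains:
            for res in ch.residues:
                yield ch, res

    def iter_atoms(self):
        for ch, res in self.iter_residues():
            for name, coord in res.atoms.items():
                yield ch, res, name, coord

    @property
    def n_residues(self) -> int:
        return sum(len(ch.residues) for ch in self.chains)

    def all_ca(self) -> np.ndarray:
        """(N, 3) array of Calpha coordinates in residue order."""
        cas = [r.ca for _, r in self.iter_residues() if "CA" in r.atoms]
        return np.array(cas) if cas else np.empty((0, 3))

    def sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain."""
        from .constants import THREE_TO_ONE

        for ch in self.chains:
            if ch.chain_id == chain_id:
                return "".join(THREE_TO_ONE[r.aa_type] for r in ch.residues)
        raise KeyError(f"no chain {chain_id!r}")


@dataclass
class EncodedVolume:
    """24 x map-shape binary occupancy volume of a placed structure."""

    data: np.ndarray  # uint8 (24, nz, ny, nx), values in {0, 1}

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[0] != N_ENCODE_CHANNELS:
            raise ValueError(f"encoded volume must be ({N_ENCODE_CHANNELS}, *map), got {self.data.shape}")


@dataclass
class LabelMasks:
    backbone: np.ndarray  # labels {0,1,2,3}
    calpha: np.ndarray    # labels {0,1,2,3}
    amino: np.ndarray     # labels {0..20}


# ---------------------------------------------------------------------------
# world <-> grid
# ---------------------------------------------------------------------------

def coord_to_index(
    coord,
    origin: tuple[float, float, float],
    voxel: tuple[float, float, float],
    shape: tuple[int, int, int] | None = None,
):
    """Map a world coordinate (x, y, z) to grid indices (i, j, k).

    ``i`` is derived from ``z``, ``j`` from ``y`` and ``k`` from ``x``; each
    index is the round-half-up nearest integer of ``(coord - origin)/voxel``.
    Returns ``(i, j, k), in_grid``; out-of-grid atoms are flagged, never
    clamped.  When ``shape`` is None the flag is always True.
    """
    if any(v <= 0 for v in voxel):
        raise ValueError(f"voxel spacings must be positive, got {voxel}")
    x, y, z = (float(c) for c in coord)
    k = int(np.floor((x - origin[0]) / voxel[0] + 0.5))
    j = int(np.floor((y - origin[1]) / voxel[1] + 0.5))
    i = int(np.floor((z - origin[2]) / voxel[2] + 0.5))
    in_grid = True
    if shape is not None:
        in_grid = 0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]
    return (i, j, k), in_grid


def index_to_coord(index, origin, voxel) -> np.ndarray:
    """World coordinate (x, y, z) of the centre of voxel (i, j, k).

    ``index`` may be a single (i, j, k) triple or an (m, 3) array of
    indices; the result has the matching shape with world axes (x, y, z).
    """
    arr = np.asarray(index, dtype=np.float64)
    if arr.ndim == 2:
        out = np.empty_like(arr)
        out[:, 0] = origin[0] + arr[:, 2] * voxel[0]
        out[:, 1] = origin[1] + arr[:, 1] * voxel[1]
        out[:, 2] = origin[2] + arr[:, 0] * voxel[2]
        return out
    i, j, k = arr
    return np.array([
        origin[0] + k * voxel[0],
        origin[1] + j * voxel[1],
        origin[2] + i * voxel[2],
    ])


# ---------------------------------------------------------------------------
# encoding and labels
# ---------------------------------------------------------------------------

def encode_structure(struct: StructureModel, geom: DensityMap) -> EncodedVolume:
    """Binary channel-wise encoding of a structure on the map grid.

    Channels 0-3 mark voxels holding CA/N/C/O atoms; the amino-acid channel
    of a residue is set at every voxel holding any atom of that residue.
    Atoms falling outside the grid are skipped (counted in the log).
    """
    shape = geom.shape
    enc = np.zeros((N_ENCODE_CHANNELS,) + shape, dtype=np.uint8)
    skipped = 0
    for ch, res, name, coord in struct.iter_atoms():
        (i, j, k), ok = coord_to_index(coord, geom.origin, geom.voxel, shape)
        if not ok:
            skipped += 1
            continue
        if name in BACKBONE_ATOMS:
            enc[BACKBONE_ATOMS.index(name), i, j, k] = 1
        enc[4 + AA_INDEX[res.aa_type], i, j, k] = 1
    if skipped:
        log.info("encode_structure: skipped %d atoms outside the grid", skipped)
    return EncodedVolume(enc)


def _neighbor_shell(mask: np.ndarray) -> np.ndarray:
    """26-connected one-voxel dilation shell around True voxels."""
    from scipy import ndimage

    dil = ndimage.binary_dilation(mask, structure=np.ones((3, 3, 3), bool))
    return dil & ~mask


def make_label_masks(struct: StructureModel, geom: DensityMap) -> LabelMasks:
    """Build the three ground-truth masks for a structure placed in the map.

    backbone: any of {CA, N, C, O} -> 3, other atoms -> 2, 26-neighbours of
    any atom -> 1, else 0.  calpha: CA -> 3, other atoms -> 2, neighbours ->
    1.  amino: Calpha voxels and their 26-neighbours carry the residue type
    (1-20); voxel collisions are resolved in favour of the residue whose
    Calpha is nearest the voxel centre.
    """
    shape = geom.shape
    backbone = np.zeros(shape, dtype=np.uint8)
    calpha = np.zeros(shape, dtype=np.uint8)
    amino = np.zeros(shape, dtype=np.uint8)

    atom_vox = np.zeros(shape, dtype=bool)
    bb_vox = np.zeros(shape, dtype=bool)
    ca_vox = np.zeros(shape, dtype=bool)
    ca_entries = []  # (index, aa_label, ca_world)
    for ch, res, name, coord in struct.iter_atoms():
        (i, j, k), ok = coord_to_index(coord, geom.origin, geom.voxel, shape)
        if not ok:
            continue
        atom_vox[i, j, k] = True
        if name in BACKBONE_ATOMS:
            bb_vox[i, j, k] = True
        if name == "CA":
            ca_vox[i, j, k] = True
            ca_entries.append(((i, j, k), AA_INDEX[res.aa_type] + 1, coord))

    shell = _neighbor_shell(atom_vox)
    backbone[shell] = 1
    backbone[atom_vox] = 2
    backbone[bb_vox] = 3
    calpha[shell] = 1
    calpha[atom_vox] = 2
    calpha[ca_vox] = 3

    # amino labels: nearest-Calpha wins on collision
    best_d2 = np.full(shape, np.inf)
    for (i, j, k), label, ca_world in ca_entries:
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    ii, jj, kk = i + di, j + dj, k + dk
                    if not (0 <= ii < shape[0] and 0 <= jj < shape[1] and 0 <= kk < shape[2]):
                        continue
                    centre = index_to_coord((ii, jj, kk), geom.origin, geom.voxel)
                    d2 = float(np.sum((centre - ca_world) ** 2))
                    if d2 < best_d2[ii, jj, kk]:
                        best_d2[ii, jj, kk] = d2
                        amino[ii, jj, kk] = label
    return LabelMasks(backbone=backbone, calpha=calpha, amino=amino)


# ---------------------------------------------------------------------------
# domain surrogates
# ---------------------------------------------------------------------------

def split_domains(struct: StructureModel, max_len: int) -> list[StructureModel]:
    """Length-based splitter standing in for structural domain parsing.

    A single chain is cut into contiguous segments of at most ``max_len``
    residues; concatenating the segments reproduces the chain.
    """
    if len(struct.chains) != 1:
        raise ValueError("split_domains expects a single-chain structure")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    chain = struct.chains[0]
    out = []
    for start in range(0, len(chain.residues), max_len):
        seg = chain.residues[start:start + max_len]
        out.append(StructureModel([Chain(chain.chain_id, list(seg))]))
    return out


def place_structure(struct: StructureModel, rotation, translation) -> StructureModel:
    """Apply a rigid transform (x -> R x + t) to every atom.

    Stands in for a density-guided docking search when the placement
    transform is known or simulated.  ``rotation`` must be orthonormal with
    determinant +1.
    """
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8) \
            or not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
        raise ValueError("rotation must be a proper orthonormal 3x3 matrix")
    chains = []
    for ch in struct.chains:
        residues = [
            Residue(r.seq_index, r.aa_type, {n: R @ c + t for n, c in r.atoms.items()})
            for r in ch.residues
        ]
        chains.append(Chain(ch.chain_id, residues))
    return StructureModel(chains)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_structure(path, altloc_policy: str = "highest_occupancy") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only residues of the 20 canonical types are kept; alternate locations
    resolve to the highest-occupancy conformer (gemmi default ordering).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.remove_alternative_conformations()
    model = st[0]
    chains = []
    for ch in model:
        residues = []
        for res in ch:
            if res.name not in AA_INDEX:
                continue
            atoms = {at.name: np.array([at.pos.x, at.pos.y, at.pos.z]) for at in res}
            if "CA" not in atoms:
                continue
            residues.append(Residue(res.seqid.num, res.name, atoms))
        if residues:
            chains.append(Chain(ch.name, residues))
    return StructureModel(chains)


def write_structure(struct: StructureModel, path) -> None:
    """Write a structure as a PDB file."""
    st = gemmi.Structure()
    st.name = "catrace"
    model = gemmi.Model("1")
    for ch in struct.chains:
        gch = gemmi.Chain(ch.chain_id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.aa_type
            gres.seqid = gemmi.SeqId(res.seq_index, " ")
            for name, coord in res.atoms.items():
                at = gemmi.Atom()
                at.name = name
                at.element = gemmi.Element(name[0])
                at.pos = gemmi.Position(*coord)
                at.occ = 1.0
                gres.add_atom(at)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def read_fasta(path) -> dict[str, str]:
    """Read chain sequences from a FASTA file, keyed by record id."""
    seqs: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            else:
                parts.append(line)
    if name is not None:
        seqs[name] = "".join(parts)
    for k, s in seqs.items():
        bad = set(s.upper()) - set(ONE_TO_THREE)
        if bad:
            raise ValueError(f"sequence {k} has unknown residue letters {sorted(bad)}")
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
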