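"""Reading, standardizing, partitioning and stitching cryo-EM density volumes.

Maps are MRC2014 files (read/written through :mod:`gemmi`).  Internally a
volume is stored as ``data[i, j, k]`` with ``i`` on world ``z``, ``j`` on
``y`` and ``k`` on ``x`` (see :mod:`catrace.constants`).  The preprocessing
pipeline is: resample to a 1 Angstrom grid, normalize (median background
subtraction, 99.9th-percentile clipping, min-max scaling to [0, 1]), then
partition into 48-cube cores padded to 64-cube processing windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy import ndimage

from .constants import CORE_SIZE, PAD_SIZE, PATCH_SIZE


class MapFormatError(ValueError):
    """Raised for malformed or non-3D MRC input."""


@dataclass
class DensityMap:
    """A 3D scalar density volume with its world-frame anchor.

    Attributes
    ----------
    data:
        float32 volume indexed ``[i, j, k]`` = (z, y, x).
    voxel:
        voxel spacing ``(voxel_x, voxel_y, voxel_z)`` in Angstrom.
    origin:
        world coordinate ``(origin_x, origin_y, origin_z)`` of grid index
        ``(0, 0, 0)`` in Angstrom.
    """

    data: np.ndarray
    voxel: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise MapFormatError(f"density volume must be 3D, got {self.data.ndim}D")
        if any(v <= 0 for v in self.voxel):
            raise ValueError(f"voxel spacings must be positive, got {self.voxel}")
        self.voxel = tuple(float(v) for v in self.voxel)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # (nz, ny, nx)


@dataclass
class GridPatch:
    """A 64-cube processing window around a 48-cube core.

    ``core_offset`` is the (i, j, k) index of the core's first voxel inside
    the parent map; its components are multiples of 48.  ``data`` is
    ``(64, 64, 64)`` for a single channel or ``(C, 64, 64, 64)`` for
    multi-channel volumes.
    """

    data: np.ndarray
    core_offset: tuple[int, int, int]

    @property
    def channel_count(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[0]


def read_map(path) -> DensityMap:
    """Read an MRC2014 map, normalizing the axis order to (z, y, x).

    Files whose axis correspondence words (MAPC/MAPR/MAPS) are permuted are
    reordered to the internal convention.  The world origin is taken from
    the ORIGIN header words, falling back to NXSTART/NYSTART/NZSTART times
    the voxel spacing when ORIGIN is all zero.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read MRC map {path}: {exc}") from exc
    if any(m.header_i32(w) <= 0 for w in (1, 2, 3)):
        raise MapFormatError(f"map {path} is not a 3D volume")
    # normalize axis order so that the grid's numpy axes are (x, y, z)
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = m.grid
    arr = np.array(grid, copy=True)  # axes (x, y, z)
    if arr.ndim != 3:
        raise MapFormatError(f"map {path} is not a 3D volume")
    voxel = tuple(float(s) for s in grid.spacing)  # (vx, vy, vz)
    if any(v <= 0 for v in voxel):
        # gemmi leaves spacing unset for maps that do not cover the full
        # unit cell (e.g. nonzero NXSTART); fall back to cell / sampling
        m_samp = [m.header_i32(w) for w in (8, 9, 10)]
        cell = [m.header_float(w) for w in (11, 12, 13)]
        if any(s <= 0 for s in m_samp) or any(c <= 0 for c in cell):
            raise MapFormatError(f"map {path} has no usable voxel spacing")
        voxel = tuple(c / s for c, s in zip(cell, m_samp))
    origin = tuple(float(m.header_float(w)) for w in (50, 51, 52))
    if origin == (0.0, 0.0, 0.0):
        nstart = [m.header_i32(w) for w in (5, 6, 7)]
        origin = tuple(float(n) * v for n, v in zip(nstart, voxel))
    data = np.ascontiguousarray(arr.transpose(2, 1, 0), dtype=np.float32)
    return DensityMap(data=data, voxel=voxel, origin=origin)


def write_map(dmap: DensityMap, path) -> None:
    """Write a map as MRC2014 mode-2 float, preserving spacing and origin."""
    nz, ny, nx = dmap.shape
    vx, vy, vz = dmap.voxel
    grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.data.transpose(2, 1, 0)))
    grid.set_unit_cell(gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90.0, 90.0, 90.0))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for w, o in zip((50, 51, 52), dmap.origin):
        m.set_header_float(w, float(o))
    m.write_ccp4_map(str(path))


def resample_map(dmap: DensityMap, target: float = 1.0) -> DensityMap:
    """Resample to an isotropic ``target`` Angstrom grid by trilinear interpolation.

    The output grid covers the input's world-space box (to within one output
    voxel) and keeps the same origin.  A map already at the target spacing
    is returned unchanged.
    """
    if target <= 0:
        raise ValueError(f"target spacing must be positive, got {target}")
    if all(abs(v - target) < 1e-12 for v in dmap.voxel):
        return replace(dmap, data=dmap.data.copy())
    vx, vy, vz = dmap.voxel
    nz, ny, nx = dmap.shape
    # voxel counts covering the same world extent
    new_n = [max(1, int(np.ceil(n * v / target))) for n, v in ((nz, vz), (ny, vy), (nx, vx))]
    coords = np.meshgrid(
        np.arange(new_n[0]) * target / vz,
        np.arange(new_n[1]) * target / vy,
        np.arange(new_n[2]) * target / vx,
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        dmap.data, np.stack([c.ravel() for c in coords]), order=1, mode="nearest"
    ).reshape(new_n)
    return DensityMap(out.astype(np.float32), voxel=(target,) * 3, origin=dmap.origin)


def normalize_map(dmap: DensityMap) -> DensityMap:
    """Standardize density values to [0, 1].

    Pipeline: subtract the median of all voxels, clip values above the
    99.9th percentile of the subtracted volume, floor negatives at zero,
    then min-max scale.  A constant input maps to all zeros.
    """
    if dmap.data.size == 0:
        raise ValueError("cannot normalize an empty volume")
    x = dmap.data.astype(np.float64)
    x = x - np.median(x)
    hi = np.percentile(x, 99.9)
    x = np.minimum(x, hi)
    x = np.maximum(x, 0.0)
    peak = x.max()
    if peak <= 0:
        out = np.zeros_like(x)
    else:
        out = (x - x.min()) / (peak - x.min())
    return replace(dmap, data=out.astype(np.float32))


def _n_cores(n: int) -> int:
    return -(-n // CORE_SIZE)


def partition_map(volume, origin_pad: int = PAD_SIZE) -> list[GridPatch]:
    """Tile a volume into 48-cube cores with 8 voxels of context per face.

    ``volume`` may be a :class:`DensityMap`, a 3D array, or a multi-channel
    ``(C, nz, ny, nx)`` array.  Cores tile the volume without overlap (edge
    cores zero-padded to full size); each patch is its core plus padding,
    zero-filled past the map bounds, so every patch is exactly 64-cube.
    """
    data = volume.data if isinstance(volume, DensityMap) else np.asarray(volume)
    multi = data.ndim == 4
    spatial = data.shape[1:] if multi else data.shape
    ncores = [_n_cores(n) for n in spatial]
    padded_spatial = tuple(c * CORE_SIZE + 2 * PAD_SIZE for c in ncores)
    pad_spec = [(PAD_SIZE, ps - PAD_SIZE - n) for ps, n in zip(padded_spatial, spatial)]
    if multi:
        pad_spec = [(0, 0)] + pad_spec
    padded = np.pad(data, pad_spec)
    patches = []
    for ci in range(ncores[0]):
        for cj in range(ncores[1]):
            for ck in range(ncores[2]):
                off = (ci * CORE_SIZE, cj * CORE_SIZE, ck * CORE_SIZE)
                sl = tuple(slice(o, o + PATCH_SIZE) for o in off)
                if multi:
                    sl = (slice(None),) + sl
                patches.append(GridPatch(data=padded[sl].copy(), core_offset=off))
    return patches


def stitch_volumes(patches: list[GridPatch], shape: tuple[int, int, int]) -> np.ndarray:
    """Reassemble patch cores into a volume of the original map shape.

    Only the 48-cube core of each patch is written back; all padding is
    discarded.  Multi-channel patches stitch channel-wise.  Raises if the
    patches do not cover every voxel of ``shape``.
    """
    if not patches:
        raise ValueError("no patches to stitch")
    multi = patches[0].data.ndim == 4
    nchan = patches[0].channel_count
    out_shape = (nchan,) + tuple(shape) if multi else tuple(shape)
    out = np.zeros(out_shape, dtype=patches[0].data.dtype)
    covered = np.zeros(shape, dtype=bool)
    core = slice(PAD_SIZE, PAD_SIZE + CORE_SIZE)
    for p in patches:
        oi, oj, ok = p.core_offset
        if any(o % CORE_SIZE for o in p.core_offset):
            raise ValueError(f"core offset {p.core_offset} not aligned to {CORE_SIZE}")
        ni = min(CORE_SIZE, shape[0] - oi)
        nj = min(CORE_SIZE, shape[1] - oj)
        nk = min(CORE_SIZE, shape[2] - ok)
        if min(ni, nj, nk) <= 0:
            continue
        src = p.data[..., core, core, core][..., :ni, :nj, :nk]
        out[..., oi:oi + ni, oj:oj + nj, ok:ok + nk] = src
        covered[oi:oi + ni, oj:oj + nj, ok:ok + nk] = True
    if not covered.all():
        raise ValueError("patches do not cover the full output volume")
    return out
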