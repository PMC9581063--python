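"""Cryo-EM density volumes: MRC2014 I/O, resampling, envelope extraction.

A :class:`DensityMap` is a 3D intensity grid on an axis-aligned orthogonal
lattice.  Voxel ``(i, j, k)`` (0-based) sits at world coordinate
``origin + (i, j, k) * voxel_size`` in ångströms, matching the orthogonal
coordinate frame of PDB atomic models.  All maps destined for the network are
resampled to 1 Å/voxel and are limited to 100 voxels per dimension, the design
envelope of the segmentation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

#: Hard upper bound on any grid dimension accepted by the network.
MAX_DIM = 100


class MRCFormatError(ValueError):
    """Raised when a file is not a readable MRC/CCP4 volume."""


class SizeLimitError(ValueError):
    """Raised when a grid exceeds the 100-voxel-per-dimension design limit."""


class EmptyComponentError(ValueError):
    """Raised when an envelope extraction retains no voxels."""


@dataclass
class DensityMap:
    """A 3D density grid with world-coordinate metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensity values, indexed ``(i, j, k)`` along the x, y, z axes.
    origin : ndarray, shape (3,)
        World coordinate (Å) of voxel ``(0, 0, 0)``.
    voxel_size : ndarray, shape (3,)
        Grid spacing (Å) along each axis.
    """

    data: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("density grid must be 3D with all dimensions >= 1")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_coord(self, index) -> np.ndarray:
        """World coordinate (Å) of a voxel index (may be fractional)."""
        return self.origin + np.asarray(index, dtype=np.float64) * self.voxel_size

    def copy(self) -> "DensityMap":
        return DensityMap(self.data.copy(), self.origin.copy(), self.voxel_size.copy())


@dataclass(frozen=True)
class PadSpec:
    """Per-axis zero-padding amounts; ``unpad`` inverts ``pad`` exactly."""

    pad_before: tuple[int, int, int]
    pad_after: tuple[int, int, int]

    def __post_init__(self):
        if min(self.pad_before) < 0 or min(self.pad_after) < 0:
            raise ValueError("padding amounts must be non-negative")


def read_mrc(path) -> DensityMap:
    """Read an MRC2014/CCP4 volume.

    Axis permutations declared by the MAPC/MAPR/MAPS header words are
    normalised so the returned grid is always indexed (x, y, z).  The world
    origin is ``ORIGIN + nstart * voxel_size`` so that both header dialects
    are honoured.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MRCFormatError(f"not a readable MRC volume: {path}: {exc}") from None
    mode = m.header_i32(4)
    if mode not in (0, 1, 2):
        raise MRCFormatError(f"unsupported MRC mode {mode} (int8/int16/float32 only)")
    # nstart words 5-7 are in column/row/section order; map them to x,y,z.
    axis_pos = [m.header_i32(i) for i in (17, 18, 19)]  # MAPC, MAPR, MAPS
    if sorted(axis_pos) != [1, 2, 3]:
        raise MRCFormatError(f"invalid axis correspondence {axis_pos}")
    nstart = np.zeros(3)
    for stored_axis, crystal_axis in enumerate(axis_pos):
        nstart[crystal_axis - 1] = m.header_i32(5 + stored_axis)
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    data = np.array(m.grid, copy=True).astype(np.float32)
    voxel_size = np.asarray(m.grid.spacing, dtype=np.float64)
    mrc_origin = np.array([m.header_float(i) for i in (50, 51, 52)], dtype=np.float64)
    origin = mrc_origin + nstart * voxel_size
    return DensityMap(data, origin, voxel_size)


def write_mrc(density: DensityMap, path) -> None:
    """Write a map as MRC2014 mode 2 (float32), canonical (x, y, z) axis order."""
    nx, ny, nz = density.shape
    grid = gemmi.FloatGrid(np.ascontiguousarray(density.data, dtype=np.float32))
    grid.unit_cell = gemmi.UnitCell(
        nx * density.voxel_size[0],
        ny * density.voxel_size[1],
        nz * density.voxel_size[2],
        90.0, 90.0, 90.0,
    )
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for word, value in zip((50, 51, 52), density.origin):
        m.set_header_float(word, float(value))
    try:
        m.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write MRC file {path}: {exc}") from None


def resample_to_unit(density: DensityMap) -> DensityMap:
    """Resample a map to 1 Å/voxel by trilinear interpolation.

    The world extent is preserved to within one voxel; positions that fall
    outside the source grid evaluate to 0.  A map already at 1 Å is returned
    unchanged.
    """
    if np.any(density.voxel_size <= 0):
        raise ValueError(f"voxel size must be positive, got {density.voxel_size}")
    if np.allclose(density.voxel_size, 1.0):
        return density
    extent = (np.array(density.shape) - 1) * density.voxel_size
    new_shape = np.maximum(np.floor(extent + 1e-9).astype(int) + 1, 1)
    # new lattice point t (in Å from origin) maps to source index t / voxel_size
    idx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in new_shape], indexing="ij")
    coords = [idx[a] / density.voxel_size[a] for a in range(3)]
    data = ndimage.map_coordinates(
        density.data.astype(np.float64), coords, order=1, mode="constant", cval=0.0
    ).astype(np.float32)
    return DensityMap(data, density.origin.copy(), np.ones(3))


def extract_component(density: DensityMap, atoms, radius: float) -> DensityMap:
    """Mask a map to the envelope of an atomic chain.

    Voxels whose center lies within ``radius`` Å (inclusive) of any atom keep
    their value; all others are zeroed.  The grid is cropped to the tight
    bounding box of retained voxels, with the origin shifted so world
    coordinates are unchanged.
    """
    atoms = np.atleast_2d(np.asarray(atoms, dtype=np.float64))
    if atoms.size == 0:
        raise ValueError("atoms must be non-empty")
    if radius <= 0:
        raise ValueError("radius must be positive")
    shape = density.shape
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    centers = np.stack(
        [density.origin[a] + grids[a] * density.voxel_size[a] for a in range(3)], axis=-1
    )
    tree = cKDTree(atoms)
    dist, _ = tree.query(centers.reshape(-1, 3), k=1)
    mask = (dist <= radius).reshape(shape)
    if not mask.any():
        raise EmptyComponentError(
            f"no voxel center within {radius} Å of any of the {len(atoms)} atoms"
        )
    kept = np.where(mask)
    lo = [int(k.min()) for k in kept]
    hi = [int(k.max()) + 1 for k in kept]
    data = np.where(mask, density.data, 0.0)[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    origin = density.origin + np.array(lo) * density.voxel_size
    return DensityMap(data.astype(np.float32), origin, density.voxel_size.copy())


def normalize(density: DensityMap) -> DensityMap:
    """Min-max scale intensities to [0, 1]; a constant map becomes all-zero."""
    lo = float(density.data.min())
    hi = float(density.data.max())
    if hi == lo:
        data = np.zeros_like(density.data)
    else:
        data = (density.data - lo) / (hi - lo)
    return replace(density.copy(), data=data.astype(np.float32))


def pad_for_network(density: DensityMap, divisor: int = 4) -> tuple[DensityMap, PadSpec]:
    """Zero-pad each dimension up to the next multiple of ``divisor``.

    Padding is split as evenly as possible, the odd voxel going to the
    "after" side.  Raises :class:`SizeLimitError` if a padded dimension would
    exceed 100 voxels.
    """
    if divisor < 1:
        raise ValueError("divisor must be >= 1")
    before, after = [], []
    for n in density.shape:
        target = -(-n // divisor) * divisor
        if target > MAX_DIM:
            raise SizeLimitError(
                f"dimension {n} pads to {target} > {MAX_DIM} voxels; the model "
                f"accepts component maps of at most {MAX_DIM} voxels per dimension"
            )
        extra = target - n
        before.append(extra // 2)
        after.append(extra - extra // 2)
    data = np.pad(density.data, list(zip(before, after)))
    origin = density.origin - np.array(before) * density.voxel_size
    padded = DensityMap(data, origin, density.voxel_size.copy())
    return padded, PadSpec(tuple(before), tuple(after))


def unpad(density: DensityMap, spec: PadSpec) -> DensityMap:
    """Invert :func:`pad_for_network` exactly."""
    sl = tuple(
        slice(b, n - a)
        for b, a, n in zip(spec.pad_before, spec.pad_after, density.shape)
    )
    origin = density.origin + np.array(spec.pad_before) * density.voxel_size
    return DensityMap(density.data[sl].copy(), origin, density.voxel_size.copy())


def unpad_array(arr: np.ndarray, spec: PadSpec) -> np.ndarray:
    """Apply the inverse of a :class:`PadSpec` to a bare array (labels, masks)."""
    sl = tuple(
        slice(b, n - a)
        for b, a, n in zip(spec.pad_before, spec.pad_after, arr.shape[:3])
    )
    return arr[sl]
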