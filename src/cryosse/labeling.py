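"""Ground-truth secondary-structure labels for density voxels.

Residue-level annotations come from STRIDE output (``ASG`` records) joined
with Cα coordinates from the corresponding PDB chain model.  Voxel-level
ground truth marks every voxel whose center lies within 3 Å of the Cα of a
helix (class 1) or β-sheet (class 2) residue; everything else is background
(class 0).  STRIDE letters H, G and I count as helix; B, b and E as β-sheet
(the lowercase ``b`` is matched case-sensitively); all other letters,
including coil and turns, are "other" and label nothing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .volio import DensityMap

logger = logging.getLogger(__name__)

BACKGROUND, HELIX, SHEET = 0, 1, 2
CLASS_NAMES = ("background", "helix", "sheet")

#: labelling / voting neighbourhood radius around a Cα atom, in Å (inclusive)
CA_RADIUS = 3.0

_HELIX_LETTERS = frozenset("HGI")
_SHEET_LETTERS = frozenset(["B", "b", "E"])


@dataclass(frozen=True)
class ResidueAnnotation:
    """One residue's secondary-structure class and Cα position (Å)."""

    chain_id: str
    residue_number: int
    ss_class: str  # 'helix' | 'sheet' | 'other'
    ca_coord: tuple[float, float, float]

    def __post_init__(self):
        if self.ss_class not in ("helix", "sheet", "other"):
            raise ValueError(f"unknown ss_class {self.ss_class!r}")
        if not np.all(np.isfinite(self.ca_coord)):
            raise ValueError("ca_coord must be finite")


class StrideJoinError(ValueError):
    """STRIDE residues that could not be matched to the PDB chain model."""


def ss_class_of_letter(letter: str) -> str:
    """Map a STRIDE one-letter code to 'helix', 'sheet' or 'other'."""
    if letter in _HELIX_LETTERS:
        return "helix"
    if letter in _SHEET_LETTERS:
        return "sheet"
    return "other"


def _ca_coords_from_pdb(pdb_path) -> dict[tuple[str, int], tuple[float, float, float]]:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("chain", str(pdb_path))
    coords: dict[tuple[str, int], tuple[float, float, float]] = {}
    model = next(structure.get_models())
    for chain in model:
        for residue in chain:
            if "CA" in residue:
                key = (chain.id.strip(), residue.id[1])
                coords.setdefault(key, tuple(map(float, residue["CA"].coord)))
    return coords


def parse_stride(stride_path, pdb_path) -> list[ResidueAnnotation]:
    """Parse STRIDE ``ASG`` records and join Cα coordinates from a PDB file.

    Returns one :class:`ResidueAnnotation` per ASG record whose residue has a
    Cα atom in the PDB model.  Residues present in STRIDE but absent from the
    PDB raise :class:`StrideJoinError`; residues found in the PDB but lacking
    a Cα atom are dropped with a logged warning.
    """
    ca_coords = _ca_coords_from_pdb(pdb_path)
    annotations: list[ResidueAnnotation] = []
    missing: list[tuple[str, str]] = []
    with open(stride_path) as fh:
        for line in fh:
            if not line.startswith("ASG"):
                continue
            fields = line.split()
            # ASG resname chain resnum ordinal code fullname phi psi area
            chain_id = fields[2].strip()
            resnum_txt = fields[3]
            code = fields[5]
            try:
                resnum = int(resnum_txt)
            except ValueError:
                # insertion codes like '52A' — strip trailing letters
                resnum = int("".join(ch for ch in resnum_txt if ch in "-0123456789"))
            key = (chain_id, resnum)
            if key not in ca_coords:
                missing.append((chain_id, resnum_txt))
                continue
            annotations.append(
                ResidueAnnotation(chain_id, resnum, ss_class_of_letter(code), ca_coords[key])
            )
    if missing:
        raise StrideJoinError(
            "STRIDE residues absent from the PDB model: "
            + ", ".join(f"{c}/{r}" for c, r in missing)
        )
    return annotations


def label_voxels(density: DensityMap, annotations) -> np.ndarray:
    """Build the ground-truth label grid for a component map.

    A voxel is labelled helix (sheet) iff its center lies within
    :data:`CA_RADIUS` of the Cα of at least one helix (sheet) residue.  A
    voxel within 3 Å of both a helix and a sheet Cα is labelled helix — the
    same priority the residue-level vote uses for ties.  Cα atoms outside the
    grid simply label no voxels.

    Returns an int8 array of the map's shape with values in {0, 1, 2}.
    """
    if not np.allclose(density.voxel_size, 1.0):
        raise ValueError("label_voxels expects a map resampled to 1 Å/voxel")
    labels = np.zeros(density.shape, dtype=np.int8)
    for target_class, value in (("sheet", SHEET), ("helix", HELIX)):
        coords = np.array(
            [a.ca_coord for a in annotations if a.ss_class == target_class], dtype=np.float64
        )
        if coords.size == 0:
            continue
        mask = _sphere_mask(density, coords, CA_RADIUS)
        labels[mask] = value  # helix pass runs last, so helix overrides sheet
    return labels


def _sphere_mask(density: DensityMap, coords: np.ndarray, radius: float) -> np.ndarray:
    """Boolean mask of voxels whose center is within ``radius`` of any point."""
    shape = density.shape
    mask = np.zeros(shape, dtype=bool)
    # restrict the KD-tree query to voxels inside the union of bounding boxes
    idx = (coords - density.origin) / density.voxel_size
    lo = np.maximum(np.floor(idx.min(axis=0) - radius).astype(int), 0)
    hi = np.minimum(np.ceil(idx.max(axis=0) + radius).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return mask
    grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
    centers = np.stack(
        [density.origin[a] + grids[a] * density.voxel_size[a] for a in range(3)], axis=-1
    )
    dist, _ = cKDTree(coords).query(centers.reshape(-1, 3), k=1)
    sub = (dist <= radius).reshape(grids[0].shape)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub
    return mask
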