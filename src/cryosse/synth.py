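"""Synthetic medium-resolution density maps with exact ground truth.

The generator emulates component maps of single protein chains at 5-10 Å
resolution: Cα traces of idealized α-helices (rise 1.5 Å/residue, 100° twist,
2.3 Å radius) and antiparallel β-sheets (3.3 Å Cα spacing along a strand,
4.8 Å between strands) are blurred with an isotropic Gaussian whose FWHM
equals the nominal resolution, sampled on a 1 Å lattice, and perturbed with
seeded Gaussian noise.  Ground-truth voxel labels are generated by the same
3 Å Cα-sphere rule used for experimental data, so labels and annotations are
exactly consistent by construction.

Three quality levels stand in for the cylindrical-fit bins of real data:
level 1 is the sharpest and cleanest (5 Å, 5% noise), level 3 the blurriest
and noisiest (10 Å, 20% noise).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .labeling import ResidueAnnotation, label_voxels
from .volio import DensityMap, write_mrc

# idealized α-helix Cα geometry (Å, degrees)
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.3
# idealized antiparallel β-sheet Cα geometry (Å)
STRAND_RISE = 3.3
STRAND_SPACING = 4.8

#: quality level -> (nominal resolution Å, noise sd as a fraction of peak)
QUALITY_LEVELS = {1: (5.0, 0.05), 2: (7.5, 0.12), 3: (10.0, 0.20)}

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SyntheticCase:
    case_id: str
    map: DensityMap
    labels: np.ndarray
    annotations: list[ResidueAnnotation]
    bin: int
    seed: int


def make_helix(n_res: int, origin=(0.0, 0.0, 0.0), orientation=None,
               chain_id: str = "A", start_residue: int = 1):
    """Cα trace and annotations of an ideal α-helix along the (rotated) z axis."""
    if n_res < 4:
        raise ValueError("a helix needs at least 4 residues")
    i = np.arange(n_res)
    theta = np.deg2rad(HELIX_TWIST_DEG) * i
    coords = np.stack([
        HELIX_RADIUS * np.cos(theta),
        HELIX_RADIUS * np.sin(theta),
        HELIX_RISE * i,
    ], axis=1)
    coords = _transform(coords, origin, orientation)
    annotations = [
        ResidueAnnotation(chain_id, start_residue + int(k), "helix", tuple(coords[k]))
        for k in range(n_res)
    ]
    return coords, annotations


def make_sheet(n_strands: int, strand_len: int, origin=(0.0, 0.0, 0.0),
               orientation=None, chain_id: str = "A", start_residue: int = 1):
    """Cα trace and annotations of an idealized antiparallel β-sheet.

    Strands run along x with 3.3 Å Cα spacing, neighbours 4.8 Å apart along y
    and alternating in direction.
    """
    if n_strands < 2 or strand_len < 3:
        raise ValueError("a sheet needs >= 2 strands of >= 3 residues")
    rows = []
    for s in range(n_strands):
        x = STRAND_RISE * np.arange(strand_len, dtype=np.float64)
        if s % 2 == 1:
            x = x[::-1]  # antiparallel neighbour
        rows.append(np.stack([x, np.full(strand_len, STRAND_SPACING * s),
                              np.zeros(strand_len)], axis=1))
    coords = np.concatenate(rows, axis=0)
    coords = _transform(coords, origin, orientation)
    annotations = [
        ResidueAnnotation(chain_id, start_residue + int(k), "sheet", tuple(coords[k]))
        for k in range(len(coords))
    ]
    return coords, annotations


def _transform(coords, origin, orientation):
    if orientation is not None:
        R = np.asarray(orientation, dtype=np.float64)
        if R.shape != (3, 3):
            raise ValueError("orientation must be a 3x3 rotation matrix")
        coords = coords @ R.T
    return coords + np.asarray(origin, dtype=np.float64)


def simulate_density(coords, resolution: float, grid_padding: float = 4.0,
                     noise_sd: float = 0.0, seed: int = 0) -> DensityMap:
    """Gaussian-kernel density of a point set on a 1 Å lattice.

    Each coordinate contributes an isotropic Gaussian with
    ``sigma = resolution / (2 sqrt(2 ln 2))`` (FWHM = nominal resolution).
    Seeded Gaussian noise with standard deviation ``noise_sd × peak`` is
    added on top.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    if coords.size == 0:
        raise ValueError("coords must be non-empty")
    if not 4.0 <= resolution <= 12.0:
        raise ValueError("resolution must be between 4 and 12 Å")
    sigma = resolution * FWHM_TO_SIGMA
    lo = np.floor(coords.min(axis=0) - grid_padding)
    hi = np.ceil(coords.max(axis=0) + grid_padding)
    shape = (hi - lo).astype(int) + 1
    data = np.zeros(shape, dtype=np.float64)
    cutoff = 5.0 * sigma
    for atom in coords:
        rel = atom - lo
        a = np.maximum(np.ceil(rel - cutoff).astype(int), 0)
        b = np.minimum(np.floor(rel + cutoff).astype(int) + 1, shape)
        if np.any(a >= b):
            continue
        axes = [np.arange(a[d], b[d]) - rel[d] for d in range(3)]
        g = [np.exp(-0.5 * (ax / sigma) ** 2) for ax in axes]
        data[a[0]:b[0], a[1]:b[1], a[2]:b[2]] += (
            g[0][:, None, None] * g[1][None, :, None] * g[2][None, None, :]
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd * data.max(), size=data.shape)
    return DensityMap(data.astype(np.float32), origin=lo, voxel_size=np.ones(3))


def make_dataset(n_cases: int, mix=(0.4, 0.3, 0.3), quality_levels=(1, 2, 3),
                 seed: int = 0) -> list[SyntheticCase]:
    """Generate a seeded collection of synthetic component-map cases.

    ``mix`` gives the proportions of helix-only, sheet-only, and mixed cases;
    quality levels are cycled so the bins are (near-)balanced.  Labels are
    produced with :func:`cryosse.labeling.label_voxels`, so every case's
    ground truth is exactly the 3 Å-sphere labelling of its annotations.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    mix = np.asarray(mix, dtype=np.float64)
    mix = mix / mix.sum()
    children = np.random.SeedSequence(seed).spawn(n_cases)
    cases = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        kind = ["helix", "sheet", "mixed"][int(rng.choice(3, p=mix))]
        level = quality_levels[i % len(quality_levels)]
        resolution, noise_sd = QUALITY_LEVELS[level]
        coords, annotations = _random_geometry(kind, rng)
        case_seed = int(rng.integers(0, 2 ** 31 - 1))
        density = simulate_density(coords, resolution, grid_padding=4.0,
                                   noise_sd=noise_sd, seed=case_seed)
        labels = label_voxels(density, annotations)
        cases.append(SyntheticCase(
            case_id=f"syn{i:03d}_{kind}_q{level}", map=density, labels=labels,
            annotations=annotations, bin=level, seed=case_seed,
        ))
    return cases


def _random_geometry(kind: str, rng):
    rot = Rotation.random(random_state=rng).as_matrix()
    if kind == "helix":
        n_res = int(rng.integers(10, 19))
        return make_helix(n_res, orientation=rot)
    if kind == "sheet":
        n_strands = int(rng.integers(3, 5))
        strand_len = int(rng.integers(5, 8))
        return make_sheet(n_strands, strand_len, orientation=rot)
    # mixed: a helix and a small sheet, well separated
    n_res = int(rng.integers(8, 14))
    h_coords, h_ann = make_helix(n_res, orientation=rot)
    rot2 = Rotation.random(random_state=rng).as_matrix()
    offset_dir = rng.normal(size=3)
    offset = 15.0 * offset_dir / np.linalg.norm(offset_dir)
    s_coords, s_ann = make_sheet(3, int(rng.integers(4, 7)), origin=offset,
                                 orientation=rot2, start_residue=n_res + 10)
    return np.concatenate([h_coords, s_coords]), h_ann + s_ann


def write_case(case: SyntheticCase, out_dir) -> dict[str, Path]:
    """Write a case as standard files: MRC map, Cα-trace PDB, STRIDE-style
    annotation file, and a labels MRC (synthetic stand-ins for curated
    experimental inputs)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "map": out_dir / f"{case.case_id}.mrc",
        "labels": out_dir / f"{case.case_id}_labels.mrc",
        "pdb": out_dir / f"{case.case_id}.pdb",
        "stride": out_dir / f"{case.case_id}.stride",
    }
    write_mrc(case.map, paths["map"])
    write_mrc(DensityMap(case.labels.astype(np.float32), case.map.origin.copy(),
                         case.map.voxel_size.copy()), paths["labels"])
    _write_ca_pdb(case.annotations, paths["pdb"])
    _write_stride(case.annotations, paths["stride"])
    return paths


def _write_ca_pdb(annotations, path) -> None:
    from Bio.PDB import PDBIO, StructureBuilder

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("synthetic")
    builder.init_model(0)
    current_chain = None
    for serial, a in enumerate(annotations, start=1):
        if a.chain_id != current_chain:
            builder.init_chain(a.chain_id)
            builder.init_seg("    ")
            current_chain = a.chain_id
        builder.init_residue("ALA", " ", a.residue_number, " ")
        builder.init_atom("CA", np.asarray(a.ca_coord, dtype=np.float32),
                          0.0, 1.0, " ", " CA ", serial, "C")
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


_STRIDE_CODE = {"helix": ("H", "AlphaHelix"), "sheet": ("E", "Strand"),
                "other": ("C", "Coil")}


def _write_stride(annotations, path) -> None:
    """STRIDE-style ASG records for synthetic annotations."""
    with open(path, "w") as fh:
        fh.write("REM  Synthetic secondary-structure assignment (STRIDE-format ASG records)\n")
        for ordinal, a in enumerate(annotations, start=1):
            code, name = _STRIDE_CODE[a.ss_class]
            fh.write(
                f"ASG  ALA {a.chain_id} {a.residue_number:4d} {ordinal:4d}    "
                f"{code}   {name:<13s} {0.0:9.2f} {0.0:9.2f} {0.0:9.1f}\n"
            )
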