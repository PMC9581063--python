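"""End-to-end prediction: one MRC map in, helix and sheet MRC masks out.

``detect`` runs the full runtime pipeline — read, resample to 1 Å, min-max
normalise, pad to multiples of 4, forward pass, per-voxel argmax, unpad — and
writes two binary masks (``<stem>_helix.mrc`` and ``<stem>_sheet.mrc``) that
carry the input map's origin and voxel size so they overlay it in a viewer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import volio
from .labeling import BACKGROUND, HELIX, SHEET
from .nn.unet import UNet3D, load_checkpoint


@dataclass
class SegmentationResult:
    """Argmax labels plus disjoint binary masks on the original input lattice."""

    label_grid: np.ndarray
    helix_mask: np.ndarray
    sheet_mask: np.ndarray
    helix_path: Path | None = None
    sheet_path: Path | None = None


def argmax_labels(probs: np.ndarray) -> np.ndarray:
    """Per-voxel class of maximal probability from a (D, H, W, 3) grid.

    Exact ties are resolved helix > sheet > background, mirroring the
    priority used by the residue-level vote.
    """
    probs = np.asarray(probs)
    if probs.ndim != 4 or probs.shape[3] != 3:
        raise ValueError(f"expected a (x, y, z, 3) probability grid, got {probs.shape}")
    # reorder classes to (helix, sheet, background) so argmax's first-wins
    # tie rule implements the helix > sheet > background priority
    reordered = probs[..., [HELIX, SHEET, BACKGROUND]]
    best = reordered.argmax(axis=3)
    return np.array([HELIX, SHEET, BACKGROUND], dtype=np.int8)[best]


def segment_density(density: volio.DensityMap, model: UNet3D) -> SegmentationResult:
    """Segment an in-memory map (resample → normalise → pad → forward → unpad)."""
    unit = volio.resample_to_unit(density)
    for n in unit.shape:
        if n > volio.MAX_DIM:
            raise volio.SizeLimitError(
                f"component map has {n} voxels along one dimension after "
                f"resampling; the model accepts at most {volio.MAX_DIM}"
            )
    padded, spec = volio.pad_for_network(volio.normalize(unit), divisor=4)
    probs = model.predict_proba(padded.data)
    labels = volio.unpad_array(argmax_labels(probs), spec)
    return SegmentationResult(
        label_grid=labels,
        helix_mask=(labels == HELIX).astype(np.float32),
        sheet_mask=(labels == SHEET).astype(np.float32),
    )


def detect(map_path, checkpoint_path, out_dir) -> SegmentationResult:
    """Run the full pipeline on an MRC file and write the two mask volumes."""
    checkpoint_path = Path(checkpoint_path)
    if not checkpoint_path.exists():
        raise FileNotFoundError(f"model checkpoint not found: {checkpoint_path}")
    model = load_checkpoint(checkpoint_path)
    density = volio.read_mrc(map_path)
    unit = volio.resample_to_unit(density)
    result = segment_density(unit, model)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = Path(map_path).stem
    result.helix_path = out_dir / f"{stem}_helix.mrc"
    result.sheet_path = out_dir / f"{stem}_sheet.mrc"
    for mask, path in ((result.helix_mask, result.helix_path),
                       (result.sheet_mask, result.sheet_path)):
        volio.write_mrc(
            volio.DensityMap(mask, unit.origin.copy(), unit.voxel_size.copy()), path
        )
    return result
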