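"""Voxel- and residue-level F1 evaluation of secondary-structure detection.

Per class (helix, β-sheet), F1 = 2PR/(P+R) is computed one-vs-rest at two
levels: over voxel labels, and over residue labels obtained by majority
voting among the predicted voxels within 3 Å of each residue's Cα (ties go
helix, then sheet, then other).  A score is NA — not zero — exactly when the
class is absent from both the truth and the prediction, leaving precision or
recall undefined; when predictions for an existing class are simply absent
the score is 0.  Across cases, each defined F1 is averaged weighted by the
case's residue count of that class.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labeling import BACKGROUND, CA_RADIUS, HELIX, SHEET
from .volio import DensityMap

logger = logging.getLogger(__name__)

_CLASS_BY_NAME = {"other": BACKGROUND, "background": BACKGROUND,
                  "helix": HELIX, "sheet": SHEET}


@dataclass
class CaseEvaluation:
    """Per-case F1 scores; ``None`` encodes NA."""

    case_id: str
    n_helix: int
    n_sheet: int
    n_total: int
    f1_voxel_helix: float | None
    f1_voxel_sheet: float | None
    f1_residue_helix: float | None
    f1_residue_sheet: float | None


@dataclass
class EvalReport:
    cases: list[CaseEvaluation] = field(default_factory=list)

    _METRICS = ("f1_voxel_helix", "f1_voxel_sheet", "f1_residue_helix", "f1_residue_sheet")

    def weighted_averages(self) -> dict[str, float | None]:
        out: dict[str, float | None] = {}
        for metric in self._METRICS:
            cls = "helix" if metric.endswith("helix") else "sheet"
            try:
                out[metric] = weighted_average(self.cases, metric, cls)
            except ValueError:
                out[metric] = None
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cases:
            rows.append({
                "case_id": c.case_id, "n_helix": c.n_helix, "n_sheet": c.n_sheet,
                "n_total": c.n_total,
                **{m: ("NA" if getattr(c, m) is None else round(getattr(c, m), 4))
                   for m in self._METRICS},
            })
        return pd.DataFrame(rows)

    def write(self, json_path=None, csv_path=None) -> dict:
        payload = {
            "cases": json.loads(self.to_frame().to_json(orient="records")),
            "weighted_averages": {
                k: (None if v is None else round(v, 4))
                for k, v in self.weighted_averages().items()
            },
        }
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(payload, fh, indent=2)
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index=False)
        return payload


def f1_class(pred_labels, true_labels, ss_class) -> float | None:
    """One-vs-rest F1 for a class; ``None`` (NA) when the class is absent
    from both truth and prediction."""
    pred = np.asarray(pred_labels).ravel()
    true = np.asarray(true_labels).ravel()
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    cls = _CLASS_BY_NAME[ss_class] if isinstance(ss_class, str) else int(ss_class)
    p = pred == cls
    t = true == cls
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    if tp + fp == 0 and tp + fn == 0:
        return None  # class absent everywhere: precision and recall undefined
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def vote_residue(label_grid: np.ndarray, ca_coord, origin=(0.0, 0.0, 0.0)) -> int:
    """Majority vote among predicted voxel labels within 3 Å of a Cα atom.

    The grid must be at 1 Å/voxel; ``origin`` is the world coordinate of
    voxel (0,0,0).  Ties are resolved helix, then sheet, then other.  A Cα
    with no grid voxel within 3 Å votes "other" with a warning.
    """
    grid = np.asarray(label_grid)
    ca = np.asarray(ca_coord, dtype=np.float64) - np.asarray(origin, dtype=np.float64)
    lo = np.maximum(np.ceil(ca - CA_RADIUS).astype(int), 0)
    hi = np.minimum(np.floor(ca + CA_RADIUS).astype(int) + 1, grid.shape)
    counts = np.zeros(3, dtype=np.int64)
    if np.all(lo < hi):
        ii, jj, kk = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
        d2 = (ii - ca[0]) ** 2 + (jj - ca[1]) ** 2 + (kk - ca[2]) ** 2
        sel = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][d2 <= CA_RADIUS ** 2]
        counts = np.bincount(sel.ravel().astype(np.int64), minlength=3)[:3]
    if counts.sum() == 0:
        logger.warning("Cα at %s has no grid voxel within %.1f Å; voting 'other'",
                       tuple(np.round(ca_coord, 2)), CA_RADIUS)
        return BACKGROUND
    # priority on ties: helix, then sheet, then background
    best = max((HELIX, SHEET, BACKGROUND), key=lambda c: (counts[c], c != BACKGROUND, c == HELIX))
    return int(best)


def evaluate_case(pred: np.ndarray, truth_grid: np.ndarray, annotations,
                  case_id: str = "case", origin=(0.0, 0.0, 0.0)) -> CaseEvaluation:
    """Voxel F1s from the two label grids; residue F1s from per-residue votes."""
    pred = np.asarray(pred)
    truth_grid = np.asarray(truth_grid)
    if pred.shape != truth_grid.shape:
        raise ValueError(f"lattice mismatch: {pred.shape} vs {truth_grid.shape}")
    true_res = np.array([_CLASS_BY_NAME[a.ss_class] for a in annotations])
    pred_res = np.array([vote_residue(pred, a.ca_coord, origin) for a in annotations])
    return CaseEvaluation(
        case_id=case_id,
        n_helix=int(np.count_nonzero(true_res == HELIX)),
        n_sheet=int(np.count_nonzero(true_res == SHEET)),
        n_total=len(annotations),
        f1_voxel_helix=f1_class(pred, truth_grid, HELIX),
        f1_voxel_sheet=f1_class(pred, truth_grid, SHEET),
        f1_residue_helix=f1_class(pred_res, true_res, HELIX) if len(annotations) else None,
        f1_residue_sheet=f1_class(pred_res, true_res, SHEET) if len(annotations) else None,
    )


def weighted_average(cases, metric: str, ss_class: str) -> float:
    """Average a metric over cases, weighted by each case's residue count of
    the class; NA cases are excluded (their weight is zero)."""
    count_attr = f"n_{ss_class}"
    total, weight = 0.0, 0
    for case in cases:
        f1 = getattr(case, metric)
        if f1 is None:
            continue
        n = getattr(case, count_attr)
        total += n * f1
        weight += n
    if weight == 0:
        raise ValueError(f"no case with class '{ss_class}' present for metric {metric}")
    return total / weight
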