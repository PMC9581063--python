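"""Dataset curation: chain de-duplication, fit-quality binning, test screening.

Training/test sets of component maps are curated in three steps:

* near-identical chains of the same protein (global-alignment identity above
  70%) are removed greedily in input order;
* each retained chain is scored by how well an ideal helical cylinder fits
  its helices (per-helix F1 of the fitted ideal helix's 3 Å tube against the
  helix-labelled voxels, averaged over helices), and chains are split into
  three quality bins by tertiles of that score;
* test candidates are screened against the training set: unknown-sequence
  candidates are dropped, candidates above 35% identity to any training chain
  are dropped, and candidates must differ structurally (at least one of the
  two length-normalised TM-scores below 0.5) from every unknown-sequence
  training chain.

The Needleman-Wunsch scoring scheme is match +1, mismatch 0, gap −1; identity
is identical aligned pairs over alignment length.  Among score-optimal
alignments the one with the most identities (then the shortest) defines the
identity, which makes the reported percentage deterministic.  ``X``/unknown
residues never count as identical.  TM-align itself is an external tool; only
its text output is parsed here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .labeling import HELIX

logger = logging.getLogger(__name__)

MATCH_SCORE, MISMATCH_SCORE, GAP_SCORE = 1, 0, -1
DEDUP_IDENTITY_MAX = 70.0   # % identity above which same-protein chains are duplicates
TEST_IDENTITY_MAX = 35.0    # % identity above which a candidate matches training data
TM_SCORE_MAX = 0.5          # at least one normalisation must fall below this
TUBE_RADIUS = 3.0          # Å, fitted-helix tube radius (the labelling radius)
MIN_HELIX_RESIDUES = 4


@dataclass(frozen=True)
class AlignmentScore:
    identity: float      # percent, 0..100
    length: int          # alignment length incl. gaps

    def __post_init__(self):
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be a percentage in [0, 100]")


@dataclass
class ChainQuality:
    per_helix_f1: list[float]
    chain_score: float
    bin: int | None = None


@dataclass(frozen=True)
class Chain:
    chain_id: str
    sequence: str | None  # None for chains with unknown sequence (UNK residues)


def nw_identity(seq_a: str, seq_b: str) -> AlignmentScore:
    """Percent identity from an optimal Needleman-Wunsch global alignment."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a, b = seq_a.upper(), seq_b.upper()
    n, m = len(a), len(b)
    # DP over (score, identities, -length), maximised lexicographically;
    # all three objectives are additive per alignment column.
    NEG = (-10 ** 9, 0, 0)
    prev = [(j * GAP_SCORE, 0, -j) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [NEG] * (m + 1)
        cur[0] = (i * GAP_SCORE, 0, -i)
        ai = a[i - 1]
        for j in range(1, m + 1):
            ident = 1 if (ai == b[j - 1] and ai != "X") else 0
            sub = MATCH_SCORE if ident else MISMATCH_SCORE
            pd = prev[j - 1]
            pu = prev[j]
            pl = cur[j - 1]
            cur[j] = max(
                (pd[0] + sub, pd[1] + ident, pd[2] - 1),
                (pu[0] + GAP_SCORE, pu[1], pu[2] - 1),
                (pl[0] + GAP_SCORE, pl[1], pl[2] - 1),
            )
        prev = cur
    _, identities, neg_len = prev[m]
    length = -neg_len
    return AlignmentScore(identity=100.0 * identities / length, length=length)


def dedup_chains(chains) -> list:
    """Greedy removal of near-identical chains of the same protein.

    ``chains`` is an ordered collection of objects with ``sequence``
    attributes (or (id, sequence) tuples).  A chain is dropped iff its
    identity with an already-retained chain exceeds 70%.
    """
    retained = []
    for chain in chains:
        seq = chain.sequence if hasattr(chain, "sequence") else chain[1]
        duplicate = False
        for kept in retained:
            kept_seq = kept.sequence if hasattr(kept, "sequence") else kept[1]
            if seq and kept_seq and nw_identity(seq, kept_seq).identity > DEDUP_IDENTITY_MAX:
                duplicate = True
                break
        if not duplicate:
            retained.append(chain)
    return retained


def _helix_segments(annotations):
    """Group helix residues into runs of consecutive residue numbers."""
    helix = sorted(
        (a for a in annotations if a.ss_class == "helix"),
        key=lambda a: (a.chain_id, a.residue_number),
    )
    segments, current = [], []
    for a in helix:
        if current and (a.chain_id != current[-1].chain_id
                        or a.residue_number != current[-1].residue_number + 1):
            segments.append(current)
            current = []
        current.append(a)
    if current:
        segments.append(current)
    return [s for s in segments if len(s) >= MIN_HELIX_RESIDUES]


def cylindrical_fit(label_grid: np.ndarray, annotations,
                    origin=(0.0, 0.0, 0.0)) -> ChainQuality | None:
    """Score how well an ideal helical cylinder fits each helix of a chain.

    For each helix (a run of >= 4 consecutive helix residues) an idealized
    helix is fitted to the Cα trace: the cylinder axis is the least-squares
    line through the trace, the cylinder radius the mean radial distance of
    the Cαs from that axis, and each Cα is snapped onto the cylinder surface
    at its own axial position and azimuth.  The fit-predicted helix voxels
    are those within 3 Å (the labelling radius) of the densely sampled fitted
    curve, scored by F1 against the helix-labelled voxels in the helix's own
    3 Å Cα neighbourhood — an ideal helix therefore scores near 1, and the
    score decays as the trace departs from ideal cylindrical geometry.  The
    chain score is the mean per-helix F1.  Returns None (with a warning) for
    chains without an eligible helix.
    """
    from scipy.spatial import cKDTree

    from .labeling import CA_RADIUS

    grid = np.asarray(label_grid)
    origin = np.asarray(origin, dtype=np.float64)
    segments = _helix_segments(annotations)
    if not segments:
        logger.warning("chain has no helix of >= %d residues; fit quality undefined",
                       MIN_HELIX_RESIDUES)
        return None
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in grid.shape], indexing="ij"), axis=-1)
    centers = (idx + origin).reshape(-1, 3)  # 1 Å lattice voxel centers
    scores = []
    for seg in segments:
        coords = np.array([a.ca_coord for a in seg], dtype=np.float64)
        centroid = coords.mean(axis=0)
        _, _, vt = np.linalg.svd(coords - centroid)
        axis = vt[0]
        t = (coords - centroid) @ axis
        radial = coords - centroid - t[:, None] * axis
        radial_norm = np.linalg.norm(radial, axis=1)
        r_mean = radial_norm.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(radial_norm[:, None] > 1e-9,
                            radial / np.maximum(radial_norm, 1e-9)[:, None], 0.0)
        ideal = centroid + t[:, None] * axis + r_mean * unit
        # densely sample the fitted curve so the 3 Å tube has no gaps
        steps = np.linspace(0.0, 1.0, 8, endpoint=False)
        between = (ideal[:-1, None, :]
                   + steps[None, :, None] * np.diff(ideal, axis=0)[:, None, :])
        curve = np.vstack([between.reshape(-1, 3), ideal[-1:]])
        d_curve, _ = cKDTree(curve).query(centers, k=1)
        inside = d_curve <= CA_RADIUS
        d_ca, _ = cKDTree(coords).query(centers, k=1)
        truth = (grid.reshape(-1) == HELIX) & (d_ca <= CA_RADIUS)
        tp = np.count_nonzero(inside & truth)
        fp = np.count_nonzero(inside & ~truth)
        fn = np.count_nonzero(~inside & truth)
        scores.append(0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn))
    return ChainQuality(per_helix_f1=scores, chain_score=float(np.mean(scores)))


def assign_bins(chain_scores) -> list[int]:
    """Tertile split: top third of scores → Bin 1, middle → 2, bottom → 3.

    Ties go upward (a score equal to a cutoff lands in the better bin), so a
    degenerate all-equal collection is entirely Bin 1.
    """
    scores = np.asarray(list(chain_scores), dtype=np.float64)
    if scores.size == 0:
        raise ValueError("no chain scores to bin")
    n = scores.size
    s_sorted = np.sort(scores)[::-1]
    q1 = s_sorted[int(np.ceil(n / 3)) - 1]
    q2 = s_sorted[int(np.ceil(2 * n / 3)) - 1]
    return [1 if s >= q1 else 2 if s >= q2 else 3 for s in scores]


def parse_tmalign(text: str) -> tuple[float, float]:
    """Extract the two length-normalised TM-scores from TM-align output."""
    scores = [float(m) for m in re.findall(r"TM-score\s*=\s*([0-9.]+)", text)]
    if len(scores) < 2:
        raise ValueError("TM-align output does not contain two TM-score lines")
    return scores[0], scores[1]


def screen_test_set(candidates, training_set, tm_scores: dict) -> list:
    """Filter test candidates against the training set.

    Rules, applied in order per candidate:

    * unknown-sequence candidates (``sequence is None``) are dropped;
    * a candidate above 35% identity with any known-sequence training chain
      is dropped;
    * against every unknown-sequence training chain, at least one of the two
      TM-scores (``tm_scores[(candidate_id, training_id)]``, a pair) must be
      below 0.5, else the candidate is dropped.

    A missing TM-score pair for a required comparison raises ValueError
    listing the offending pairs.
    """
    unknown_train = [t for t in training_set if t.sequence is None]
    known_train = [t for t in training_set if t.sequence is not None]
    missing = [
        (c.chain_id, t.chain_id)
        for c in candidates if c.sequence is not None
        for t in unknown_train if (c.chain_id, t.chain_id) not in tm_scores
    ]
    if missing:
        raise ValueError(f"missing TM-score pairs for comparisons: {missing}")
    kept = []
    for cand in candidates:
        if cand.sequence is None:
            continue
        if any(nw_identity(cand.sequence, t.sequence).identity > TEST_IDENTITY_MAX
               for t in known_train):
            continue
        if any(min(tm_scores[(cand.chain_id, t.chain_id)]) >= TM_SCORE_MAX
               for t in unknown_train):
            continue
        kept.append(cand)
    return kept
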