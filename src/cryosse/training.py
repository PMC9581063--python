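"""Training: combined loss, class weighting, GEM, and the 3-phase curriculum.

The loss is a convex mixture of inverse-frequency-weighted cross-entropy and
soft dice loss over the three voxel classes.  Training proceeds through three
curriculum phases over data-quality bins — phase 1 uses Bin 1 (best fit),
phase 2 Bins 1-2, phase 3 all bins — and, in phases 2 and 3, a variant of
gradient episodic memory (GEM): at every optimisation step the gradient on a
small episodic memory (five examples drawn from earlier-phase bins, pooled
into one aggregate memory gradient) is computed, and the current gradient is
projected so it cannot point against it.  The projection is the closed-form
minimal-norm correction for a single constraint:

    g' = g - (g.m / ||m||^2) m      when g.m < 0, else g' = g.

Optimisation uses Adam with a step learning-rate decay (×0.1 every
``weight_decay_step`` epochs).  A batch is one component map, since map sizes
vary from case to case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn.layers import softmax_channels
from .nn.unet import UNet3D

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassWeights:
    """Per-class cross-entropy weights, proportional to inverse frequency."""

    w_background: float
    w_helix: float
    w_sheet: float

    def __post_init__(self):
        arr = self.as_array()
        if np.any(arr <= 0):
            raise ValueError("class weights must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_background, self.w_helix, self.w_sheet], dtype=np.float64)


@dataclass(frozen=True)
class CurriculumPhase:
    phase_index: int
    bins_included: tuple[int, ...]

    def __post_init__(self):
        expected = {1: (1,), 2: (1, 2), 3: (1, 2, 3)}
        if expected.get(self.phase_index) != tuple(self.bins_included):
            raise ValueError(
                f"phase {self.phase_index} must include bins {expected.get(self.phase_index)}"
            )


PHASES = (
    CurriculumPhase(1, (1,)),
    CurriculumPhase(2, (1, 2)),
    CurriculumPhase(3, (1, 2, 3)),
)


@dataclass
class TrainConfig:
    """Hyper-parameters of the curriculum training run."""

    learning_rate: float = 1e-3
    weight_decay_step: int = 1000  # epochs between ×0.1 learning-rate decays
    dropout_rate: float = 0.1
    epochs_per_phase: tuple[int, int, int] = (3, 3, 3)
    memory_size: int = 5
    dice_weight: float = 0.5
    batch_size: int = 1  # maps whose gradients are averaged per Adam step
    augment_rotations: bool = False  # random right-angle rotations per step
    select_best: bool = False  # restore the best-validation-F1 weights at the end
    seed: int = 0
    patience: int | None = None  # early stopping per phase on validation loss

    def __post_init__(self):
        if self.memory_size < 0:
            raise ValueError("memory_size must be >= 0")
        if not 0.0 <= self.dice_weight <= 1.0:
            raise ValueError("dice_weight must be in [0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if len(self.epochs_per_phase) != 3 or min(self.epochs_per_phase) < 0:
            raise ValueError("epochs_per_phase must be three non-negative integers")


# --------------------------------------------------------------------------
# loss
# --------------------------------------------------------------------------

def compute_class_weights(label_grids) -> ClassWeights:
    """Inverse-frequency class weights over a collection of label grids.

    ``w_c ∝ 1 / freq_c``, normalised to sum to 1.  Every class must occur at
    least once in the collection.
    """
    counts = np.zeros(3, dtype=np.int64)
    for grid in label_grids:
        counts += np.bincount(np.asarray(grid).ravel().astype(np.int64), minlength=3)[:3]
    for c, name in enumerate(("background", "helix", "sheet")):
        if counts[c] == 0:
            raise ValueError(f"class '{name}' has zero voxels in the training subset")
    inv = counts.sum() / counts
    inv = inv / inv.sum()
    return ClassWeights(*inv)


def _soft_dice_terms(probs4: np.ndarray, onehot: np.ndarray):
    """Per-class soft-dice loss and its gradient wrt probabilities.

    ``probs4``/``onehot``: (3, N).  A class whose denominator (sum of
    probabilities + sum of truths) is zero contributes zero loss.
    """
    p_sum = probs4.sum(axis=1)
    t_sum = onehot.sum(axis=1)
    inter = (probs4 * onehot).sum(axis=1)
    denom = p_sum + t_sum
    losses = np.zeros(3)
    grad = np.zeros_like(probs4)
    for c in range(3):
        if denom[c] <= 0:
            continue
        losses[c] = 1.0 - 2.0 * inter[c] / denom[c]
        # d(1 - 2I/D)/dp_i = -(2 t_i D - 2 I)/D^2
        grad[c] = -(2.0 * onehot[c] * denom[c] - 2.0 * inter[c]) / denom[c] ** 2
    return losses.mean(), grad / 3.0


def combined_loss(probs: np.ndarray, truth: np.ndarray, weights: ClassWeights,
                  dice_weight: float) -> float:
    """(1 − dice_weight)·weighted-CE + dice_weight·soft-dice on a (D,H,W,3) grid.

    The cross-entropy is the weighted mean of ``−log p_true`` with the weight
    of each voxel's true class, normalised by the total weight, so that equal
    weights reduce to the plain mean cross-entropy.
    """
    probs = np.asarray(probs, dtype=np.float64)
    truth = np.asarray(truth)
    if probs.shape[:3] != truth.shape or probs.shape[3] != 3:
        raise ValueError(f"lattice mismatch: probs {probs.shape} vs truth {truth.shape}")
    w = weights.as_array()
    flat_t = truth.ravel().astype(np.int64)
    flat_p = probs.reshape(-1, 3)
    p_true = np.clip(flat_p[np.arange(flat_t.size), flat_t], 1e-12, None)
    w_vox = w[flat_t]
    ce = float((w_vox * -np.log(p_true)).sum() / w_vox.sum())
    onehot = np.zeros((3, flat_t.size))
    onehot[flat_t, np.arange(flat_t.size)] = 1.0
    dice, _ = _soft_dice_terms(flat_p.T, onehot)
    return (1.0 - dice_weight) * ce + dice_weight * float(dice)


def loss_and_logit_grad(logits: np.ndarray, truth: np.ndarray, weights: ClassWeights,
                        dice_weight: float):
    """Loss value and its gradient with respect to (3, D, H, W) logits."""
    shape = logits.shape[1:]
    flat_t = np.asarray(truth).ravel().astype(np.int64)
    probs = softmax_channels(logits).reshape(3, -1).astype(np.float64)  # (3, N)
    n = flat_t.size
    onehot = np.zeros((3, n))
    onehot[flat_t, np.arange(n)] = 1.0
    w = weights.as_array()
    w_vox = w[flat_t]
    w_norm = w_vox.sum()
    p_true = np.clip(probs[flat_t, np.arange(n)], 1e-12, None)
    ce = (w_vox * -np.log(p_true)).sum() / w_norm
    dce_dlogits = (probs - onehot) * (w_vox / w_norm)
    dice, ddice_dp = _soft_dice_terms(probs, onehot)
    # chain through softmax: dz_c = p_c (g_c - sum_k g_k p_k)
    gp = (ddice_dp * probs).sum(axis=0, keepdims=True)
    ddice_dlogits = probs * (ddice_dp - gp)
    loss = (1.0 - dice_weight) * ce + dice_weight * dice
    dlogits = ((1.0 - dice_weight) * dce_dlogits + dice_weight * ddice_dlogits)
    return float(loss), dlogits.astype(np.float32).reshape((3,) + shape)


# --------------------------------------------------------------------------
# GEM
# --------------------------------------------------------------------------

def gem_project(grad: np.ndarray, mem_grad: np.ndarray) -> np.ndarray:
    """Project a gradient so it does not oppose the episodic-memory gradient.

    Returns ``grad`` unchanged when ``grad·mem_grad >= 0``; otherwise the
    minimal-norm correction ``grad − (grad·mem_grad/‖mem_grad‖²)·mem_grad``,
    which zeroes the dot product.
    """
    grad = np.asarray(grad, dtype=np.float64)
    mem_grad = np.asarray(mem_grad, dtype=np.float64)
    if grad.shape != mem_grad.shape:
        raise ValueError("gradient vectors must have identical length")
    mm = float(mem_grad @ mem_grad)
    if mm == 0.0:
        raise ValueError("memory gradient is all-zero")
    gm = float(grad @ mem_grad)
    if gm >= 0.0:
        return grad
    return grad - (gm / mm) * mem_grad


def sample_episodic_memory(previous_phase_examples, memory_size: int, rng) -> list:
    """Uniform sample without replacement of up to ``memory_size`` examples."""
    examples = list(previous_phase_examples)
    if len(examples) <= memory_size:
        return examples
    idx = rng.choice(len(examples), size=memory_size, replace=False)
    return [examples[i] for i in sorted(idx)]


# --------------------------------------------------------------------------
# optimiser
# --------------------------------------------------------------------------

class Adam:
    """Adam over a model's parameter dictionaries."""

    def __init__(self, model: UNet3D, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(arr) for _, _, arr in model.parameters()]
        self._v = [np.zeros_like(arr) for _, _, arr in model.parameters()]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, (layer, name, arr) in enumerate(self.model.parameters()):
            g = layer.grads[name]
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / b1t
            vhat = self._v[i] / b2t
            arr -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(arr.dtype)


def collect_flat_grads(model: UNet3D) -> np.ndarray:
    return np.concatenate([layer.grads[name].ravel().astype(np.float64)
                           for layer, name, _ in model.parameters()])

def assign_flat_grads(model: UNet3D, flat: np.ndarray) -> None:
    pos = 0
    for layer, name, _ in model.parameters():
        g = layer.grads[name]
        g[...] = flat[pos:pos + g.size].reshape(g.shape).astype(g.dtype)
        pos += g.size


# --------------------------------------------------------------------------
# curriculum training
# --------------------------------------------------------------------------

def _sample_grad(model, volume, labels, weights, dice_weight):
    """Forward + backward for one sample; gradients accumulate in the model."""
    logits = model.forward_logits(volume, training=True)
    loss, dlogits = loss_and_logit_grad(logits, labels, weights, dice_weight)
    model.backward(dlogits)
    return loss


def _random_right_angle_rotation(volume, labels, rng):
    """Apply one of the right-angle orientations to a (volume, labels) pair.

    Composing an axis permutation with axis flips covers the full 48-element
    cube symmetry group; labels are rotated identically so ground truth stays
    aligned.
    """
    perm = tuple(rng.permutation(3))
    flips = [a for a in range(3) if rng.random() < 0.5]
    v = np.flip(np.transpose(volume, perm), flips)
    l = np.flip(np.transpose(labels, perm), flips)
    return np.ascontiguousarray(v), np.ascontiguousarray(l)


def train_curriculum(model: UNet3D, datasets_by_bin: dict, config: TrainConfig,
                     validation=None):
    """Run the three-phase curriculum with GEM on a bin-partitioned dataset.

    Parameters
    ----------
    model : UNet3D
        Freshly built (or partially trained) network; trained in place.
    datasets_by_bin : dict
        ``{1: [(volume, labels), ...], 2: [...], 3: [...]}`` with volumes
        already normalised to [0, 1] and padded to multiples of 4.  Bins 2-3
        may be empty; bin 1 must not be.
    validation : list of (volume, labels), optional
        Held-out samples; evaluation-mode loss is recorded per epoch and
        drives early stopping when ``config.patience`` is set.

    Returns
    -------
    (model, history) where history maps phase/epoch records, the episodic
    memory sizes, and a counter of GEM projections actually applied.
    """
    for b in (1, 2, 3):
        datasets_by_bin.setdefault(b, [])
    if not datasets_by_bin[1]:
        raise ValueError("curriculum phase 1 requires a non-empty Bin 1")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model, config.learning_rate)
    history = {"epochs": [], "gem_projections": 0, "memory_sizes": [],
               "phase_class_weights": []}
    epoch_global = 0
    best_state = None

    for phase in PHASES:
        n_epochs = config.epochs_per_phase[phase.phase_index - 1]
        train_set = [s for b in phase.bins_included for s in datasets_by_bin[b]]
        if n_epochs == 0 or not train_set:
            history["memory_sizes"].append(0)
            history["phase_class_weights"].append(None)
            continue
        try:
            weights = compute_class_weights([labels for _, labels in train_set])
        except ValueError as exc:
            # a class can be absent from the early bins of a small corpus;
            # fall back to the class distribution of the full dataset
            all_labels = [labels for b in (1, 2, 3) for _, labels in datasets_by_bin[b]]
            logger.warning("%s; using whole-dataset class weights for phase %d",
                           exc, phase.phase_index)
            weights = compute_class_weights(all_labels)
        history["phase_class_weights"].append(weights)
        if phase.phase_index == 1:
            memory: list = []
        else:
            previous = [s for b in range(1, phase.phase_index) for s in datasets_by_bin[b]]
            memory = sample_episodic_memory(previous, config.memory_size, rng)
        history["memory_sizes"].append(len(memory))
        best_val, stale = np.inf, 0
        for _ in range(n_epochs):
            lr_scale = 0.1 ** (epoch_global // max(config.weight_decay_step, 1))
            optimizer.lr = config.learning_rate * lr_scale
            order = rng.permutation(len(train_set))
            epoch_loss = 0.0
            bs = config.batch_size
            for start in range(0, len(order), bs):
                chunk = order[start:start + bs]
                model.zero_grad()
                for i in chunk:
                    volume, labels = train_set[i]
                    if config.augment_rotations:
                        volume, labels = _random_right_angle_rotation(volume, labels, rng)
                    epoch_loss += _sample_grad(model, volume, labels, weights,
                                               config.dice_weight)
                grad = collect_flat_grads(model) / len(chunk)
                if memory:
                    model.zero_grad()
                    for mv, ml in memory:
                        _sample_grad(model, mv, ml, weights, config.dice_weight)
                    mem_flat = collect_flat_grads(model) / len(memory)
                    if mem_flat @ mem_flat > 0 and grad @ mem_flat < 0:
                        grad = gem_project(grad, mem_flat)
                        history["gem_projections"] += 1
                assign_flat_grads(model, grad)
                optimizer.step()
            record = {
                "phase": phase.phase_index,
                "epoch": epoch_global,
                "lr": optimizer.lr,
                "train_loss": epoch_loss / len(train_set),
            }
            if validation:
                val_loss = 0.0
                for entry in validation:
                    vv, vl = entry[0], entry[1]
                    logits = model.forward_logits(vv, training=False)
                    vloss, _ = loss_and_logit_grad(logits, vl, weights, config.dice_weight)
                    val_loss += vloss
                record["val_loss"] = val_loss / len(validation)
                if config.select_best:
                    record["val_f1"] = _validation_f1(model, validation)
                    if record["val_f1"] > history.get("best_val_f1", -1.0):
                        history["best_val_f1"] = record["val_f1"]
                        history["best_epoch"] = epoch_global
                        best_state = {key: arr.copy()
                                      for key, arr in model.state_arrays().items()}
            history["epochs"].append(record)
            epoch_global += 1
            if validation and config.patience is not None:
                if record["val_loss"] < best_val - 1e-6:
                    best_val, stale = record["val_loss"], 0
                else:
                    stale += 1
                    if stale > config.patience:
                        logger.info("early stop in phase %d", phase.phase_index)
                        break
    if best_state is not None:
        model.load_state_arrays(best_state)
        logger.info("restored best-validation weights from epoch %s",
                    history.get("best_epoch"))
    return model, history


def _validation_f1(model, validation) -> float:
    """Balanced mean of helix and sheet F1 over a validation set.

    Validation entries are ``(volume, labels)`` pairs, optionally extended to
    ``(volume, labels, annotations, origin)``; with annotations present the
    score is residue-level (majority vote around each Cα), matching the
    protocol's headline metric, otherwise voxel-level.
    """
    from .evaluation import f1_class, vote_residue
    from .inference import argmax_labels
    from .labeling import BACKGROUND, HELIX, SHEET

    class_of = {"helix": HELIX, "sheet": SHEET, "other": BACKGROUND}
    scores = []
    for entry in validation:
        volume, labels = entry[0], entry[1]
        pred = argmax_labels(model.predict_proba(volume))
        if len(entry) >= 4 and entry[2] is not None:
            annotations, origin = entry[2], entry[3]
            true_res = np.array([class_of[a.ss_class] for a in annotations])
            pred_res = np.array([vote_residue(pred, a.ca_coord, origin)
                                 for a in annotations])
            pred, labels = pred_res, true_res
        for cls in (HELIX, SHEET):
            f1 = f1_class(pred, labels, cls)
            if f1 is not None:
                scores.append(f1)
    return float(np.mean(scores)) if scores else 0.0
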