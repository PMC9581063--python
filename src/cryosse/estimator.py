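"""Scikit-learn-style estimator wrapping the full segmentation workflow.

:class:`SecondaryStructureSegmenter` is the package's primary entry point:
``fit`` runs the three-phase curriculum with gradient episodic memory on a
collection of (density, label) component maps, ``predict`` returns per-voxel
class grids, and ``predict_proba`` the 3-class probability grids.  Parameters
follow scikit-learn conventions (settable in ``__init__``, fitted state in
trailing-underscore attributes), so the estimator composes with ``clone`` and
``get_params``/``set_params`` based tooling.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import volio
from .inference import argmax_labels
from .nn.unet import NetworkConfig, UNet3D, count_parameters
from .training import TrainConfig, train_curriculum


def _proper_rotations():
    """The 24 rotations of the cube as (axis permutation, flip axes) pairs
    with determinant +1 (mirror images excluded)."""
    from itertools import permutations

    def perm_sign(p):
        sign = 1
        p = list(p)
        for i in range(3):
            while p[i] != i:
                j = p[i]
                p[i], p[j] = p[j], p[i]
                sign = -sign
        return sign

    out = []
    for perm in permutations(range(3)):
        for mask in range(8):
            flips = tuple(a for a in range(3) if mask >> a & 1)
            if perm_sign(perm) * (-1) ** len(flips) == 1:
                out.append((perm, flips))
    return out


_ROTATIONS = _proper_rotations()


def _orientation_averaged_proba(model, vol):
    """Mean class probabilities over the 24 proper right-angle orientations."""
    inv_total = None
    for perm, flips in _ROTATIONS:
        v = np.ascontiguousarray(np.flip(np.transpose(vol, perm), flips))
        probs = model.predict_proba(v)  # (d', h', w', 3)
        back = np.flip(probs, flips)
        inv_perm = tuple(np.argsort(perm)) + (3,)
        restored = np.transpose(back, inv_perm)
        inv_total = restored if inv_total is None else inv_total + restored
    return (inv_total / len(_ROTATIONS)).astype(np.float32)


class SecondaryStructureSegmenter(BaseEstimator):
    """3-class voxel segmenter for medium-resolution cryo-EM component maps.

    Parameters
    ----------
    base_channels : int
        Width of the first U-Net composite layer; widths double per level.
        64 matches a full-scale model; 8 is a desk-scale setting.
    dropout_rate : float
        Dropout applied between composite layers during training.
    dice_weight : float
        Fraction of the combined loss contributed by soft dice (the rest is
        inverse-frequency-weighted cross-entropy).
    learning_rate, lr_decay_step : float, int
        Adam step size, decayed ×0.1 every ``lr_decay_step`` epochs.
    epochs_per_phase : tuple of 3 ints
        Epoch budget of each curriculum phase.
    memory_size : int
        Number of episodic-memory examples used for the GEM projection.
    batch_size : int
        Maps whose gradients are accumulated and averaged per Adam step
        (sizes may differ; accumulation sidesteps tensor batching).
    augment_rotations : bool
        Present each training map in a random right-angle orientation per
        step; useful orientation coverage for small corpora.
    orientation_average : bool
        At prediction time, average class probabilities over the 24 proper
        right-angle rotations of the input.
    select_best : bool
        Keep the weights of the epoch with the best balanced validation F1
        (requires validation data in ``fit``; residue-level when validation
        entries carry Cα annotations).
    patience : int or None
        Per-phase early stopping on validation loss, if validation data is
        passed to ``fit``.
    seed : int
        Seeds weight initialisation, shuffling, dropout, augmentation and
        memory sampling.

    Attributes
    ----------
    model_ : UNet3D
        The trained network.
    history_ : dict
        Per-epoch losses, episodic-memory sizes, GEM projection count.
    n_parameters_ : int
        Trainable parameter count of the fitted network.
    classes_ : ndarray
        ``[0, 1, 2]`` — background, helix, sheet.
    """

    def __init__(self, base_channels=8, dropout_rate=0.1, dice_weight=0.5,
                 learning_rate=1e-3, lr_decay_step=1000,
                 epochs_per_phase=(3, 3, 3), memory_size=5, batch_size=1,
                 augment_rotations=False, orientation_average=False,
                 select_best=False, patience=None, seed=0):
        self.base_channels = base_channels
        self.dropout_rate = dropout_rate
        self.dice_weight = dice_weight
        self.learning_rate = learning_rate
        self.lr_decay_step = lr_decay_step
        self.epochs_per_phase = epochs_per_phase
        self.memory_size = memory_size
        self.batch_size = batch_size
        self.augment_rotations = augment_rotations
        self.orientation_average = orientation_average
        self.select_best = select_best
        self.patience = patience
        self.seed = seed

    # -- helpers ----------------------------------------------------------

    @staticmethod
    def _as_density(x) -> volio.DensityMap:
        if isinstance(x, volio.DensityMap):
            return x
        return volio.DensityMap(np.asarray(x))

    def _prepare(self, x, labels=None):
        """Normalise + pad a sample; labels are padded with background."""
        density = self._as_density(x)
        padded, spec = volio.pad_for_network(volio.normalize(density), divisor=4)
        if labels is None:
            return padded.data, spec
        lab = np.pad(np.asarray(labels),
                     list(zip(spec.pad_before, spec.pad_after)))
        return padded.data, lab.astype(np.int8), spec

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y, bins=None, validation=None):
        """Train on component maps.

        Parameters
        ----------
        X : sequence of DensityMap or 3D arrays (1 Å/voxel)
        y : sequence of int label grids matching X
        bins : sequence of {1, 2, 3}, optional
            Curriculum quality bin of each sample (1 = best fit).  Defaults
            to all samples in bin 1, i.e. plain non-curriculum training.
        validation : sequence of (map, labels), optional
        """
        if len(X) != len(y):
            raise ValueError("X and y must have the same length")
        if bins is None:
            bins = [1] * len(X)
        datasets_by_bin: dict[int, list] = {1: [], 2: [], 3: []}
        for x_i, y_i, b in zip(X, y, bins):
            vol, lab, _ = self._prepare(x_i, y_i)
            datasets_by_bin[int(b)].append((vol, lab))
        val_prepared = None
        if validation is not None:
            # entries are (map, labels) or (map, labels, annotations); with
            # annotations, checkpoint selection scores residue-level F1
            val_prepared = []
            for entry in validation:
                density = self._as_density(entry[0])
                padded, spec = volio.pad_for_network(volio.normalize(density), divisor=4)
                lab = np.pad(np.asarray(entry[1]),
                             list(zip(spec.pad_before, spec.pad_after))).astype(np.int8)
                annotations = entry[2] if len(entry) > 2 else None
                val_prepared.append((padded.data, lab, annotations, padded.origin))
        config = TrainConfig(
            learning_rate=self.learning_rate,
            weight_decay_step=self.lr_decay_step,
            dropout_rate=self.dropout_rate,
            epochs_per_phase=tuple(self.epochs_per_phase),
            memory_size=self.memory_size,
            dice_weight=self.dice_weight,
            batch_size=self.batch_size,
            augment_rotations=self.augment_rotations,
            select_best=self.select_best,
            seed=self.seed,
            patience=self.patience,
        )
        model = UNet3D(NetworkConfig(base_channels=self.base_channels,
                                     dropout_rate=self.dropout_rate),
                       seed=self.seed)
        self.model_, self.history_ = train_curriculum(
            model, datasets_by_bin, config, validation=val_prepared)
        self.n_parameters_ = count_parameters(self.model_)
        self.classes_ = np.array([0, 1, 2])
        return self

    def predict_proba(self, X):
        """Per-voxel class probability grids, shape (x, y, z, 3) each.

        When ``orientation_average`` is set, the probabilities are the mean
        over the 24 proper right-angle rotations of the input (each rotated
        map is segmented and the prediction rotated back).  The network is
        not rotation-equivariant, so averaging over the cube group removes
        the dependence of the prediction on the arbitrary orientation in
        which a component was boxed.
        """
        self._check_fitted()
        out = []
        for x in X:
            vol, spec = self._prepare(x)
            if self.orientation_average:
                probs = _orientation_averaged_proba(self.model_, vol)
            else:
                probs = self.model_.predict_proba(vol)
            out.append(volio.unpad_array(probs, spec))
        return out

    def predict(self, X):
        """Per-voxel argmax label grids (ties: helix > sheet > background)."""
        return [argmax_labels(p) for p in self.predict_proba(X)]

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this SecondaryStructureSegmenter is not fitted yet")
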