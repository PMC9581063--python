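"""End-to-end 3D U-Net for 3-class voxel segmentation of density maps.

The network has five composite layers: two on the down-sampling path, a
bottleneck, and two on the up-sampling path.  Each composite layer is two
(convolution 3³ → batch-norm → ReLU) blocks.  Consecutive layers are joined
by dropout followed by 2× max pooling on the way down, or by a 2³/stride-2
transpose convolution on the way up; mirrored layers are connected by
channel-concatenation skips.  A final 1³ convolution maps to the three class
channels (background, helix, sheet).  Because every operation is convolutional
the model accepts any input whose dimensions are multiples of 4 (two 2×
poolings must divide evenly), up to the 100-voxel design limit.

Channel widths double per level (c, 2c, 4c at the bottleneck) and are
configurable; the parameter count for a given width is reported by
:func:`count_parameters` rather than assumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ..volio import MAX_DIM, SizeLimitError
from .layers import (
    BatchNorm3d,
    Conv3d,
    ConvTranspose3d,
    Dropout,
    MaxPool3d,
    ReLU,
    softmax_channels,
)

NUM_CLASSES = 3
CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    ``base_channels`` is the width of the first composite layer; widths double
    per level.  ``depth`` and ``num_classes`` are fixed by the architecture
    and recorded for checkpoint self-description.
    """

    base_channels: int = 64
    dropout_rate: float = 0.1
    batchnorm_affine: bool = True
    num_classes: int = NUM_CLASSES
    depth: int = 5

    def __post_init__(self):
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.num_classes != NUM_CLASSES or self.depth != 5:
            raise ValueError("the architecture is fixed at 5 composite layers and 3 classes")


class _ConvBlock:
    """Two (conv 3³ → batch-norm → ReLU) units."""

    def __init__(self, cin, cout, rng, affine):
        self.ops = [
            Conv3d(cin, cout, 3, rng), BatchNorm3d(cout, affine=affine), ReLU(),
            Conv3d(cout, cout, 3, rng), BatchNorm3d(cout, affine=affine), ReLU(),
        ]

    def forward(self, x, training):
        for op in self.ops:
            x = op.forward(x, training)
        return x

    def backward(self, dy):
        for op in reversed(self.ops):
            dy = op.backward(dy)
        return dy


class UNet3D:
    """The segmentation network; see the module docstring for the topology."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        c = config.base_channels
        aff = config.batchnorm_affine
        self.enc1 = _ConvBlock(1, c, rng, aff)
        self.drop1 = Dropout(config.dropout_rate, rng)
        self.pool1 = MaxPool3d()
        self.enc2 = _ConvBlock(c, 2 * c, rng, aff)
        self.drop2 = Dropout(config.dropout_rate, rng)
        self.pool2 = MaxPool3d()
        self.bottleneck = _ConvBlock(2 * c, 4 * c, rng, aff)
        self.drop3 = Dropout(config.dropout_rate, rng)
        self.up2 = ConvTranspose3d(4 * c, 2 * c, rng)
        self.dec2 = _ConvBlock(4 * c, 2 * c, rng, aff)
        self.drop4 = Dropout(config.dropout_rate, rng)
        self.up1 = ConvTranspose3d(2 * c, c, rng)
        self.dec1 = _ConvBlock(2 * c, c, rng, aff)
        self.final = Conv3d(c, config.num_classes, 1, rng)

    # -- plumbing ---------------------------------------------------------

    def _layers(self):
        for block in (self.enc1, self.enc2, self.bottleneck, self.dec2, self.dec1):
            yield from block.ops
        yield from (self.up2, self.up1, self.final)

    def parameters(self):
        """Yield (layer, name, array) for every trainable parameter."""
        for layer in self._layers():
            for name, arr in layer.params.items():
                yield layer, name, arr

    def zero_grad(self):
        for layer in self._layers():
            layer.zero_grad()

    # -- forward / backward ----------------------------------------------

    def validate_input(self, shape):
        for n in shape:
            if n > MAX_DIM:
                raise SizeLimitError(
                    f"input dimension {n} exceeds the {MAX_DIM}-voxel design limit"
                )
            if n % 4 != 0:
                raise ValueError(
                    f"input dimension {n} is not a multiple of 4; "
                    "use pad_for_network before inference"
                )

    def forward_logits(self, volume: np.ndarray, training: bool = False) -> np.ndarray:
        """(D, H, W) density -> (3, D, H, W) class logits."""
        self.validate_input(volume.shape)
        x = np.asarray(volume, dtype=np.float32)[None]  # 1 input channel
        e1 = self.enc1.forward(x, training)
        x = self.pool1.forward(self.drop1.forward(e1, training), training)
        e2 = self.enc2.forward(x, training)
        x = self.pool2.forward(self.drop2.forward(e2, training), training)
        x = self.bottleneck.forward(x, training)
        x = self.up2.forward(self.drop3.forward(x, training), training)
        x = self.dec2.forward(np.concatenate([e2, x], axis=0), training)
        x = self.up1.forward(self.drop4.forward(x, training), training)
        x = self.dec1.forward(np.concatenate([e1, x], axis=0), training)
        self._skip_channels = (e1.shape[0], e2.shape[0])
        return self.final.forward(x, training)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        c1, c2 = self._skip_channels
        dy = self.final.backward(dlogits)
        dy = self.dec1.backward(dy)
        de1, dy = dy[:c1], dy[c1:]
        dy = self.drop4.backward(self.up1.backward(dy))
        dy = self.dec2.backward(dy)
        de2, dy = dy[:c2], dy[c2:]
        dy = self.drop3.backward(self.up2.backward(dy))
        dy = self.bottleneck.backward(dy)
        dy = self.drop2.backward(self.pool2.backward(dy)) + de2
        dy = self.enc2.backward(dy)
        dy = self.drop1.backward(self.pool1.backward(dy)) + de1
        self.enc1.backward(dy)

    def predict_proba(self, volume: np.ndarray) -> np.ndarray:
        """(D, H, W) density -> (D, H, W, 3) per-voxel class probabilities."""
        logits = self.forward_logits(volume, training=False)
        return softmax_channels(logits).transpose(1, 2, 3, 0)

    # -- checkpointing ----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self._layers()):
            for name, arr in layer.params.items():
                state[f"layer{i}.{name}"] = arr
        return state

    def load_state_arrays(self, state) -> None:
        for i, layer in enumerate(self._layers()):
            for name in layer.params:
                layer.params[name][...] = state[f"layer{i}.{name}"]


def build_model(config: NetworkConfig, seed: int = 0) -> UNet3D:
    """Construct a randomly initialised (Kaiming) network from a config."""
    return UNet3D(config, seed=seed)


def forward(model: UNet3D, volume: np.ndarray) -> np.ndarray:
    """Evaluation-mode forward pass returning a (D, H, W, 3) probability grid."""
    return model.predict_proba(volume)


def count_parameters(model: UNet3D) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(arr.size for _, _, arr in model.parameters()))


def save_checkpoint(model: UNet3D, path) -> None:
    """Write weights + config + class-order metadata as a single .npz file."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "class_order": ["background", "helix", "sheet"],
    }
    state = model.state_arrays()
    np.savez_compressed(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> UNet3D:
    """Rebuild a network from a checkpoint written by :func:`save_checkpoint`."""
    try:
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["_meta"]).decode())
            state = {k: npz[k] for k in npz.files if k != "_meta"}
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise IOError(f"unreadable checkpoint {path}: {exc}") from None
    if meta.get("version") != CHECKPOINT_VERSION:
        raise IOError(f"unsupported checkpoint version {meta.get('version')}")
    model = UNet3D(NetworkConfig(**meta["config"]))
    model.load_state_arrays(state)
    return model
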