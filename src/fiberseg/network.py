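"""The SEM/TEM encoder-decoder segmentation network.

A depth-4 fully convolutional encoder-decoder in the U-Net family.  The
contracting path has, per block, ``convs_per_block`` bias-free convolutions
(5x5 kernels in the first block, 3x3 elsewhere), each followed by batch
normalization and ReLU, then a channel-preserving 5x5 stride-2 convolution
that halves the resolution.  Channel widths double per block starting from
16.  The expanding path mirrors this: bilinear x2 upsampling followed by a
2x2 convolution down to the skip width, concatenation with the block's
pre-stride features, and ``convs_per_block`` convolutions whose first halves
the concatenated width (5x5 kernels at the finest level, 3x3 elsewhere).
A 1x1 convolution with bias maps to 3 channels and a softmax yields
per-pixel class probabilities (background, myelin, axon).

The SEM variant uses 3 convolutions per block (1,953,219 trainable
parameters); the TEM variant uses 2 (1,552,387).  These totals pin down
every architectural convention above: changing any of them (bias-free
convs, 5x5 strided downsampling, 2x2 post-upsampling convs, 5x5 finest
expansion kernels, biased 1x1 classifier) breaks at least one total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .engine import BatchNorm2d, Conv2d, Dropout, Param, ReLU, Upsample2x, softmax

__all__ = ["NetworkSpec", "UNet", "build_network", "count_trainable_parameters",
           "load_model", "save_model"]

_CONVS_PER_BLOCK = {"SEM": 3, "TEM": 2}
_PIXEL_SIZE = {"SEM": 0.1, "TEM": 0.01}


@dataclass
class NetworkSpec:
    """Complete architectural description; fully determines the parameter count.

    Parameters
    ----------
    variant
        ``"SEM"`` (3 convolutions per block, working pixel size 0.1 um) or
        ``"TEM"`` (2 convolutions per block, 0.01 um).
    depth
        Number of resolution halvings; input sides must be divisible by
        ``2**depth``.
    base_width
        Channels of the first block; doubled per block.
    convs_per_block, training_pixel_size
        Default from the variant; overridable for reduced desk-scale models.
    """

    variant: str = "SEM"
    depth: int = 4
    base_width: int = 16
    convs_per_block: int | None = None
    dropout: float = 0.25
    first_kernel: int = 5
    kernel: int = 3
    down_kernel: int = 5
    up_kernel: int = 2
    n_classes: int = 3
    training_pixel_size: float | None = None
    dtype: str = "float32"

    def __post_init__(self) -> None:
        self.variant = self.variant.upper()
        if self.variant not in _CONVS_PER_BLOCK:
            raise ValueError(f"variant must be 'SEM' or 'TEM', got {self.variant!r}")
        if self.convs_per_block is None:
            self.convs_per_block = _CONVS_PER_BLOCK[self.variant]
        if self.training_pixel_size is None:
            self.training_pixel_size = _PIXEL_SIZE[self.variant]

    @property
    def widths(self) -> list[int]:
        return [self.base_width * 2 ** b for b in range(self.depth)]

    @property
    def divisor(self) -> int:
        return 2 ** self.depth

    def to_dict(self) -> dict:
        return {
            "variant": self.variant, "depth": self.depth, "base_width": self.base_width,
            "convs_per_block": self.convs_per_block, "dropout": self.dropout,
            "first_kernel": self.first_kernel, "kernel": self.kernel,
            "down_kernel": self.down_kernel, "up_kernel": self.up_kernel,
            "n_classes": self.n_classes, "training_pixel_size": self.training_pixel_size,
            "dtype": self.dtype,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(**d)


class UNet:
    """Encoder-decoder model built from a :class:`NetworkSpec`.

    Holds explicit layer lists; ``forward`` caches activations so that
    ``backward`` (which takes the gradient with respect to the pre-softmax
    logits) can propagate through the skip connections.
    """

    def __init__(self, spec: NetworkSpec, seed: int | None = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.rng = np.random.default_rng(rng.integers(2**31))  # dropout stream
        self.training = False
        w = spec.widths
        dtype = np.dtype(spec.dtype)

        def conv_unit(cin, cout, k, stride=1, drop=True):
            unit = [Conv2d(cin, cout, k, stride=stride, bias=False, rng=rng, dtype=dtype),
                    BatchNorm2d(cout, dtype=dtype), ReLU()]
            if drop and spec.dropout > 0:
                unit.append(Dropout(spec.dropout))
            return unit

        # contracting path
        self.enc_blocks: list[list] = []
        self.down_layers: list[list] = []
        cin = 1
        for b in range(spec.depth):
            k = spec.first_kernel if b == 0 else spec.kernel
            block: list = []
            for i in range(spec.convs_per_block):
                block.extend(conv_unit(cin if i == 0 else w[b], w[b], k))
                cin = w[b]
            self.enc_blocks.append(block)
            self.down_layers.append(conv_unit(w[b], w[b], spec.down_kernel,
                                              stride=2, drop=False))

        # expanding path, deepest level first
        self.up_layers: list[list] = []
        self.dec_blocks: list[list] = []
        cin = w[-1]
        for lvl in reversed(range(spec.depth)):
            up = [Upsample2x()] + conv_unit(cin, w[lvl], spec.up_kernel, drop=False)
            self.up_layers.append(up)
            k = spec.first_kernel if lvl == 0 else spec.kernel
            block = []
            for i in range(spec.convs_per_block):
                block.extend(conv_unit(2 * w[lvl] if i == 0 else w[lvl], w[lvl], k))
            self.dec_blocks.append(block)
            cin = w[lvl]

        self.classifier = Conv2d(w[0], spec.n_classes, 1, bias=True, rng=rng,
                                 dtype=dtype)
        self._levels = list(reversed(range(spec.depth)))  # decoder level order

    # -- mode & parameter plumbing ------------------------------------------

    def train(self) -> "UNet":
        self.training = True
        return self

    def eval(self) -> "UNet":
        self.training = False
        return self

    def _layer_groups(self):
        for b, block in enumerate(self.enc_blocks):
            yield f"enc{b}", block
            yield f"down{b}", self.down_layers[b]
        for i, lvl in enumerate(self._levels):
            yield f"up{lvl}", self.up_layers[i]
            yield f"dec{lvl}", self.dec_blocks[i]
        yield "classifier", [self.classifier]

    def named_params(self) -> list[tuple[str, Param]]:
        out = []
        for gname, layers in self._layer_groups():
            for li, layer in enumerate(layers):
                for pi, p in enumerate(layer.params()):
                    out.append((f"{gname}.{li}.{pi}", p))
        return out

    def params(self) -> list[Param]:
        return [p for _, p in self.named_params()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def set_bn_momentum(self, momentum: float) -> None:
        for _, layers in self._layer_groups():
            for layer in layers:
                if isinstance(layer, BatchNorm2d):
                    layer.momentum = momentum

    def named_buffers(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for gname, layers in self._layer_groups():
            for li, layer in enumerate(layers):
                if isinstance(layer, BatchNorm2d):
                    out.append((f"{gname}.{li}.running_mean", layer.running_mean))
                    out.append((f"{gname}.{li}.running_var", layer.running_var))
        return out

    # -- forward / backward --------------------------------------------------

    def _run(self, layers: list, x: np.ndarray) -> np.ndarray:
        for layer in layers:
            if isinstance(layer, BatchNorm2d):
                x = layer.forward(x, self.training)
            elif isinstance(layer, Dropout):
                x = layer.forward(x, self.training, self.rng)
            else:
                x = layer.forward(x)
        return x

    @staticmethod
    def _run_back(layers: list, d: np.ndarray) -> np.ndarray:
        for layer in reversed(layers):
            d = layer.backward(d)
        return d

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map ``(N, 1, H, W)`` normalized patches to ``(N, n_classes, H, W)``
        per-pixel class probabilities (softmax over channel 1)."""
        x = np.asarray(x, dtype=np.dtype(self.spec.dtype))
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        n, c, h, w = x.shape
        if h % self.spec.divisor or w % self.spec.divisor:
            raise ValueError(
                f"input sides must be divisible by {self.spec.divisor}, got {(h, w)}")
        skips = []
        for b in range(self.spec.depth):
            x = self._run(self.enc_blocks[b], x)
            skips.append(x)
            x = self._run(self.down_layers[b], x)
        for i, lvl in enumerate(self._levels):
            x = self._run(self.up_layers[i], x)
            x = np.concatenate([skips[lvl], x], axis=1)
            x = self._run(self.dec_blocks[i], x)
        logits = self.classifier.forward(x)
        self._logits = logits
        return softmax(logits, axis=1)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate a gradient with respect to the pre-softmax logits."""
        d = self.classifier.backward(np.asarray(dlogits, dtype=np.dtype(self.spec.dtype)))
        dskips: dict[int, np.ndarray] = {}
        for i in reversed(range(len(self._levels))):
            lvl = self._levels[i]
            d = self._run_back(self.dec_blocks[i], d)
            w = self.spec.widths[lvl]
            dskips[lvl] = d[:, :w]
            d = self._run_back(self.up_layers[i], np.ascontiguousarray(d[:, w:]))
        for b in reversed(range(self.spec.depth)):
            d = self._run_back(self.down_layers[b], d)
            d = d + dskips[b]
            d = self._run_back(self.enc_blocks[b], d)

    __call__ = forward


def build_network(spec: NetworkSpec, seed: int | None = 0) -> UNet:
    """Instantiate the model described by ``spec`` with He-initialized weights."""
    return UNet(spec, seed=seed)


def count_trainable_parameters(spec: NetworkSpec) -> int:
    """Total trainable parameters: convolution kernels, the classifier bias,
    and one scale/shift pair per batch-normalized channel (running statistics
    are not trainable and are not counted)."""
    return UNet(spec, seed=0).num_parameters()


def save_model(model: UNet, out_dir: str | Path) -> None:
    """Write weights, batch-norm statistics and the spec sidecar to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = {f"param:{n}": p.data for n, p in model.named_params()}
    arrays.update({f"buffer:{n}": b for n, b in model.named_buffers()})
    np.savez(out_dir / "weights.npz", **arrays)
    with open(out_dir / "network_spec.json", "w") as fh:
        json.dump(model.spec.to_dict(), fh, indent=2)


def load_model(model_dir: str | Path) -> UNet:
    model_dir = Path(model_dir)
    with open(model_dir / "network_spec.json") as fh:
        spec = NetworkSpec.from_dict(json.load(fh))
    model = UNet(spec, seed=0)
    with np.load(model_dir / "weights.npz") as data:
        for n, p in model.named_params():
            p.data[...] = data[f"param:{n}"]
        for n, b in model.named_buffers():
            b[...] = data[f"buffer:{n}"]
    return model.eval()
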