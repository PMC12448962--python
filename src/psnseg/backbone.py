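"""Segmentation-model contract, Swin UNETR architecture descriptor, and the
desk-scale reference encoder-decoder.

The patient-specific fine-tuning strategy is backbone-agnostic, so this
package ships three things:

* :class:`ArchitectureDescriptor` — a declarative record of the full
  clinical Swin UNETR configuration (patch size, embedding width, stage
  depths/heads, attention window, drop-path, decoder design), exportable to
  YAML and consumable by an external Swin UNETR implementation where one is
  installed;
* the :class:`ModelContract` protocol every backbone must satisfy (two-channel
  score grid of the input's spatial shape, serializable parameters);
* :class:`ReferenceNet` — a small numpy convolutional encoder-decoder used
  for CPU-scale experiments and tests.  Its decoder mirrors the clinical
  design in miniature: stride-2 downsampling, skip concatenation per stage,
  3x3x3 convolution blocks, and a 1x1x1 two-class head.

Model input is the clipped HU window mapped linearly to [0, 1].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
import yaml

from . import nn
from .volume import Volume

__all__ = [
    "ArchitectureDescriptor",
    "build_swin_descriptor",
    "ModelContract",
    "ReferenceNet",
    "build_reference_net",
    "softmax_scores",
    "sliding_window_predict",
]


@dataclass(frozen=True)
class ArchitectureDescriptor:
    """Declarative Swin UNETR configuration for two-class volumetric
    segmentation (target vs background)."""

    patch_size: tuple[int, int, int] = (2, 2, 2)
    embed_dim: int = 48
    depths: tuple[int, int, int, int] = (2, 2, 2, 2)
    heads: tuple[int, int, int, int] = (3, 6, 12, 24)
    window: tuple[int, int, int] = (7, 7, 7)
    stage_channels: tuple[int, int, int, int] = (48, 96, 192, 384)
    bottleneck_channels: int = 768
    drop_path_rate: float = 0.10
    decoder: str = (
        "residual blocks of two 3x3x3 convolutions with instance normalization; "
        "stride-2 transposed-convolution upsampling; skip concatenation per stage"
    )
    head: str = "1x1x1 convolution, softmax over {CTV, background}"

    def __post_init__(self) -> None:
        if len(self.heads) != len(self.depths):
            raise ValueError("heads and depths must have equal length")
        expected = tuple(self.embed_dim * 2**i for i in range(len(self.depths)))
        if self.stage_channels != expected:
            raise ValueError(
                f"stage_channels must double from embed_dim: expected {expected}, "
                f"got {self.stage_channels}"
            )

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(
            {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()},
            sort_keys=True,
        )


def build_swin_descriptor() -> ArchitectureDescriptor:
    """The clinical-scale configuration: 2x2x2 voxel patches embedded at
    width 48, four two-block Swin stages (48->96->192->384 channels, heads
    3/6/12/24, 7x7x7 attention windows), a 768-channel bottleneck and 0.10
    drop-path."""
    return ArchitectureDescriptor()


@runtime_checkable
class ModelContract(Protocol):
    """What the training and inference code requires of a backbone."""

    def forward(self, x: np.ndarray) -> np.ndarray: ...
    def backward(self, grad_scores: np.ndarray) -> None: ...
    def parameters(self) -> dict[str, np.ndarray]: ...
    def load_parameters(self, params: dict[str, np.ndarray]) -> None: ...
    def train(self) -> None: ...
    def eval(self) -> None: ...


def softmax_scores(scores: np.ndarray) -> np.ndarray:
    """Per-voxel softmax over the channel axis of a (2, D, H, W) score grid."""
    shifted = scores - scores.max(axis=0, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=0, keepdims=True)


class ReferenceNet:
    """Small seeded encoder-decoder satisfying :class:`ModelContract`.

    ``width`` channels at full resolution, doubling at each of ``depth``
    stride-2 stages; decoder upsamples (nearest) and fuses skip features with
    a 3x3x3 convolution per stage; 1x1x1 two-channel head.  Channel 1 scores
    the target class.
    """

    def __init__(self, width: int = 8, depth: int = 2, seed: int = 0):
        if width < 1 or depth < 1:
            raise ValueError("width and depth must be >= 1")
        self.width, self.depth, self.seed = width, depth, seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
        self.stem = nn.Conv3d(1, width, stride=1, rng=rng)
        self.enc_down: list[nn.Conv3d] = []
        self.enc_conv: list[nn.Conv3d] = []
        ch = width
        for _ in range(depth):
            self.enc_down.append(nn.Conv3d(ch, ch * 2, stride=2, rng=rng))
            self.enc_conv.append(nn.Conv3d(ch * 2, ch * 2, stride=1, rng=rng))
            ch *= 2
        # Decoder stage: 1x1x1 projection of the concatenated (upsampled +
        # skip) features, then a 3x3x3 convolution at the reduced width —
        # same receptive field as a full-width fusion at half the FLOPs.
        self.dec_proj: list[nn.Conv1x1] = []
        self.dec_conv: list[nn.Conv3d] = []
        for _ in range(depth):
            self.dec_proj.append(nn.Conv1x1(ch + ch // 2, ch // 2, rng=rng))
            self.dec_conv.append(nn.Conv3d(ch // 2, ch // 2, stride=1, rng=rng))
            ch //= 2
        self.head = nn.Conv1x1(width, 2, rng=rng)
        self.upsample = nn.Upsample2x()
        self._relus: dict[str, nn.ReLU] = {}
        self.training = True

    # -- layer bookkeeping ---------------------------------------------------
    def _layers(self) -> list:
        return [
            self.stem, *self.enc_down, *self.enc_conv,
            *self.dec_proj, *self.dec_conv, self.head,
        ]

    def _layer_names(self) -> list[str]:
        names = ["stem"]
        names += [f"down{i}" for i in range(self.depth)]
        names += [f"enc{i}" for i in range(self.depth)]
        names += [f"decp{i}" for i in range(self.depth)]
        names += [f"dec{i}" for i in range(self.depth)]
        names += ["head"]
        return names

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in zip(self._layer_names(), self._layers()):
            for k, v in layer.params.items():
                out[f"{name}.{k}"] = v
        return out

    def load_parameters(self, params: dict[str, np.ndarray]) -> None:
        own = self.parameters()
        if set(own) != set(params):
            raise ValueError(
                f"parameter name mismatch: missing {set(own) - set(params)}, "
                f"unexpected {set(params) - set(own)}"
            )
        for name, layer in zip(self._layer_names(), self._layers()):
            for k in layer.params:
                src = np.asarray(params[f"{name}.{k}"], dtype=layer.params[k].dtype)
                if src.shape != layer.params[k].shape:
                    raise ValueError(f"shape mismatch for {name}.{k}")
                layer.params[k][...] = src

    def train(self) -> None:
        self.training = True

    def eval(self) -> None:
        self.training = False

    # -- forward / backward --------------------------------------------------
    def _relu(self, key: str) -> nn.ReLU:
        if key not in self._relus:
            self._relus[key] = nn.ReLU()
        return self._relus[key]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(1, D, H, W) normalized intensities -> (2, D, H, W) class scores."""
        if x.ndim != 4 or x.shape[0] != 1:
            raise ValueError(f"expected input shape (1, D, H, W), got {x.shape}")
        if any(n % 2**self.depth or n < 2**self.depth for n in x.shape[1:]):
            raise ValueError(
                f"spatial shape {x.shape[1:]} must be a multiple of 2^depth = {2**self.depth}"
            )
        x = x.astype(np.float32)
        h = self._relu("stem").forward(self.stem.forward(x))
        skips = []
        for i in range(self.depth):
            skips.append(h)
            h = self._relu(f"down{i}").forward(self.enc_down[i].forward(h))
            h = self._relu(f"enc{i}").forward(self.enc_conv[i].forward(h))
        self._up_shapes = []
        for i in range(self.depth):
            skip = skips.pop()
            up = h.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)
            self._up_shapes.append(h.shape)
            h = np.concatenate([up, skip], axis=0)
            h = self._relu(f"decp{i}").forward(self.dec_proj[i].forward(h))
            h = self._relu(f"dec{i}").forward(self.dec_conv[i].forward(h))
        return self.head.forward(h)

    def backward(self, grad_scores: np.ndarray) -> None:
        g = self.head.backward(grad_scores)
        skip_grads = []
        for i in reversed(range(self.depth)):
            g = self._relu(f"dec{i}").backward(g)
            g = self.dec_conv[i].backward(g)
            g = self._relu(f"decp{i}").backward(g)
            g = self.dec_proj[i].backward(g)
            c, d, h_, w = self._up_shapes[i]
            g_up, g_skip = g[:c], g[c:]
            skip_grads.append(g_skip)  # decoder stage i consumed skip depth-1-i
            g = g_up.reshape(c, d, 2, h_, 2, w, 2).sum(axis=(2, 4, 6))
        for i in reversed(range(self.depth)):
            g = self._relu(f"enc{i}").backward(g)
            g = self.enc_conv[i].backward(g)
            g = self._relu(f"down{i}").backward(g)
            g = self.enc_down[i].backward(g)
            g = g + skip_grads[i]  # append order makes skip_grads[j] = skip j
        g = self._relu("stem").backward(g)
        self.stem.backward(g)

    def optimizer(self, lr: float, weight_decay: float) -> nn.AdamW:
        return nn.AdamW(self._layers(), lr=lr, weight_decay=weight_decay)


def build_reference_net(width: int = 8, depth: int = 2, seed: int = 0) -> ReferenceNet:
    """Seeded desk-scale backbone satisfying the model contract."""
    return ReferenceNet(width=width, depth=depth, seed=seed)


def sliding_window_predict(
    model,
    image: Volume,
    patch: tuple[int, int, int],
    overlap: float = 0.5,
) -> np.ndarray:
    """Whole-volume binary prediction by overlap-averaged patch softmax.

    Patch windows tile the grid at stride ``patch * (1 - overlap)`` (always
    including the far edge); per-voxel class probabilities are averaged over
    all covering windows and the target channel is selected by argmax.
    """
    shape = image.shape
    patch = tuple(int(p) for p in patch)
    if any(p > n for p, n in zip(patch, shape)):
        raise ValueError(f"patch {patch} larger than grid {shape}")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    starts_per_axis = []
    for n, p in zip(shape, patch):
        stride = max(1, int(round(p * (1.0 - overlap))))
        starts = list(range(0, n - p + 1, stride))
        if starts[-1] != n - p:
            starts.append(n - p)
        starts_per_axis.append(starts)
    prob = np.zeros(shape, dtype=np.float64)
    count = np.zeros(shape, dtype=np.float64)
    model.eval()
    vals = image.values.astype(np.float32)
    for sz in starts_per_axis[0]:
        for sy in starts_per_axis[1]:
            for sx in starts_per_axis[2]:
                sl = (
                    slice(sz, sz + patch[0]),
                    slice(sy, sy + patch[1]),
                    slice(sx, sx + patch[2]),
                )
                scores = model.forward(vals[sl][None])
                prob[sl] += softmax_scores(scores)[1]
                count[sl] += 1.0
    return (prob / count > 0.5).astype(np.uint8)
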