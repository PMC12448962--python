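"""Minimal numpy building blocks for the desk-scale segmentation network.

This is a deliberately small, fully deterministic convolutional toolkit:
3x3x3 convolutions (stride 1 and 2) evaluated as 27 shifted channel matmuls
(faster and far less memory-hungry than im2col at these sizes), 1x1x1
convolutions, ReLU, nearest-neighbour upsampling, channel concatenation, and
an AdamW optimizer.  Everything runs in float32 on a single thread; given
identical seeds and inputs, forward, backward and updates are bit-reproducible.

Tensors are (C, D, H, W).  Each layer caches what its backward pass needs;
``backward`` consumes the upstream gradient and accumulates parameter
gradients in ``Layer.grads``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3d", "Conv1x1", "ReLU", "Upsample2x", "AdamW", "he_init"]


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv3d:
    """3x3x3 convolution, padding 1, stride 1 or 2, with bias."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        self.c_in, self.c_out, self.stride = c_in, c_out, stride
        self.w = he_init(rng, (c_out, c_in, 3, 3, 3), fan_in=c_in * 27)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.grads = {"w": np.zeros_like(self.w), "b": np.zeros_like(self.b)}
        self._xp: np.ndarray | None = None

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"w": self.w, "b": self.b}

    def _out_shape(self, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        # padding 1, kernel 3: stride 1 preserves size, stride 2 halves (ceil).
        return tuple((n + 2 - 3) // self.stride + 1 for n in spatial)

    def _w_flat(self) -> np.ndarray:
        # (c_out, 27 * c_in), tap-major to match the im2col row layout
        return np.ascontiguousarray(
            self.w.transpose(0, 2, 3, 4, 1).reshape(self.c_out, 27 * self.c_in)
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w_ = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        do, ho, wo = self._out_shape((d, h, w_))
        s = self.stride
        n = do * ho * wo
        cols = np.empty((27, c, n), dtype=np.float32)
        t = 0
        for dz in range(3):
            for dy in range(3):
                for dx in range(3):
                    cols[t] = xp[
                        :, dz : dz + d : s, dy : dy + h : s, dx : dx + w_ : s
                    ].reshape(c, -1)
                    t += 1
        cols = cols.reshape(27 * c, n)
        y = self._w_flat() @ cols + self.b[:, None]
        self._xp = xp
        self._cols = cols
        self._in_spatial = (d, h, w_)
        return y.reshape(self.c_out, do, ho, wo)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xp = self._xp
        assert xp is not None, "forward must run before backward"
        d, h, w_ = self._in_spatial
        s = self.stride
        gyf = np.ascontiguousarray(gy.reshape(self.c_out, -1), dtype=np.float32)
        # Weight gradients: one sgemm against the im2col matrix from forward.
        gw_flat = gyf @ self._cols.T  # (c_out, 27 * c_in), tap-major
        self.grads["w"] += gw_flat.reshape(self.c_out, 3, 3, 3, self.c_in).transpose(
            0, 4, 1, 2, 3
        )
        self.grads["b"] += gyf.sum(axis=1)
        self._cols = None
        if s == 1:
            # Input gradient = correlation of gy with the flipped kernel,
            # also as a single sgemm over gathered gy shifts.
            gyp = np.pad(gyf.reshape(gy.shape), ((0, 0), (1, 1), (1, 1), (1, 1)))
            gcols = np.empty((27, self.c_out, d * h * w_), dtype=np.float32)
            t = 0
            for dz in range(3):
                for dy in range(3):
                    for dx in range(3):
                        gcols[t] = gyp[:, dz : dz + d, dy : dy + h, dx : dx + w_].reshape(
                            self.c_out, -1
                        )
                        t += 1
            # (c_in, 27 * c_out): tap t holds the flipped-tap weights
            w_back = np.ascontiguousarray(
                self.w[:, :, ::-1, ::-1, ::-1].transpose(1, 2, 3, 4, 0).reshape(
                    self.c_in, 27 * self.c_out
                )
            )
            gx = w_back @ gcols.reshape(27 * self.c_out, -1)
            self._xp = None
            return gx.reshape(self.c_in, d, h, w_)
        # Stride 2: scatter-add into the padded grid (small feature maps only).
        gxp = np.zeros_like(xp)
        for dz in range(3):
            for dy in range(3):
                for dx in range(3):
                    sl = (
                        slice(None),
                        slice(dz, dz + d, s),
                        slice(dy, dy + h, s),
                        slice(dx, dx + w_, s),
                    )
                    gpatch = self.w[:, :, dz, dy, dx].T @ gyf
                    gxp[sl] += gpatch.reshape(gxp[sl].shape)
        self._xp = None
        return gxp[:, 1 : 1 + d, 1 : 1 + h, 1 : 1 + w_]


class Conv1x1:
    """Pointwise convolution (channel mixing)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.w = he_init(rng, (c_out, c_in), fan_in=c_in)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.grads = {"w": np.zeros_like(self.w), "b": np.zeros_like(self.b)}
        self._x: np.ndarray | None = None

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"w": self.w, "b": self.b}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        spatial = x.shape[1:]
        y = self.w @ x.reshape(self.c_in, -1) + self.b[:, None]
        return y.reshape(self.c_out, *spatial)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        spatial = x.shape[1:]
        gyf = gy.reshape(self.c_out, -1)
        self.grads["w"] += gyf @ x.reshape(self.c_in, -1).T
        self.grads["b"] += gyf.sum(axis=1)
        self._x = None
        return (self.w.T @ gyf).reshape(self.c_in, *spatial)


class ReLU:
    params: dict[str, np.ndarray] = {}
    grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, np.float32(0.0))


class Upsample2x:
    """Nearest-neighbour 2x upsampling; backward is 2x2x2 block summation."""

    params: dict[str, np.ndarray] = {}
    grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        c, d, h, w = self._in_shape
        return (
            gy.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6)).astype(np.float32)
        )


class AdamW:
    """AdamW with decoupled weight decay over a named-parameter collection."""

    def __init__(
        self,
        layers: list,
        lr: float = 1e-4,
        weight_decay: float = 1e-5,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.layers = [l for l in layers if l.params]
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def zero_grad(self) -> None:
        for layer in self.layers:
            for g in layer.grads.values():
                g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                update = (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
                p -= (self.lr * (update + self.wd * p)).astype(p.dtype)
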