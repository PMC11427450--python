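"""Layers with explicit forward/backward passes.

All activations are float32 ``(N, H, W, C)`` arrays (channels last, so the
im2col lowering is nine contiguous-channel strided copies and the column
matrix reshapes for free).  Convolution weights are stored directly in GEMM
layout ``(k*k*cin, cout)``, shift-major.
"""
from __future__ import annotations

import numpy as np

_SHIFTS3 = [(di, dj) for di in range(3) for dj in range(3)]


class Conv2d:
    """k x k convolution, stride 1, 'same' zero padding (k in {1, 3}).

    He-normal initialization from the supplied generator.  The 3x3 path
    lowers the padded input into nine contiguous per-shift column blocks
    (persistent buffers, so pages are touched once) and accumulates nine
    slim GEMMs — faster on one core than a monolithic im2col matrix.
    """

    def __init__(self, cin: int, cout: int, k: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        if k not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        rng = rng if rng is not None else np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * k * k))
        self.k = k
        self.cin, self.cout = cin, cout
        self.W = (rng.standard_normal((k * k * cin, cout)) * std).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._bufs: dict[str, np.ndarray] = {}
        self._cols: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def _buf(self, name: str, shape: tuple[int, ...]) -> np.ndarray:
        buf = self._bufs.get(name)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=np.float32)
            self._bufs[name] = buf
        return buf

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {c}")
        if self.k == 1:
            cols = x.reshape(-1, c)
            self._cols = cols if train else None
            out = cols @ self.W
            out += self.b
            return out.reshape(n, h, w, self.cout)
        xp = self._buf("xp", (n, h + 2, w + 2, c))
        if self._bufs.get("_xp_zeroed") is not xp:
            xp[:] = 0.0
            self._bufs["_xp_zeroed"] = xp  # border stays zero across calls
        np.copyto(xp[:, 1:-1, 1:-1, :], x)
        cols9 = self._buf("cols9", (9, n, h, w, c))
        for s, (di, dj) in enumerate(_SHIFTS3):
            np.copyto(cols9[s], xp[:, di:di + h, dj:dj + w, :])
        self._cols = cols9 if train else None
        out = self._buf("out", (n * h * w, self.cout))
        np.dot(cols9[0].reshape(-1, c), self.W[:c], out=out)
        for s in range(1, 9):
            out += cols9[s].reshape(-1, c) @ self.W[s * c:(s + 1) * c]
        out += self.b
        return out.reshape(n, h, w, self.cout).copy()

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, h, w, _ = g.shape
        c = self.cin
        g2 = np.ascontiguousarray(g).reshape(-1, self.cout)
        if self.k == 1:
            self.dW = self._cols.T @ g2
            self.db = g2.sum(axis=0)
            self._cols = None
            return (g2 @ self.W.T).reshape(n, h, w, c)
        cols9 = self._cols
        self._cols = None
        dW = np.empty_like(self.W)
        for s in range(9):
            np.dot(cols9[s].reshape(-1, c).T, g2, out=dW[s * c:(s + 1) * c])
        self.dW = dW
        self.db = g2.sum(axis=0)
        dxp = self._buf("dxp", (n, h + 2, w + 2, c))
        dxp[:] = 0.0
        dcols = self._buf("dcols", (n, h, w, c))
        for s, (di, dj) in enumerate(_SHIFTS3):
            np.dot(g2, self.W[s * c:(s + 1) * c].T,
                   out=dcols.reshape(-1, c))
            dxp[:, di:di + h, dj:dj + w, :] += dcols
        return dxp[:, 1:-1, 1:-1, :].copy()

    def params(self):
        return [(self, "W", "dW"), (self, "b", "db")]


class GroupNorm:
    """Group normalization over channel groups (statistics per sample, so
    behavior is identical in training and inference and independent of the
    batch size), with learnable per-channel gain and bias."""

    def __init__(self, channels: int, groups: int = 8) -> None:
        self.channels = channels
        self.groups = min(groups, channels)
        while channels % self.groups:
            self.groups -= 1
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.eps = 1e-5

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        g = self.groups
        cg = c // g
        xg = x.reshape(n, h * w, g, cg)
        m = h * w * cg
        s1 = np.einsum("nsgc->ng", xg, optimize=True)
        s2 = np.einsum("nsgc,nsgc->ng", xg, xg, optimize=True)
        mu = s1 / m
        var = np.maximum(s2 / m - mu * mu, 0.0)
        inv = 1.0 / np.sqrt(var + self.eps)
        # normalization + affine fused into one per-channel affine map
        a = np.repeat(inv, cg, axis=1).astype(np.float32)        # (n, c)
        b = (-np.repeat(mu * inv, cg, axis=1)).astype(np.float32)
        if train:
            self._x, self._a, self._b, self._m = x, a, b, m
        return x * (a * self.gamma)[:, None, None, :] \
            + (b * self.gamma + self.beta)[:, None, None, :]

    def backward(self, gr: np.ndarray) -> np.ndarray:
        n, h, w, c = gr.shape
        g = self.groups
        cg = c // g
        x, a, b, m = self._x, self._a, self._b, self._m
        self._x = None
        # all statistics derive from two per-(n, c) reductions
        r1 = np.einsum("nhwc,nhwc->nc", gr, x, optimize=True)   # sum gr*x
        r2 = np.einsum("nhwc->nc", gr, optimize=True)           # sum gr
        xhat_r1 = r1 * a + r2 * b          # per-(n, c) sum of gr * xhat
        self.dgamma = xhat_r1.sum(axis=0)
        self.dbeta = r2.sum(axis=0)
        sum_gy = (self.gamma * r2).reshape(n, g, cg).sum(axis=2)
        sum_gyxh = (self.gamma * xhat_r1).reshape(n, g, cg).sum(axis=2)
        inv = a  # per-channel copy of 1/sigma
        P = (-inv * a * np.repeat(sum_gyxh, cg, axis=1) / m).astype(np.float32)
        Q = (inv * self.gamma).astype(np.float32)
        R = (-inv * (np.repeat(sum_gy, cg, axis=1)
                     + b * np.repeat(sum_gyxh, cg, axis=1)) / m).astype(np.float32)
        return (x * P[:, None, None, :] + gr * Q[:, None, None, :]
                + R[:, None, None, :])

    def params(self):
        return [(self, "gamma", "dgamma"), (self, "beta", "dbeta")]


class ReLU:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        self._mask = x > 0 if train else None
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        out = g * self._mask
        self._mask = None
        return out

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling, stride 2; the gradient routes to the argmax element
    (first occurrence on ties)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        win = (x.reshape(n, h // 2, 2, w // 2, 2, c)
               .transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4))
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._inshape = idx, x.shape
        return np.ascontiguousarray(out)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, h, w, c = self._inshape
        flat = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(flat, self._idx[..., None], g[..., None], axis=-1)
        self._idx = None
        return np.ascontiguousarray(
            flat.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3).reshape(n, h, w, c))

    def params(self):
        return []


class Upsample2:
    """Direct twofold upsampling (nearest neighbor by default, bilinear as a
    configuration option)."""

    def __init__(self, mode: str = "nearest") -> None:
        if mode not in ("nearest", "bilinear"):
            raise ValueError("mode must be 'nearest' or 'bilinear'")
        self.mode = mode

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        up = np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)
        if self.mode == "bilinear":
            # half-pixel-aligned smoothing of the nearest-neighbor expansion
            up = (up + np.roll(up, 1, axis=1) + np.roll(up, 1, axis=2)
                  + np.roll(np.roll(up, 1, axis=1), 1, axis=2)) / 4.0
        return up

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.mode == "bilinear":
            g = (g + np.roll(g, -1, axis=1) + np.roll(g, -1, axis=2)
                 + np.roll(np.roll(g, -1, axis=1), -1, axis=2)) / 4.0
        n, h, w, c = g.shape
        return g.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))

    def params(self):
        return []
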