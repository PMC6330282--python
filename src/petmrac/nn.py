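"""Minimal NumPy neural-network framework for 3D encoder-decoder nets.

Implements exactly the pieces the pseudo-CT U-net needs — 3D convolution
(stride 1 and 2, 'same' padding), batch normalization, ReLU, inverted
dropout, 2x transposed convolution, He-normal initialization and Adam —
with hand-written backpropagation.  Tensors are laid out (N, C, D, H, W),
float32 end to end.

Convolutions are lowered to an im2col matrix and a single BLAS GEMM per
layer; the adjoint scatters the GEMM result back through the same offsets
(col2im), so strided convolutions and their gradients share one code path.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Conv3d", "BatchNorm3d", "ReLU", "Dropout", "ConvTranspose3d",
           "Adam", "mse_loss", "he_normal"]

F32 = np.float32


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, kernel k in {1, 3}, stride in {1, 2}, 'same' padding.

    Evaluated as one (cout, cin) GEMM per kernel offset against a shifted
    view of the padded input, which keeps the working set small and routes
    the arithmetic through BLAS.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if k not in (1, 3):
            raise ValueError("kernel size must be 1 or 3")
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        rng = rng or np.random.default_rng()
        self.params["W"] = he_normal(rng, (cout, cin, k, k, k), cin * k ** 3)
        self.params["b"] = np.zeros(cout, dtype=F32)
        self._xp = None

    def _pad(self, x):
        p = self.k // 2
        if p == 0:
            return x
        return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))

    def _offsets(self, spatial):
        d, h, w = spatial
        s = self.stride
        for di in range(self.k):
            for dj in range(self.k):
                for dk in range(self.k):
                    yield (di, dj, dk), (slice(di, di + d, s),
                                         slice(dj, dj + h, s),
                                         slice(dk, dk + w, s))

    def forward(self, x, train: bool = True):
        if self.stride == 2 and any(s % 2 for s in x.shape[2:]):
            raise ValueError(f"spatial dims {x.shape[2:]} not divisible by 2")
        xp = self._pad(x)
        n = x.shape[0]
        out_sp = tuple(s // self.stride for s in x.shape[2:])
        m = n * int(np.prod(out_sp))
        # im2col: one row per (channel, kernel offset), then a single GEMM
        cols = np.empty((self.cin * self.k ** 3, m), dtype=F32)
        i = 0
        for c in range(self.cin):
            for _, sl in self._offsets(x.shape[2:]):
                cols[i] = xp[:, c, sl[0], sl[1], sl[2]].reshape(-1)
                i += 1
        self._cols = cols
        self._xshape = x.shape
        w_mat = self.params["W"].reshape(self.cout, -1)
        y = (w_mat @ cols).reshape(self.cout, n, *out_sp).transpose(1, 0, 2, 3, 4)
        return (y + self.params["b"][None, :, None, None, None]).astype(F32)

    def backward(self, dy):
        n, _, *out_sp = dy.shape
        dy_mat = np.ascontiguousarray(dy.transpose(1, 0, 2, 3, 4)).reshape(
            self.cout, -1)
        self.grads["W"] = (dy_mat @ self._cols.T).reshape(self.params["W"].shape)
        self.grads["b"] = dy.sum(axis=(0, 2, 3, 4)).astype(F32)
        dcols = self.params["W"].reshape(self.cout, -1).T @ dy_mat
        p = self.k // 2
        pad_sp = tuple(s + 2 * p for s in self._xshape[2:])
        dxp = np.zeros((n, self.cin) + pad_sp, dtype=F32)
        i = 0
        for c in range(self.cin):
            for _, sl in self._offsets(self._xshape[2:]):
                dxp[:, c, sl[0], sl[1], sl[2]] += dcols[i].reshape(
                    (n,) + tuple(out_sp))
                i += 1
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        return np.ascontiguousarray(dxp)


class BatchNorm3d(Layer):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(c, dtype=F32)
        self.params["beta"] = np.zeros(c, dtype=F32)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self._cache = None

    def forward(self, x, train: bool = True):
        g = self.params["gamma"][None, :, None, None, None]
        b = self.params["beta"][None, :, None, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3, 4))
            var = x.var(axis=(0, 2, 3, 4))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(F32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * ivar[None, :, None, None, None]
        self._cache = (xhat.astype(F32), ivar.astype(F32))
        return (g * xhat + b).astype(F32)

    def backward(self, dy):
        xhat, ivar = self._cache
        g = self.params["gamma"]
        axes = (0, 2, 3, 4)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        dbeta = dy.sum(axis=axes)
        dgamma = (dy * xhat).sum(axis=axes)
        self.grads["gamma"] = dgamma.astype(F32)
        self.grads["beta"] = dbeta.astype(F32)
        gi = (g * ivar)[None, :, None, None, None]
        dx = gi / m * (m * dy
                       - dbeta[None, :, None, None, None]
                       - xhat * dgamma[None, :, None, None, None])
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train: bool = True):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(F32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0).astype(F32)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout fraction must be in [0, 1)")
        self.p, self.rng = p, rng
        self._mask = None

    def forward(self, x, train: bool = True):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(F32)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(F32)


class ConvTranspose3d(Layer):
    """2x upsampling transposed convolution (kernel 2, stride 2)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.cin, self.cout = cin, cout
        rng = rng or np.random.default_rng()
        self.params["W"] = he_normal(rng, (cin, cout, 2, 2, 2), cin)
        self.params["b"] = np.zeros(cout, dtype=F32)
        self._x = None

    def forward(self, x, train: bool = True):
        self._x = x
        n, c, d, h, w = x.shape
        tmp = np.einsum("ncdhw,coijk->nodihjwk", x, self.params["W"],
                        optimize=True)
        y = tmp.reshape(n, self.cout, 2 * d, 2 * h, 2 * w)
        return (y + self.params["b"][None, :, None, None, None]).astype(F32)

    def backward(self, dy):
        x = self._x
        n, c, d, h, w = x.shape
        dyb = dy.reshape(n, self.cout, d, 2, h, 2, w, 2)
        self.grads["W"] = np.einsum("ncdhw,nodihjwk->coijk", x, dyb,
                                    optimize=True).astype(F32)
        self.grads["b"] = dy.sum(axis=(0, 2, 3, 4)).astype(F32)
        dx = np.einsum("nodihjwk,coijk->ncdhw", dyb, self.params["W"],
                       optimize=True)
        return dx.astype(F32)


class Adam:
    def __init__(self, layers, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mhat = self.m[i][k] / b1t
                vhat = self.v[i][k] / b2t
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient w.r.t. pred."""
    diff = (pred - target).astype(np.float64)
    loss = float(np.mean(diff * diff))
    grad = (2.0 * diff / diff.size).astype(F32)
    return loss, grad
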