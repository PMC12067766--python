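"""Minimal CPU neural-network layers with explicit backpropagation.

Everything the segmentation network needs, in plain numpy: 3×3 same-padding
convolutions via im2col (both passes are single BLAS matmuls), ReLU, 2×2 max
pooling, 2× nearest-neighbour upsampling, a numerically stable binary
cross-entropy on logits, and Adam. Layers cache what their backward pass
needs on ``forward(..., train=True)``; parameters and gradients are plain
float32 arrays so checkpoints are ``np.savez`` files.

Activations use a channels-first-over-batch layout ``(C, N, H, W)``: with
channels outermost, the im2col patch matrix ``(C*9, N*H*W)`` is built from
nine contiguous slice copies and every reshape around the GEMMs is free,
which is what keeps single-core training practical.

All randomness flows through ``numpy.random.Generator`` instances supplied
by the caller, so initialisation and training are reproducible on a fixed
seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d", "ReLU", "MaxPool2", "UpsampleNearest2", "Adam",
    "bce_with_logits", "sigmoid",
]

_OFFSETS = [(di, dj) for di in range(3) for dj in range(3)]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(C, N, H, W) -> (C*9, N*H*W) patch matrix for 3x3 same-pad convolution."""
    c, n, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((c, 9, n, h, w), dtype=np.float32)
    for k, (di, dj) in enumerate(_OFFSETS):
        cols[:, k] = xp[:, :, di:di + h, dj:dj + w]
    return cols.reshape(c * 9, n * h * w)


class Conv2d:
    """3×3 (or 1×1) convolution, stride 1, same padding, He-initialised.

    ``needs_input_grad=False`` skips the (expensive) data-gradient GEMM in
    backward — used for the network's first layer, whose input is data.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, needs_input_grad: bool = True) -> None:
        if kernel not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.needs_input_grad = needs_input_grad
        fan_in = c_in * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, std, size=(c_out, fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c, n, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        cols = x.reshape(c, n * h * w) if self.kernel == 1 else _im2col3(x)
        y = self.W @ cols + self.b[:, None]
        if train:
            self._cache = (cols, x.shape)
        return y.reshape(self.c_out, n, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        cols, xshape = self._cache
        c, n, h, w = xshape
        dyf = dy.reshape(self.c_out, n * h * w)
        self.dW += dyf @ cols.T
        self.db += dyf.sum(axis=1)
        if not self.needs_input_grad:
            return None
        if self.kernel == 1:
            return (self.W.T @ dyf).reshape(c, n, h, w)
        # dx = conv(dy, W rotated 180° with in/out channels swapped)
        w4 = self.W.reshape(self.c_out, self.c_in, 3, 3)
        w_rot = np.ascontiguousarray(
            w4[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        ).reshape(self.c_in, self.c_out * 9)
        return (w_rot @ _im2col3(dy)).reshape(c, n, h, w)


class BatchNorm2d:
    """Per-channel batch normalisation with running statistics.

    Training normalises by the batch moments over (N, H, W) and updates the
    running mean/variance (momentum 0.1); inference uses the running
    statistics. Stabilises optimisation enough that the segmentation head
    converges within the short training schedules used here, and makes the
    network's response scale-free in the raw intensity units of the input.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean,
                "running_var": self.running_var}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        sh = (-1, 1, 1, 1)
        if train:
            mu = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu.reshape(sh)) * inv.reshape(sh)
            self._cache = (xhat, inv)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean.reshape(sh)) * inv.reshape(sh)
        return (self.gamma.reshape(sh) * xhat
                + self.beta.reshape(sh)).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        sh = (-1, 1, 1, 1)
        m = dy[0].size  # N*H*W per channel
        self.dgamma += (dy * xhat).sum(axis=(1, 2, 3))
        self.dbeta += dy.sum(axis=(1, 2, 3))
        dxhat = dy * self.gamma.reshape(sh)
        dx = (dxhat - dxhat.mean(axis=(1, 2, 3)).reshape(sh)
              - xhat * (dxhat * xhat).mean(axis=(1, 2, 3)).reshape(sh))
        return (dx * inv.reshape(sh)).astype(np.float32)


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """2×2 max pooling, stride 2. Gradient is split evenly among ties."""

    def __init__(self) -> None:
        self._cache: tuple | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c, n, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even, got {h}x{w}")
        r = x.reshape(c, n, h // 2, 2, w // 2, 2)
        y = r.max(axis=(3, 5))
        if train:
            winners = r == y[:, :, :, None, :, None]
            counts = winners.sum(axis=(3, 5), keepdims=True)
            self._cache = (winners, counts, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        winners, counts, xshape = self._cache
        g = dy[:, :, :, None, :, None] * winners / counts
        return g.reshape(xshape).astype(np.float32)


class UpsampleNearest2:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, n, h, w = dy.shape
        return dy.reshape(c, n, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def bce_with_logits(logits: np.ndarray, targets: np.ndarray,
                    ) -> tuple[float, np.ndarray]:
    """Mean per-pixel binary cross-entropy on raw logits.

    Returns ``(loss, dloss/dlogits)``. Stable form:
    ``max(z,0) − z·y + log(1 + exp(−|z|))``; the gradient is
    ``(σ(z) − y) / n_elements``.
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - y) / z.size
    return float(loss.mean()), grad.astype(np.float32)


class Adam:
    """Adam over a list of ``(param, grad)`` array pairs (updated in place)."""

    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * (g * g)
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[:] = 0
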