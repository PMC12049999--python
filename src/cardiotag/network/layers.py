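"""Minimal trainable 3D convolutional layers in numpy.

Channels-last layout throughout: activations are ``(B, D, H, W, C)``
float32 arrays. 3x3x3 convolutions run through numba-jitted direct
stencil kernels when numba is importable (the default environment), and
fall back to an im2col + BLAS matmul formulation otherwise; both routes
compute identical results and exact analytic gradients. The scope is
deliberately small: exactly the operations a 3D UNet needs
(same-padding conv, ReLU, 2x max-pool, 2x nearest-neighbour
upsampling) plus an Adam optimizer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = ["Param", "Conv3d", "ReLU", "MaxPool3d", "Upsample3d", "Adam"]

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


# -- im2col fallback path ------------------------------------------------


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, D, H, W, C) -> (B*D*H*W, 27*C) patch matrix for a 3^3 window.

    Feature order is offset-major, channel-minor.
    """
    B, D, H, W, C = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
    sb, sd, sh, sw, sc = xp.strides
    view = as_strided(
        xp,
        shape=(B, D, H, W, 3, 3, 3, C),
        strides=(sb, sd, sh, sw, sd, sh, sw, sc),
        writeable=False,
    )
    return np.ascontiguousarray(view).reshape(B * D * H * W, 27 * C)


# -- numba direct kernels ------------------------------------------------

if _HAVE_NUMBA:

    @numba.njit(fastmath=True, cache=True)
    def _nb_conv3d(xp, W2, b):  # pragma: no cover - jitted
        """Direct stencil conv. xp padded (B, D+2, H+2, W+2, C);
        W2 (3, 3, 3*C, Co) with the k and c axes fused (contiguous)."""
        B, Dp, Hp, Wp, C = xp.shape
        D, H, Wd = Dp - 2, Hp - 2, Wp - 2
        Co = W2.shape[3]
        KC = 3 * C
        out = np.empty((B, D, H, Wd, Co), dtype=np.float32)
        row = np.empty((Wd, Co), dtype=np.float32)
        for bb in range(B):
            for d in range(D):
                for h in range(H):
                    for w in range(Wd):
                        for co in range(Co):
                            row[w, co] = b[co]
                    for i in range(3):
                        for j in range(3):
                            xr = xp[bb, d + i, h + j].reshape(Wp * C)
                            for w in range(Wd):
                                base = w * C
                                for t in range(KC):
                                    v = xr[base + t]
                                    for co in range(Co):
                                        row[w, co] += v * W2[i, j, t, co]
                    out[bb, d, h] = row
        return out

    @numba.njit(fastmath=True, cache=True)
    def _nb_conv3d_wgrad(xp, g):  # pragma: no cover - jitted
        """d loss / d W2 given the cached padded input and output grad."""
        B, Dp, Hp, Wp, C = xp.shape
        D, H, Wd = Dp - 2, Hp - 2, Wp - 2
        Co = g.shape[4]
        KC = 3 * C
        gW = np.zeros((3, 3, KC, Co), dtype=np.float32)
        for bb in range(B):
            for d in range(D):
                for h in range(H):
                    for i in range(3):
                        for j in range(3):
                            xr = xp[bb, d + i, h + j].reshape(Wp * C)
                            for w in range(Wd):
                                base = w * C
                                for t in range(KC):
                                    v = xr[base + t]
                                    if v != 0.0:
                                        for co in range(Co):
                                            gW[i, j, t, co] += v * g[bb, d, h, w, co]
        return gW


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0.0


class Conv3d:
    """Same-padding 3D convolution, kernel size 1 or 3.

    Weights are stored as a (27*c_in, c_out) matrix in offset-major,
    channel-minor row order (for k=3), shared by both execution paths.
    """

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        if ksize not in (1, 3):
            raise ValueError("kernel size must be 1 or 3")
        self.c_in, self.c_out, self.ksize = c_in, c_out, ksize
        fan_in = c_in * ksize**3
        std = np.sqrt(2.0 / fan_in)  # He initialization for ReLU stacks
        self.W = Param(rng.normal(0.0, std, (fan_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def _flipped_weights(self) -> np.ndarray:
        """(27*c_out, c_in) correlation kernel for the input gradient."""
        Wk = self.W.value.reshape(3, 3, 3, self.c_in, self.c_out)
        Wf = Wk[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3)
        return np.ascontiguousarray(Wf).reshape(27 * self.c_out, self.c_in)

    # -- forward ---------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, D, H, W, C = x.shape
        if self.ksize == 1:
            out = x.reshape(-1, C) @ self.W.value + self.b.value
            if train:
                self._cache = ("k1", x)
            return out.reshape(B, D, H, W, self.c_out)
        if _HAVE_NUMBA:
            xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
            out = _nb_conv3d(
                xp, self.W.value.reshape(3, 3, 3 * C, self.c_out), self.b.value
            )
            if train:
                self._cache = ("nb", xp)
            return out
        cols = _im2col(x)
        out = cols @ self.W.value + self.b.value
        if train:
            self._cache = ("im2col", cols, x.shape)
        return out.reshape(B, D, H, W, self.c_out)

    # -- backward --------------------------------------------------------

    def backward(self, g: np.ndarray, need_input_grad: bool = True):
        cache = self._cache
        self._cache = None
        g = np.ascontiguousarray(g, dtype=np.float32)
        if cache[0] == "k1":
            x = cache[1]
            gf = g.reshape(-1, self.c_out)
            self.W.grad += x.reshape(-1, self.c_in).T @ gf
            self.b.grad += gf.sum(axis=0)
            return (gf @ self.W.value.T).reshape(x.shape) if need_input_grad else None
        if cache[0] == "nb":
            xp = cache[1]
            self.W.grad += _nb_conv3d_wgrad(xp, g).reshape(27 * self.c_in, self.c_out)
            self.b.grad += g.reshape(-1, self.c_out).sum(axis=0)
            if not need_input_grad:
                return None
            gp = np.pad(g, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
            Wf = self._flipped_weights().reshape(3, 3, 3 * self.c_out, self.c_in)
            return _nb_conv3d(gp, Wf, np.zeros(self.c_in, dtype=np.float32))
        _, cols, xshape = cache
        gf = g.reshape(-1, self.c_out)
        self.W.grad += cols.T @ gf
        self.b.grad += gf.sum(axis=0)
        if not need_input_grad:
            return None
        gcols = _im2col(gf.reshape(g.shape))
        return (gcols @ self._flipped_weights()).reshape(xshape)


class ReLU:
    params: list = []

    def __init__(self):
        self._mask = None

    def forward(self, x, train: bool = True):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, g):
        g = g * self._mask
        self._mask = None
        return g


class MaxPool3d:
    """2x2x2 max pooling (spatial dims must be even)."""

    params: list = []

    def __init__(self):
        self._cache = None

    def forward(self, x, train: bool = True):
        B, D, H, W, C = x.shape
        xr = x.reshape(B, D // 2, 2, H // 2, 2, W // 2, 2, C)
        out = xr.max(axis=(2, 4, 6))
        if train:
            self._cache = (xr, out, x.shape)
        return out

    def backward(self, g):
        xr, out, xshape = self._cache
        mask = xr == out[:, :, None, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4, 6), keepdims=True)
        gr = mask * (g[:, :, None, :, None, :, None, :] / counts)
        self._cache = None
        return gr.reshape(xshape).astype(np.float32)


class Upsample3d:
    """2x nearest-neighbour upsampling."""

    params: list = []

    def forward(self, x, train: bool = True):
        return np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)

    def backward(self, g):
        B, D, H, W, C = g.shape
        gr = g.reshape(B, D // 2, 2, H // 2, 2, W // 2, 2, C)
        return gr.sum(axis=(2, 4, 6))


class Adam:
    """Adam with bias correction over a fixed parameter list."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
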