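"""3D UNet for displacement regression.

Encoder-decoder with skip connections: each resolution level applies two
3x3x3 convolutions with ReLU; the channel count starts at ``base_channels``
and doubles at every down-sampling step. The decoder mirrors the encoder
with nearest-neighbour upsampling followed by a channel-halving
convolution and concatenation of the skip tensor. The input is the
two-channel concatenation of the ED tag image with the image at another
cardiac phase; the output has two channels for the short-axis network
(in-plane x, y displacements, mm) or one channel for the long-axis
network (z displacement, mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError
from .layers import Adam, Conv3d, MaxPool3d, ReLU, Upsample3d

__all__ = ["NetworkSpec", "UNet3D", "build_network", "masked_mse"]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description.

    ``base_channels`` is the reference channel count N (64 in the
    full-scale configuration; 8 or 16 in scaled-down presets); ``depth``
    the number of down-sampling steps. ``out_channels`` is 2 for the
    short-axis network (x, y) and 1 for the long-axis network (z).
    """

    base_channels: int = 64
    depth: int = 4
    in_channels: int = 2
    out_channels: int = 2

    def __post_init__(self):
        if self.base_channels < 1:
            raise ConfigurationError("base_channels must be >= 1")
        if self.out_channels not in (1, 2):
            raise ConfigurationError("out_channels must be 1 or 2")
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")

    @property
    def target_channels(self) -> tuple:
        """Displacement components this network predicts: (x, y) or (z,)."""
        return (0, 1) if self.out_channels == 2 else (2,)


class _Block:
    """conv-ReLU-conv-ReLU."""

    def __init__(self, c_in, c_out, rng):
        self.layers = [
            Conv3d(c_in, c_out, 3, rng),
            ReLU(),
            Conv3d(c_out, c_out, 3, rng),
            ReLU(),
        ]

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class UNet3D:
    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        N = spec.base_channels
        self.enc = []
        c = spec.in_channels
        for lev in range(spec.depth):
            self.enc.append(_Block(c, N * 2**lev, rng))
            c = N * 2**lev
        self.bottleneck = _Block(c, N * 2**spec.depth, rng)
        self.upconvs = []
        self.dec = []
        for lev in reversed(range(spec.depth)):
            ch = N * 2**lev
            self.upconvs.append(Conv3d(ch * 2, ch, 3, rng))
            self.dec.append(_Block(ch * 2, ch, rng))
        self.out_conv = Conv3d(N, spec.out_channels, 1, rng)
        self._pools = None

    @property
    def params(self):
        out = []
        for b in self.enc:
            out += b.params
        out += self.bottleneck.params
        for c, b in zip(self.upconvs, self.dec):
            out += c.params + b.params
        out += self.out_conv.params
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params))

    def _check_input(self, x):
        if x.ndim != 5 or x.shape[-1] != self.spec.in_channels:
            raise ConfigurationError(
                f"expected (B, D, H, W, {self.spec.in_channels}) input, got {x.shape}"
            )
        side = min(x.shape[1:4])
        if side // 2**self.spec.depth < 1 or side % 2**self.spec.depth:
            raise ConfigurationError(
                f"spatial size {x.shape[1:4]} incompatible with depth {self.spec.depth}"
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(B, D, H, W, in) -> (B, D, H, W, out); spatial size preserved."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._check_input(x)
        skips = []
        pools = []
        for b in self.enc:
            x = b.forward(x, train)
            skips.append(x)
            p = MaxPool3d()
            x = p.forward(x, train)
            pools.append(p)
        x = self.bottleneck.forward(x, train)
        ups = []
        for conv, block, skip in zip(self.upconvs, self.dec, reversed(skips)):
            u = Upsample3d()
            x = u.forward(x, train)
            x = conv.forward(x, train)
            x = np.concatenate([skip, x], axis=-1)
            x = block.forward(x, train)
            ups.append(u)
        if train:
            self._pools, self._ups = pools, ups
        return self.out_conv.forward(x, train)

    def backward(self, g: np.ndarray):
        g = self.out_conv.backward(np.ascontiguousarray(g, dtype=np.float32))
        g_skips = []
        for conv, block, u in zip(
            reversed(self.upconvs), reversed(self.dec), reversed(self._ups)
        ):
            g = block.backward(g)
            ch = g.shape[-1] // 2
            g_skips.append(g[..., :ch])
            g = conv.backward(g[..., ch:])
            g = u.backward(g)
        g = self.bottleneck.backward(g)
        # g_skips were collected shallowest-level first; encoder backward
        # runs deepest-level first
        for b, p, gs in zip(reversed(self.enc), reversed(self._pools), reversed(g_skips)):
            g = p.backward(g)
            g = b.backward(g + gs)
        self._pools = self._ups = None
        return g

    # -- weight (de)serialization ---------------------------------------

    def get_weights(self):
        return [p.value.copy() for p in self.params]

    def set_weights(self, weights):
        params = self.params
        if len(weights) != len(params):
            raise ConfigurationError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ConfigurationError("weight shape mismatch")
            p.value = np.ascontiguousarray(w, dtype=np.float32)

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.params, lr=lr)


def build_network(spec: NetworkSpec, seed: int = 0, patch_size: int | None = None) -> UNet3D:
    """Instantiate a UNet; validates that ``patch_size`` survives the
    down-sampling chain when given."""
    if patch_size is not None and (
        patch_size % 2**spec.depth or patch_size // 2**spec.depth < 1
    ):
        raise ConfigurationError(
            f"patch size {patch_size} incompatible with depth {spec.depth}"
        )
    return UNet3D(spec, seed)


def masked_mse(pred: np.ndarray, target: np.ndarray, mask: np.ndarray):
    """Mean squared error over myocardial voxels only.

    ``mask`` is (B, D, H, W) boolean; the mean runs over masked voxels
    and output channels. Returns (loss, dloss/dpred). Target values
    outside the mask never contribute.
    """
    m = mask[..., None].astype(np.float32)
    n = float(m.sum() * pred.shape[-1])
    if n == 0:
        raise ValueError("empty myocardium mask in loss")
    diff = (pred - target) * m
    loss = float(np.sum(diff**2) / n)
    return loss, (2.0 / n) * diff
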