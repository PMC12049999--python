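"""Training loop: Adam on myocardium-masked MSE with LR-halving schedule.

The schedule follows the tagged-MR displacement-regression recipe:
25 epochs of Adam at an initial learning rate of 1e-4 and batch size 32,
with the learning rate halved (at most three times) whenever the
validation loss worsens relative to the best epoch seen so far; the
weights of the best-validation epoch are the ones kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import ConfigurationError
from .unet import NetworkSpec, UNet3D, build_network, masked_mse

__all__ = ["TrainConfig", "train", "evaluate_loss"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 25
    batch_size: int = 32
    initial_lr: float = 1e-4
    max_lr_halvings: int = 3
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size) < 1 or self.initial_lr <= 0:
            raise ConfigurationError("epochs, batch_size, initial_lr must be positive")
        if self.max_lr_halvings < 0 or self.max_lr_halvings > 3:
            raise ConfigurationError("max_lr_halvings must be in [0, 3]")


def _batch(samples, idx, channels):
    imgs = np.stack([samples[i].image for i in idx]).astype(np.float32)
    tgts = np.stack([samples[i].target[..., channels] for i in idx]).astype(np.float32)
    masks = np.stack([samples[i].mask for i in idx])
    return imgs, tgts, masks


def evaluate_loss(net: UNet3D, samples, batch_size: int = 32) -> float:
    """Masked-MSE over a sample set, weighted by per-batch mask size."""
    channels = list(net.spec.target_channels)
    total, weight = 0.0, 0.0
    for start in range(0, len(samples), batch_size):
        idx = range(start, min(start + batch_size, len(samples)))
        imgs, tgts, masks = _batch(samples, idx, channels)
        pred = net.forward(imgs, train=False)
        loss, _ = masked_mse(pred, tgts, masks)
        w = float(masks.sum())
        total += loss * w
        weight += w
    return total / weight


def train(
    train_samples,
    val_samples,
    spec: NetworkSpec,
    config: TrainConfig,
    net: UNet3D | None = None,
):
    """Train a displacement network; returns (net, history).

    ``net`` holds the best-validation weights on return; ``history`` is
    a per-epoch DataFrame (train loss, validation loss, learning rate).
    Fully deterministic for a fixed config seed.
    """
    if not len(train_samples):
        raise ConfigurationError("empty training set")
    if not len(val_samples):
        raise ConfigurationError("empty validation set")
    rng = np.random.default_rng(config.seed)
    if net is None:
        net = build_network(spec, seed=int(rng.integers(2**31 - 1)))
    channels = list(spec.target_channels)
    opt = net.make_optimizer(config.initial_lr)
    lr = config.initial_lr
    halvings = 0
    best_val = np.inf
    best_weights = net.get_weights()
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_samples))
        train_loss, nb = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            imgs, tgts, masks = _batch(train_samples, idx, channels)
            pred = net.forward(imgs, train=True)
            loss, grad = masked_mse(pred, tgts, masks)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {nb} "
                    f"(lr={lr:g}); aborting"
                )
            opt.zero_grad()
            net.backward(grad)
            opt.lr = lr
            opt.step()
            train_loss += loss
            nb += 1
        val_loss = evaluate_loss(net, val_samples, config.batch_size)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": train_loss / max(nb, 1),
                "val_loss": val_loss,
                "lr": lr,
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            best_weights = net.get_weights()
        elif halvings < config.max_lr_halvings:
            lr /= 2.0
            halvings += 1
    net.set_weights(best_weights)
    return net, pd.DataFrame(rows)
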