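"""Patch datasets and case-level splits for displacement training.

Training samples pair the ED tag image with the image at another
cardiac phase; the regression target is the Lagrangian displacement
field of that phase. Patches are cut on a fixed stride lattice and kept
only when at least a minimum fraction of their voxels is myocardium, so
the loss (which is masked to the myocardium) always has support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError

__all__ = [
    "SplitManifest",
    "PatchSample",
    "split_cases",
    "patch_corners",
    "extract_patches",
]


@dataclass(frozen=True)
class SplitManifest:
    """Case-level train/validation/test assignment."""

    train: tuple
    val: tuple
    test: tuple
    fractions: tuple
    seed: int

    def __post_init__(self):
        sets = [set(self.train), set(self.val), set(self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ConfigurationError("splits must be disjoint")


def split_cases(case_ids, fractions=(0.8, 0.1, 0.1), seed: int = 0) -> SplitManifest:
    """Deterministic shuffled case-level partition.

    The split is by case, never by patch, so no anatomy contributes to
    more than one split. Fractions must sum to 1; counts are rounded so
    that every split receives at least one case when possible.
    """
    ids = list(case_ids)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("split fractions must sum to 1")
    if len(ids) < 3:
        raise ConfigurationError("need at least 3 cases to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(fractions[0] * len(ids)))
    n_val = int(round(fractions[1] * len(ids)))
    n_train = min(n_train, len(ids) - 2)
    n_val = max(1, min(n_val, len(ids) - n_train - 1))
    tr = tuple(ids[i] for i in order[:n_train])
    va = tuple(ids[i] for i in order[n_train : n_train + n_val])
    te = tuple(ids[i] for i in order[n_train + n_val :])
    return SplitManifest(tr, va, te, tuple(fractions), seed)


@dataclass
class PatchSample:
    """One training patch.

    ``image`` is the 2-channel (ED, phase) intensity patch; ``target``
    the 3-component displacement patch in mm (networks select their
    component subset); ``mask`` the myocardium indicator. Provenance
    identifies the originating case, phase and lattice corner so the
    source block can be reconstructed exactly.
    """

    image: np.ndarray  # (s, s, s, 2) float32
    target: np.ndarray  # (s, s, s, 3) float32
    mask: np.ndarray  # (s, s, s) bool
    case_id: object
    phase: int
    corner: tuple


def patch_corners(shape, size: int, stride: int) -> list:
    """Lattice of fully contained patch corners, lexicographic order."""
    if any(size > n for n in shape):
        raise ConfigurationError(f"patch size {size} exceeds volume shape {shape}")
    axes = [range(0, n - size + 1, stride) for n in shape]
    return [(i, j, k) for i in axes[0] for j in axes[1] for k in axes[2]]


def extract_patches(
    ed_image: np.ndarray,
    phase_image: np.ndarray,
    field: np.ndarray,
    mask: np.ndarray,
    size: int = 64,
    stride: int = 16,
    min_myo_fraction: float = 0.10,
    case_id=None,
    phase: int = 0,
) -> list:
    """Cut patches on the stride lattice, keeping myocardium-rich ones.

    A candidate is retained iff at least ``min_myo_fraction`` of its
    voxels are myocardium. Arrays are views into the source volumes (no
    copies); ordering is lexicographic in the corner index.
    """
    shape = ed_image.shape
    if phase_image.shape != shape or mask.shape != shape or field.shape[:3] != shape:
        raise ConfigurationError("volumes must share one grid shape")
    out = []
    thresh = min_myo_fraction * size**3
    for c in patch_corners(shape, size, stride):
        sl = tuple(slice(o, o + size) for o in c)
        m = mask[sl]
        if m.sum() < thresh:
            continue
        img = np.stack([ed_image[sl], phase_image[sl]], axis=-1)
        out.append(PatchSample(img, field[sl], m, case_id, phase, c))
    return out
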