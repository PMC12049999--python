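"""Full-volume displacement inference by overlapping-patch stitching.

The short-axis network supplies the in-plane (x, y) displacement
components and the long-axis network the through-plane (z) component.
Overlapping patches are blended with a separable raised-cosine weight
window and the accumulated weights divided out, so the blend is an
exact partition of unity: a network emitting a constant field stitches
to exactly that constant.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from scipy.ndimage import map_coordinates

from ..errors import ConfigurationError
from ..grids import GridSpec
from ..motion import PhaseField
from ..tagging import normalize01
from .unet import NetworkSpec, UNet3D, build_network

__all__ = [
    "raised_cosine_window",
    "infer_field",
    "track_landmarks",
    "save_checkpoint",
    "load_checkpoint",
]


def raised_cosine_window(size: int, eps: float = 1e-3) -> np.ndarray:
    """Separable 3D Hann-type window, strictly positive."""
    t = (np.arange(size) + 0.5) / size
    w1 = 0.5 - 0.5 * np.cos(2 * np.pi * t) + eps
    return w1[:, None, None] * w1[None, :, None] * w1[None, None, :]


def _stitch_corners(n: int, size: int, stride: int) -> list:
    starts = list(range(0, max(n - size, 0) + 1, stride))
    if starts[-1] != n - size:
        starts.append(n - size)
    return starts


def _predict_volume(net: UNet3D, ed, phase, patch_size, stride, batch_size=8):
    shape = ed.shape
    if any(n < patch_size for n in shape):
        raise ConfigurationError(
            f"volume shape {shape} smaller than patch size {patch_size}"
        )
    window = raised_cosine_window(patch_size).astype(np.float32)
    c_out = net.spec.out_channels
    acc = np.zeros(shape + (c_out,), dtype=np.float64)
    wacc = np.zeros(shape, dtype=np.float64)
    corners = [
        (i, j, k)
        for i in _stitch_corners(shape[0], patch_size, stride)
        for j in _stitch_corners(shape[1], patch_size, stride)
        for k in _stitch_corners(shape[2], patch_size, stride)
    ]
    for start in range(0, len(corners), batch_size):
        chunk = corners[start : start + batch_size]
        batch = np.stack(
            [
                np.stack(
                    [
                        ed[c[0] : c[0] + patch_size, c[1] : c[1] + patch_size, c[2] : c[2] + patch_size],
                        phase[c[0] : c[0] + patch_size, c[1] : c[1] + patch_size, c[2] : c[2] + patch_size],
                    ],
                    axis=-1,
                )
                for c in chunk
            ]
        ).astype(np.float32)
        pred = net.forward(batch, train=False)
        for c, p in zip(chunk, pred):
            sl = tuple(slice(o, o + patch_size) for o in c)
            acc[sl] += p * window[..., None]
            wacc[sl] += window
    return acc / wacc[..., None]


def infer_field(
    ed_image,
    phase_image,
    sax_net: UNet3D,
    lax_net: UNet3D,
    grid: GridSpec | None = None,
    patch_size: int = 64,
    stride: int = 32,
    phase_index: int = 0,
    normalize: bool = True,
) -> PhaseField:
    """Predict the full-volume Lagrangian displacement field (mm).

    ``ed_image``/``phase_image`` may be TaggedImage objects or raw
    arrays. Intensities are min-max normalized to [0, 1] per volume
    before prediction unless ``normalize`` is False.
    """
    from ..tagging import TaggedImage

    if isinstance(ed_image, TaggedImage):
        grid = grid or ed_image.grid
        ed_image = ed_image.intensities
    if isinstance(phase_image, TaggedImage):
        phase_image = phase_image.intensities
    if grid is None:
        grid = GridSpec(shape=ed_image.shape, spacing=(1.0, 1.0, 1.0))
    if sax_net.spec.out_channels != 2 or lax_net.spec.out_channels != 1:
        raise ConfigurationError("expected a 2-channel SAX net and 1-channel LAX net")
    ed = normalize01(np.asarray(ed_image)) if normalize else np.asarray(ed_image)
    ph = normalize01(np.asarray(phase_image)) if normalize else np.asarray(phase_image)
    sax = _predict_volume(sax_net, ed, ph, patch_size, stride)
    lax = _predict_volume(lax_net, ed, ph, patch_size, stride)
    vec = np.concatenate([sax, lax], axis=-1).astype(np.float32)
    return PhaseField(grid, vec, phase_index)


def track_landmarks(landmarks: np.ndarray, fields: list) -> np.ndarray:
    """Warp ED landmark points (n, 3) mm through every phase field.

    Returns trajectories of shape (n, n_phases, 3). Landmarks outside
    the field grid are clamped to the border with a warning.
    """
    pts = np.atleast_2d(np.asarray(landmarks, dtype=float))
    grid = fields[0].grid
    idx = grid.world_to_index(pts)
    out_of_grid = np.any((idx < 0) | (idx > np.asarray(grid.shape) - 1), axis=1)
    if out_of_grid.any():
        warnings.warn(
            f"{int(out_of_grid.sum())} landmark(s) outside the field grid", stacklevel=2
        )
    coords = [idx[:, a] for a in range(3)]
    traj = np.empty((len(pts), len(fields), 3))
    for t, f in enumerate(fields):
        disp = np.stack(
            [
                map_coordinates(
                    f.vectors[..., c].astype(np.float64), coords, order=1, mode="nearest"
                )
                for c in range(3)
            ],
            axis=-1,
        )
        traj[:, t] = pts + disp
    return traj


# -- checkpointing -------------------------------------------------------


def save_checkpoint(path, net: UNet3D, acq=None, manifest: dict | None = None):
    """Single-file checkpoint: weights + architecture + acquisition tag."""
    meta = {
        "spec": {
            "base_channels": net.spec.base_channels,
            "depth": net.spec.depth,
            "in_channels": net.spec.in_channels,
            "out_channels": net.spec.out_channels,
        },
        "tag_distance_mm": None if acq is None else float(acq.tag_distance),
        "manifest": manifest or {},
    }
    arrays = {f"w{i}": w for i, w in enumerate(net.get_weights())}
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path, expected_acq=None, allow_mismatch: bool = False):
    """Load a checkpoint; refuses acquisition-mismatched weights.

    A network trained on one tag distance is not meant for images from
    another; pass ``allow_mismatch=True`` to override deliberately.
    """
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    spec = NetworkSpec(**meta["spec"])
    if expected_acq is not None and meta["tag_distance_mm"] is not None:
        if (
            abs(expected_acq.tag_distance - meta["tag_distance_mm"]) > 1e-9
            and not allow_mismatch
        ):
            raise ConfigurationError(
                f"checkpoint was trained for tag distance {meta['tag_distance_mm']} mm, "
                f"not {expected_acq.tag_distance} mm (pass allow_mismatch to override)"
            )
    net = build_network(spec, seed=0)
    weights = [data[f"w{i}"] for i in range(len([k for k in data.files if k.startswith("w")]))]
    net.set_weights(weights)
    return net, meta
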