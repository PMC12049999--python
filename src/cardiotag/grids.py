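"""Regular 3D sampling grids and their world-coordinate conventions.

All volumes in this package live on axis-aligned regular grids. The
convention, used everywhere and written into NIfTI affines, is:

* indices are 0-based,
* the world position of voxel index ``(i, j, k)`` is
  ``origin + index * spacing`` (voxel-*center* convention),
* grid axes coincide with world axes (no rotation): x and y span the
  short-axis plane, z is the left-ventricular long axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = ["GridSpec"]


def _centered_origin(shape, spacing):
    return tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned regular grid.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z). Each component must be >= 8.
    spacing : tuple of float
        Voxel spacing in mm, strictly positive.
    origin : tuple of float, optional
        World position (mm) of the center of voxel (0, 0, 0). Defaults to
        a grid centered on the world origin.
    """

    shape: tuple = (128, 128, 128)
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = None  # type: ignore[assignment]

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or len(spacing) != 3:
            raise ConfigurationError("GridSpec requires 3D shape and spacing")
        if any(n < 8 for n in shape):
            raise ConfigurationError(f"grid shape components must be >= 8, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ConfigurationError(f"grid spacing must be positive, got {spacing}")
        origin = self.origin
        if origin is None:
            origin = _centered_origin(shape, spacing)
        origin = tuple(float(o) for o in origin)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    # -- coordinate transforms -------------------------------------------

    @property
    def affine(self) -> np.ndarray:
        """4x4 index->world affine (diagonal; no rotation)."""
        A = np.eye(4)
        A[:3, :3] = np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    @property
    def extent(self):
        """(min, max) world coordinates of voxel centers per axis, mm."""
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, xyz) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def coordinate_arrays(self):
        """Per-axis 1D world-coordinate arrays (x, y, z), mm."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def meshgrid(self):
        """Dense voxel-center coordinates, three arrays of shape ``shape``."""
        x, y, z = self.coordinate_arrays()
        return np.meshgrid(x, y, z, indexing="ij")

    def contains_points(self, pts) -> np.ndarray:
        lo, hi = self.extent
        pts = np.atleast_2d(pts)
        return np.all((pts >= lo - 1e-9) & (pts <= hi + 1e-9), axis=1)
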