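"""Parametric left-ventricular anatomies and their voxelization.

The LV is modelled as a truncated thick-walled prolate ellipsoid: an
endocardial and an epicardial ellipsoid of revolution about the z (long)
axis, cut by a flat basal plane. The family is parameterized by the
equatorial endocardial radius, wall thickness, apex-to-base length and
the basal truncation fraction, and is sampled uniformly within
configurable ranges to produce randomized anatomies with exactly known
masks, surfaces and local cardiac direction frames.

Static background structures (a liver ellipsoid and a partial chest
ring) are added around the LV so that images contain non-moving tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError
from .grids import GridSpec

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_MYOCARDIUM",
    "LABEL_BLOOD",
    "LABEL_LIVER",
    "LABEL_CHEST",
    "LVGeometry",
    "LabelVolume",
    "SurfaceMesh",
    "DirectionField",
    "DEFAULT_GEOMETRY_RANGES",
    "sample_lv_geometry",
    "voxelize_lv",
    "analytic_shell_volume",
    "add_static_background",
    "local_directions",
]

LABEL_BACKGROUND = 0
LABEL_MYOCARDIUM = 1
LABEL_BLOOD = 2
LABEL_LIVER = 3
LABEL_CHEST = 4

VERTEX_ENDO = 1
VERTEX_EPI = 2
VERTEX_BASE = 3


@dataclass(frozen=True)
class LVGeometry:
    """Truncated thick-walled prolate ellipsoid LV.

    The long axis is fixed to the grid z axis; short-axis planes are x-y.
    ``long_axis_length`` is the apex-to-base distance (epicardial apex to
    basal truncation plane). The basal plane sits at
    ``center_z + base_truncation_fraction * c_epi`` where ``c_epi`` is the
    epicardial long semi-axis.
    """

    endo_radius_eq: float  # mm, equatorial endocardial radius
    wall_thickness: float  # mm
    long_axis_length: float  # mm, apex-to-base
    base_truncation_fraction: float = 0.6  # in (0, 1]
    center: tuple = (0.0, 0.0, 0.0)  # mm

    def __post_init__(self):
        if self.endo_radius_eq <= 0:
            raise ConfigurationError("endo_radius_eq must be > 0")
        if self.wall_thickness <= 0:
            raise ConfigurationError("wall_thickness must be > 0")
        if not (0 < self.base_truncation_fraction <= 1):
            raise ConfigurationError("base_truncation_fraction must be in (0, 1]")
        if self.c_endo <= 0:
            raise ConfigurationError(
                "long_axis_length too short for the given wall thickness"
            )
        if self.c_endo <= self.endo_radius_eq * 0.5:
            # keep the shape prolate-ish; extreme oblate shapes break the
            # base-truncation convention
            warnings.warn("LV geometry is strongly oblate", stacklevel=2)

    # -- derived quantities ----------------------------------------------

    @property
    def a_endo(self) -> float:
        return self.endo_radius_eq

    @property
    def a_epi(self) -> float:
        return self.endo_radius_eq + self.wall_thickness

    @property
    def c_epi(self) -> float:
        """Epicardial long semi-axis (mm)."""
        return self.long_axis_length / (1.0 + self.base_truncation_fraction)

    @property
    def c_endo(self) -> float:
        return self.c_epi - self.wall_thickness

    @property
    def base_z(self) -> float:
        """z of the basal truncation plane (mm, world)."""
        return self.center[2] + self.base_truncation_fraction * self.c_epi

    @property
    def apex_z(self) -> float:
        """z of the epicardial apex (mm, world)."""
        return self.center[2] - self.c_epi

    def endo_radius_at_z(self, z):
        """Endocardial radius of the ED ellipsoid at world height z (mm).

        Zero above/below the endocardial poles (apex cap region).
        """
        w = (np.asarray(z, dtype=float) - self.center[2]) / self.c_endo
        r2 = 1.0 - w**2
        return self.a_endo * np.sqrt(np.clip(r2, 0.0, None))

    def epi_radius_at_z(self, z):
        w = (np.asarray(z, dtype=float) - self.center[2]) / self.c_epi
        r2 = 1.0 - w**2
        return self.a_epi * np.sqrt(np.clip(r2, 0.0, None))


@dataclass
class LabelVolume:
    """Integer tissue labels on a regular grid."""

    grid: GridSpec
    labels: np.ndarray  # int16, shape == grid.shape

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.labels.shape != tuple(self.grid.shape):
            raise ConfigurationError(
                f"label array shape {self.labels.shape} != grid shape {self.grid.shape}"
            )

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.grid, self.labels.copy())


@dataclass
class SurfaceMesh:
    """Triangulated LV surface (endo + epi shells, open at the base)."""

    vertices: np.ndarray  # (n, 3) float, mm
    faces: np.ndarray  # (m, 3) int, 0-based
    vertex_labels: np.ndarray  # (n,) int: 1 endo, 2 epi, 3 base ring

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.vertex_labels = np.asarray(self.vertex_labels, dtype=np.int16)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(), self.faces.copy(), self.vertex_labels.copy()
        )


@dataclass
class DirectionField:
    """Local cardiac direction frame per myocardial voxel.

    Dense ``(shape, 3)`` arrays; vectors are valid only where ``valid`` is
    True (myocardial voxels off the long axis).
    """

    grid: GridSpec
    valid: np.ndarray  # bool, grid.shape
    radial: np.ndarray  # float32, grid.shape + (3,)
    circumferential: np.ndarray
    longitudinal: np.ndarray


DEFAULT_GEOMETRY_RANGES = {
    "endo_radius_eq": (15.0, 30.0),
    "wall_thickness": (6.0, 14.0),
    "long_axis_length": (65.0, 95.0),
    "base_truncation_fraction": (0.45, 0.7),
}


def sample_lv_geometry(seed: int, ranges: dict | None = None) -> LVGeometry:
    """Draw a random LV geometry uniformly within parameter ranges.

    Deterministic for a fixed seed. ``ranges`` maps parameter name to
    (min, max); missing entries fall back to :data:`DEFAULT_GEOMETRY_RANGES`.
    """
    table = dict(DEFAULT_GEOMETRY_RANGES)
    if ranges:
        table.update(ranges)
    for name, (lo, hi) in table.items():
        if lo > hi:
            raise ConfigurationError(f"range for {name} has min > max: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    draw = {name: rng.uniform(lo, hi) for name, (lo, hi) in sorted(table.items())}
    return LVGeometry(
        endo_radius_eq=draw["endo_radius_eq"],
        wall_thickness=draw["wall_thickness"],
        long_axis_length=draw["long_axis_length"],
        base_truncation_fraction=draw["base_truncation_fraction"],
    )


def _ellipsoid_q(x, y, z, center, a, c):
    cx, cy, cz = center
    return ((x - cx) / a) ** 2 + ((y - cy) / a) ** 2 + ((z - cz) / c) ** 2


def analytic_shell_volume(geometry: LVGeometry) -> float:
    """Exact myocardial volume (mm^3) of the truncated ellipsoid shell."""

    def trunc_vol(a, c):
        # volume of ellipsoid (a, a, c) below the basal plane
        t = np.clip((geometry.base_z - geometry.center[2]) / c, -1.0, 1.0)
        return np.pi * a**2 * c * (2.0 / 3.0 + t - t**3 / 3.0)

    return trunc_vol(geometry.a_epi, geometry.c_epi) - trunc_vol(
        geometry.a_endo, geometry.c_endo
    )


def _check_fit(geometry: LVGeometry, grid: GridSpec):
    lo, hi = grid.extent
    cx, cy, cz = geometry.center
    xlo, xhi = cx - geometry.a_epi, cx + geometry.a_epi
    ylo, yhi = cy - geometry.a_epi, cy + geometry.a_epi
    zlo, zhi = geometry.apex_z, geometry.base_z
    for axis, (qlo, qhi) in enumerate([(xlo, xhi), (ylo, yhi), (zlo, zhi)]):
        if qlo < lo[axis] or qhi > hi[axis]:
            raise DomainError(
                f"geometry extent [{qlo:.1f}, {qhi:.1f}] mm exceeds grid extent "
                f"[{lo[axis]:.1f}, {hi[axis]:.1f}] mm on axis {axis}"
            )


def voxelize_lv(geometry: LVGeometry, grid: GridSpec):
    """Voxelize an LV geometry to (LabelVolume, SurfaceMesh).

    Voxel membership is by the voxel-center inclusion test: a voxel is
    myocardium when its center lies between the endo and epi ellipsoids
    and below the basal plane, blood when inside the endo ellipsoid and
    below the basal plane.
    """
    _check_fit(geometry, grid)
    x, y, z = grid.meshgrid()
    q_endo = _ellipsoid_q(x, y, z, geometry.center, geometry.a_endo, geometry.c_endo)
    q_epi = _ellipsoid_q(x, y, z, geometry.center, geometry.a_epi, geometry.c_epi)
    below_base = z <= geometry.base_z
    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[(q_epi <= 1.0) & (q_endo >= 1.0) & below_base] = LABEL_MYOCARDIUM
    labels[(q_endo < 1.0) & below_base] = LABEL_BLOOD
    if not np.any(labels == LABEL_MYOCARDIUM):
        raise DomainError("voxelization produced an empty myocardium")
    mesh = _build_surface_mesh(geometry)
    return LabelVolume(grid, labels), mesh


def _build_surface_mesh(
    geometry: LVGeometry, n_theta: int = 48, n_phi: int = 32
) -> SurfaceMesh:
    """Triangulate the endo and epi ellipsoid caps up to the basal plane."""
    verts, faces, vlabels = [], [], []

    def add_shell(a, c, surf_label):
        base_offset = len(verts)
        cx, cy, cz = geometry.center
        # colatitude phi from the apex pole (phi=0) to the basal plane
        cos_max = np.clip((cz - geometry.base_z) / c, -1.0, 1.0)
        phi_max = float(np.arccos(cos_max))
        verts.append([cx, cy, cz - c])  # apex pole
        vlabels.append(surf_label)
        phis = np.linspace(phi_max / n_phi, phi_max, n_phi)
        thetas = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
        for i, phi in enumerate(phis):
            ring_label = VERTEX_BASE if i == len(phis) - 1 else surf_label
            for th in thetas:
                verts.append(
                    [
                        cx + a * np.sin(phi) * np.cos(th),
                        cy + a * np.sin(phi) * np.sin(th),
                        cz - c * np.cos(phi),
                    ]
                )
                vlabels.append(ring_label)
        ring = lambda i: base_offset + 1 + i * n_theta  # noqa: E731
        for j in range(n_theta):  # apex fan
            faces.append([base_offset, ring(0) + j, ring(0) + (j + 1) % n_theta])
        for i in range(n_phi - 1):
            for j in range(n_theta):
                a0, a1 = ring(i) + j, ring(i) + (j + 1) % n_theta
                b0, b1 = ring(i + 1) + j, ring(i + 1) + (j + 1) % n_theta
                faces.append([a0, b0, b1])
                faces.append([a0, b1, a1])

    add_shell(geometry.a_endo, geometry.c_endo, VERTEX_ENDO)
    add_shell(geometry.a_epi, geometry.c_epi, VERTEX_EPI)
    return SurfaceMesh(np.array(verts), np.array(faces), np.array(vlabels))


def add_static_background(
    labels: LabelVolume, seed: int, max_retries: int = 100
) -> LabelVolume:
    """Add a liver ellipsoid and a partial chest ring around the LV.

    Both structures are static across the cardiac cycle. Placement is
    randomized per seed and retried until neither overlaps the
    myocardium or blood pool; sizes scale with the grid extent so that
    scaled-down simulation grids keep proportionate backgrounds.
    """
    if not set(np.unique(labels.labels)).issubset({0, 1, 2}):
        raise ConfigurationError("input labels must contain only {0, 1, 2}")
    rng = np.random.default_rng(seed)
    grid = labels.grid
    lo, hi = grid.extent
    half = (hi - lo) / 2.0
    center_world = (hi + lo) / 2.0
    scale = float(min(half[:2])) / 63.5  # 1.0 for the default 128 @ 1 mm grid
    x, y, z = grid.meshgrid()
    out = labels.labels.copy()
    from scipy.ndimage import binary_dilation

    # 2-voxel safety margin so the wall never touches static tissue even
    # after systolic thickening
    heart = binary_dilation(
        (out == LABEL_MYOCARDIUM) | (out == LABEL_BLOOD), iterations=2
    )
    heart_zlo = z[heart].min() if heart.any() else center_world[2]

    # -- liver: one ellipsoid tucked below the apex, lateral jitter
    placed = False
    for _ in range(max_retries):
        axes = rng.uniform([18, 14, 10], [30, 22, 18]) * scale
        cen = np.array(
            [
                center_world[0] + rng.uniform(-0.3, 0.3) * half[0],
                center_world[1] + rng.uniform(-0.3, 0.3) * half[1],
                heart_zlo - axes[2] * rng.uniform(0.75, 1.0),
            ]
        )
        q = (
            ((x - cen[0]) / axes[0]) ** 2
            + ((y - cen[1]) / axes[1]) ** 2
            + ((z - cen[2]) / axes[2]) ** 2
        )
        liver = q <= 1.0
        if liver.any() and not (liver & heart).any():
            out[liver & (out == LABEL_BACKGROUND)] = LABEL_LIVER
            placed = True
            break
    if not placed:
        raise ConfigurationError("could not place liver without overlap")

    # -- chest wall: partial ring (annular cylinder arc) around the torso
    placed = False
    for _ in range(max_retries):
        ring_r = rng.uniform(0.80, 0.88) * float(min(half[:2]))
        thickness = rng.uniform(5.0, 9.0) * scale
        ang0 = rng.uniform(0, 2 * np.pi)
        span = rng.uniform(np.pi * 0.8, np.pi * 1.3)
        rho = np.hypot(x - center_world[0], y - center_world[1])
        ang = np.mod(np.arctan2(y - center_world[1], x - center_world[0]) - ang0, 2 * np.pi)
        ring = (np.abs(rho - ring_r) <= thickness / 2) & (ang <= span)
        if ring.any() and not (ring & heart).any():
            out[ring & (out == LABEL_BACKGROUND)] = LABEL_CHEST
            placed = True
            break
    if not placed:
        raise ConfigurationError("could not place chest ring without overlap")
    return LabelVolume(grid, out)


def local_directions(geometry: LVGeometry, labels: LabelVolume) -> DirectionField:
    """Radial/circumferential/longitudinal unit frame per myocardial voxel.

    Longitudinal is +z; circumferential is z x (in-plane radial);
    radial = circumferential x longitudinal, pointing away from the long
    axis. Voxels on the axis (zero in-plane radius) are excluded.
    """
    grid = labels.grid
    myo = labels.mask(LABEL_MYOCARDIUM)
    if not myo.any():
        raise DomainError("empty myocardium")
    x, y, _ = grid.meshgrid()
    dx = x - geometry.center[0]
    dy = y - geometry.center[1]
    rho = np.hypot(dx, dy)
    valid = myo & (rho > 1e-9)
    n_excluded = int(myo.sum() - valid.sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} myocardial voxel(s) on the long axis excluded "
            "from the direction field",
            stacklevel=2,
        )
    shape = tuple(grid.shape)
    radial = np.zeros(shape + (3,), dtype=np.float32)
    circ = np.zeros_like(radial)
    longi = np.zeros_like(radial)
    with np.errstate(invalid="ignore", divide="ignore"):
        ex = np.where(valid, dx / rho, 0.0)
        ey = np.where(valid, dy / rho, 0.0)
    radial[..., 0] = ex
    radial[..., 1] = ey
    # circumferential = longitudinal x radial = z x r
    circ[..., 0] = -ey
    circ[..., 1] = ex
    longi[..., 2] = 1.0
    longi *= valid[..., None]
    return DirectionField(grid, valid, radial, circ, longi)
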