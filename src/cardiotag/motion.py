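"""Closed-form incompressible LV motion with analytic ground truth.

The cardiac cycle is modelled by an axisymmetric mapping in cylindrical
coordinates (r, theta, zeta) about the LV long axis, with zeta measured
*down from the basal plane* (the base is stationary, the apex moves
toward it). With activation a(t) in [0, 1], endocardial contraction c,
peak twist tau and longitudinal shortening s:

    zeta' = zeta * (1 - s a)
    theta' = theta + a tau * zeta / H
    r'^2  = (R(zeta) (1 - c a))^2 + (r^2 - R(zeta)^2) / (1 - s a)

where R(zeta) is the end-diastolic endocardial radius at that height and
H the apex-to-base length. The mapping contracts the endocardium by the
factor (1 - c a), shortens the wall longitudinally by (1 - s a), twists
linearly from base to apex, and is exactly volume preserving
(det F = 1) by construction, which makes it a closed-form stand-in for a
biomechanical simulation: displacement, deformation gradient and strain
are all available analytically, so network predictions can be scored
against exact ground truth.

The amplitudes (c, tau, s) are drawn by mapping biophysical parameter
ranges (myocardial shear-modulus scaling 0.25-10, peak active stress
0.1-1.0 MPa, diastolic filling pressure 4-25 mmHg) monotonically onto
kinematic amplitude ranges; the biophysical values are carried in the
dataset manifests as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .anatomy import (
    LABEL_BLOOD,
    LABEL_MYOCARDIUM,
    LabelVolume,
    LVGeometry,
)
from .errors import ConfigurationError, DomainError
from .grids import GridSpec

__all__ = [
    "BiophysicsMeta",
    "MotionParams",
    "PhaseField",
    "DEFAULT_AMPLITUDE_RANGES",
    "BIOPHYSICS_RANGES",
    "amplitudes_from_biophysics",
    "sample_motion_params",
    "activation",
    "forward_map",
    "inverse_map",
    "lv_displacement",
    "deformation_gradient_analytic",
    "warp_labels",
    "midline_length_ratio",
    "ground_truth_strains",
]

#: Biophysical parameter ranges carried as metadata (shear-modulus scale,
#: peak active stress in MPa, diastolic filling pressure in mmHg).
BIOPHYSICS_RANGES = {
    "shear_modulus_scale": (0.25, 10.0),
    "active_stress_mpa": (0.1, 1.0),
    "filling_pressure_mmhg": (4.0, 25.0),
}

#: Kinematic amplitude ranges the biophysical ranges are mapped onto.
DEFAULT_AMPLITUDE_RANGES = {
    "contraction": (0.05, 0.35),
    "twist_deg": (5.0, 20.0),
    "shortening": (0.05, 0.25),
}


@dataclass(frozen=True)
class BiophysicsMeta:
    shear_modulus_scale: float = 1.0
    active_stress_mpa: float = 0.5
    filling_pressure_mmhg: float = 12.0

    def as_dict(self):
        return asdict(self)


@dataclass(frozen=True)
class MotionParams:
    """Kinematic motion amplitudes and cycle timing."""

    contraction: float = 0.2  # peak fractional endocardial radius reduction
    twist_deg: float = 12.0  # peak apex-to-base twist, degrees
    shortening: float = 0.15  # peak longitudinal shortening fraction
    n_phases: int = 24
    peak_phase_fraction: float = 0.375  # systolic peak as fraction of cycle
    biophysics: BiophysicsMeta = field(default_factory=BiophysicsMeta)

    def __post_init__(self):
        if not (0 <= self.contraction < 1):
            raise ConfigurationError("contraction must be in [0, 1)")
        if not (0 <= self.shortening < 1):
            raise ConfigurationError("shortening must be in [0, 1)")
        if self.n_phases < 2:
            raise ConfigurationError("n_phases must be >= 2")
        if not (0 < self.peak_phase_fraction < 1):
            raise ConfigurationError("peak_phase_fraction must be in (0, 1)")

    @property
    def peak_phase(self) -> int:
        return int(round(self.peak_phase_fraction * self.n_phases))


@dataclass
class PhaseField:
    """Lagrangian displacement field on the ED grid, mm.

    ``vectors[i, j, k]`` is u(X) = x(t) - X for the material point at ED
    voxel center X; zero outside moving tissue. Component order (x, y, z).
    """

    grid: GridSpec
    vectors: np.ndarray  # float32, grid.shape + (3,)
    phase_index: int

    def __post_init__(self):
        self.vectors = np.ascontiguousarray(self.vectors, dtype=np.float32)
        if self.vectors.shape != tuple(self.grid.shape) + (3,):
            raise ConfigurationError("PhaseField vector array has wrong shape")


def amplitudes_from_biophysics(meta: BiophysicsMeta, rng=None) -> dict:
    """Map biophysical metadata monotonically onto (c, tau, s) amplitudes.

    Active stress and filling pressure increase, and shear modulus
    (stiffness, log-scaled) decreases, a common normalized drive in
    [0, 1]; each amplitude is then an affine function of the drive within
    :data:`DEFAULT_AMPLITUDE_RANGES`. If ``rng`` is given, a small
    per-component jitter decorrelates the three amplitudes while keeping
    the mapping monotone in each biophysical input.
    """
    lo, hi = BIOPHYSICS_RANGES["active_stress_mpa"]
    alpha = (meta.active_stress_mpa - lo) / (hi - lo)
    lo, hi = BIOPHYSICS_RANGES["filling_pressure_mmhg"]
    gamma = (meta.filling_pressure_mmhg - lo) / (hi - lo)
    lo, hi = BIOPHYSICS_RANGES["shear_modulus_scale"]
    beta = np.log(meta.shear_modulus_scale / lo) / np.log(hi / lo)
    drive = 0.15 + 0.55 * alpha + 0.25 * gamma - 0.35 * beta
    out = {}
    for name, key in [
        ("contraction", "contraction"),
        ("twist_deg", "twist_deg"),
        ("shortening", "shortening"),
    ]:
        d = drive
        if rng is not None:
            d = d + rng.normal(0.0, 0.08)
        d = float(np.clip(d, 0.0, 1.0))
        lo, hi = DEFAULT_AMPLITUDE_RANGES[key]
        out[name] = lo + (hi - lo) * d
    return out


def sample_motion_params(seed: int, n_phases: int = 24) -> MotionParams:
    """Draw motion parameters by sampling the biophysical ranges.

    Shear-modulus scale is sampled log-uniformly, active stress and
    filling pressure uniformly, then mapped to kinematic amplitudes.
    """
    rng = np.random.default_rng(seed)
    lo, hi = BIOPHYSICS_RANGES["shear_modulus_scale"]
    shear = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    stress = float(rng.uniform(*BIOPHYSICS_RANGES["active_stress_mpa"]))
    pressure = float(rng.uniform(*BIOPHYSICS_RANGES["filling_pressure_mmhg"]))
    meta = BiophysicsMeta(shear, stress, pressure)
    amp = amplitudes_from_biophysics(meta, rng)
    return MotionParams(
        contraction=amp["contraction"],
        twist_deg=amp["twist_deg"],
        shortening=amp["shortening"],
        n_phases=n_phases,
        biophysics=meta,
    )


def activation(phase: int, params: MotionParams) -> float:
    """Raised-cosine temporal envelope: 0 at ED, 1 at the systolic peak,
    back to 0 at the end of the cycle."""
    if not (0 <= phase < params.n_phases):
        raise IndexError(f"phase {phase} out of range [0, {params.n_phases})")
    pk = params.peak_phase
    if pk < 1 or pk > params.n_phases - 2:
        raise ConfigurationError("peak phase must be an interior phase")
    if phase <= pk:
        return 0.5 * (1.0 - np.cos(np.pi * phase / pk))
    return 0.5 * (1.0 + np.cos(np.pi * (phase - pk) / (params.n_phases - 1 - pk)))


def _factors(params: MotionParams, phase: int):
    a = activation(phase, params)
    g = 1.0 - params.shortening * a
    k = 1.0 - params.contraction * a
    if g <= 0 or k <= 0:
        raise ConfigurationError(
            "contraction/shortening times activation must stay below 1"
        )
    return a, g, k


def _to_cyl(geometry: LVGeometry, pts: np.ndarray):
    cx, cy, _ = geometry.center
    r = np.hypot(pts[..., 0] - cx, pts[..., 1] - cy)
    theta = np.arctan2(pts[..., 1] - cy, pts[..., 0] - cx)
    zeta = geometry.base_z - pts[..., 2]
    return r, theta, zeta


def forward_map(
    geometry: LVGeometry, params: MotionParams, phase: int, points: np.ndarray
) -> np.ndarray:
    """Map ED material points (n, 3) mm to their position at ``phase``."""
    pts = np.asarray(points, dtype=float)
    a, g, k = _factors(params, phase)
    r, theta, zeta = _to_cyl(geometry, pts)
    R = geometry.endo_radius_at_z(geometry.base_z - zeta)
    r2p = (R * k) ** 2 + (r**2 - R**2) / g
    rp = np.sqrt(np.clip(r2p, 0.0, None))
    tw = np.deg2rad(params.twist_deg) * a / geometry.long_axis_length
    thp = theta + tw * zeta
    zp = geometry.base_z - zeta * g
    cx, cy, _ = geometry.center
    out = np.empty_like(pts)
    out[..., 0] = cx + rp * np.cos(thp)
    out[..., 1] = cy + rp * np.sin(thp)
    out[..., 2] = zp
    return out


def inverse_map(
    geometry: LVGeometry, params: MotionParams, phase: int, points: np.ndarray
) -> np.ndarray:
    """Closed-form inverse: position at ``phase`` -> ED material coordinate.

    Inverted component-wise (zeta, then theta, then r). Points whose
    radial inversion is impossible (inside the contracted endocardium,
    which no wall material reaches) get NaN coordinates; callers treat
    those as non-tissue.
    """
    pts = np.asarray(points, dtype=float)
    a, g, k = _factors(params, phase)
    rp, thp, zep = _to_cyl(geometry, pts)
    zeta = zep / g
    R = geometry.endo_radius_at_z(geometry.base_z - zeta)
    tw = np.deg2rad(params.twist_deg) * a / geometry.long_axis_length
    theta = thp - tw * zeta
    r2 = (rp**2 - (R * k) ** 2) * g + R**2
    r = np.where(r2 >= 0.0, np.sqrt(np.clip(r2, 0.0, None)), np.nan)
    cx, cy, _ = geometry.center
    out = np.empty_like(pts)
    out[..., 0] = cx + r * np.cos(theta)
    out[..., 1] = cy + r * np.sin(theta)
    out[..., 2] = geometry.base_z - zeta
    return out


def lv_displacement(
    geometry: LVGeometry,
    params: MotionParams,
    phase: int,
    grid: GridSpec,
    labels: LabelVolume | None = None,
) -> PhaseField:
    """Lagrangian displacement field u(X) on the ED grid.

    Nonzero only on myocardial voxels; static tissues and background are
    zero. ``labels`` (the ED label volume) may be passed to avoid
    re-voxelizing.
    """
    from .anatomy import voxelize_lv

    if labels is None:
        labels, _ = voxelize_lv(geometry, grid)
    myo = labels.mask(LABEL_MYOCARDIUM)
    vec = np.zeros(tuple(grid.shape) + (3,), dtype=np.float32)
    if phase != 0:
        idx = np.argwhere(myo)
        X = grid.index_to_world(idx)
        x = forward_map(geometry, params, phase, X)
        vec[myo] = (x - X).astype(np.float32)
    return PhaseField(grid, vec, phase)


def deformation_gradient_analytic(
    geometry: LVGeometry, params: MotionParams, phase: int, points: np.ndarray
) -> np.ndarray:
    """Analytic deformation gradient F = dx'/dX, shape (n, 3, 3).

    Valid for material points in the wall (including the apex cap, where
    the endocardial radius is zero). Points on the long axis are a
    coordinate singularity and raise a domain error.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    a, g, k = _factors(params, phase)
    r, theta, zeta = _to_cyl(geometry, pts)
    if np.any(r < 1e-9):
        raise DomainError("deformation gradient undefined on the long axis")
    z_world = geometry.base_z - zeta
    w = (z_world - geometry.center[2]) / geometry.c_endo
    inside = np.abs(w) < 1.0
    R = geometry.endo_radius_at_z(z_world)
    # R * dR/dzeta is finite everywhere: a_endo^2 * w / c_endo inside the
    # endocardial poles, 0 in the apex cap.
    R_Rz = np.where(inside, geometry.a_endo**2 * w / geometry.c_endo, 0.0)
    r2p = (R * k) ** 2 + (r**2 - R**2) / g
    rp = np.sqrt(np.clip(r2p, 1e-18, None))
    tw = np.deg2rad(params.twist_deg) * a / geometry.long_axis_length
    thp = theta + tw * zeta

    drp_dr = r / (g * rp)
    drp_dzeta = R_Rz * (k**2 - 1.0 / g) / rp
    ct, st = np.cos(theta), np.sin(theta)
    ctp, stp = np.cos(thp), np.sin(thp)

    F = np.empty(pts.shape[:-1] + (3, 3), dtype=float)
    # in-plane block: d(x', y')/d(X, Y)
    F[..., 0, 0] = ctp * drp_dr * ct + rp * stp * st / r
    F[..., 0, 1] = ctp * drp_dr * st - rp * stp * ct / r
    F[..., 1, 0] = stp * drp_dr * ct - rp * ctp * st / r
    F[..., 1, 1] = stp * drp_dr * st + rp * ctp * ct / r
    # dzeta/dZ = -1
    F[..., 0, 2] = -(ctp * drp_dzeta - rp * stp * tw)
    F[..., 1, 2] = -(stp * drp_dzeta + rp * ctp * tw)
    F[..., 2, 0] = 0.0
    F[..., 2, 1] = 0.0
    F[..., 2, 2] = g
    return F


def warp_labels(
    labels: LabelVolume, geometry: LVGeometry, params: MotionParams, phase: int
) -> LabelVolume:
    """Warp the ED label volume to a cardiac phase.

    Moving labels are assigned through the inverse map: each voxel center
    is pulled back to its ED material coordinate and the ED label looked
    up (nearest neighbour). The blood pool is assigned from the deformed
    endocardial surface. Static tissues (liver, chest) keep their voxels;
    where the deformed wall overlaps them the wall takes precedence.
    """
    if phase == 0:
        return labels.copy()
    grid = labels.grid
    a, g, k = _factors(params, phase)
    ed = labels.labels
    out = np.where((ed == LABEL_MYOCARDIUM) | (ed == LABEL_BLOOD), 0, ed).astype(
        np.int16
    )
    x, y, z = grid.meshgrid()
    below = z <= geometry.base_z
    pts = np.stack([x[below], y[below], z[below]], axis=-1)
    X = inverse_map(geometry, params, phase, pts)

    # blood: inside the deformed endocardial surface
    zeta_mat = (geometry.base_z - pts[:, 2]) / g
    z_mat = geometry.base_z - zeta_mat
    endo_apex_z = geometry.center[2] - geometry.c_endo
    rp = np.hypot(pts[:, 0] - geometry.center[0], pts[:, 1] - geometry.center[1])
    blood = (z_mat >= endo_apex_z) & (rp < geometry.endo_radius_at_z(z_mat) * k)

    # myocardium: ED label at the material coordinate
    finite = np.all(np.isfinite(X), axis=1)
    myo = np.zeros(len(pts), dtype=bool)
    if finite.any():
        idx = np.rint(grid.world_to_index(X[finite])).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
        sel = np.where(finite)[0][ok]
        ii = idx[ok]
        myo[sel] = ed[ii[:, 0], ii[:, 1], ii[:, 2]] == LABEL_MYOCARDIUM

    flat = out[below]
    flat[blood] = LABEL_BLOOD
    flat[myo] = LABEL_MYOCARDIUM
    out[below] = flat
    return LabelVolume(grid, out)


def _wall_quadrature(geometry: LVGeometry, spacing: float = 2.0) -> np.ndarray:
    """Deterministic lattice of material points inside the ED wall."""
    pad = 1.0
    xs = np.arange(
        geometry.center[0] - geometry.a_epi + pad,
        geometry.center[0] + geometry.a_epi,
        spacing,
    )
    zs = np.arange(geometry.apex_z + pad, geometry.base_z, spacing)
    X, Y, Z = np.meshgrid(xs, xs, zs, indexing="ij")
    from .anatomy import _ellipsoid_q

    q_en = _ellipsoid_q(X, Y, Z, geometry.center, geometry.a_endo, geometry.c_endo)
    q_ep = _ellipsoid_q(X, Y, Z, geometry.center, geometry.a_epi, geometry.c_epi)
    rho = np.hypot(X - geometry.center[0], Y - geometry.center[1])
    keep = (q_ep <= 1.0) & (q_en >= 1.0) & (rho > 1.5)
    return np.stack([X[keep], Y[keep], Z[keep]], axis=-1)


def midline_length_ratio(
    geometry: LVGeometry, params: MotionParams, phase: int, n: int = 4000
) -> float:
    """Closed-form oracle for the LAX skeleton-length strain route.

    Computes the exact length ratio (deformed / ED) of the mid-wall
    contour of an LAX cut: the curve midway between endo and epi
    surfaces in the x-z plane, traced from base around the apex and
    back, mapped with the analytic forward map. This is the quantity
    the mask skeleton route estimates; it differs from the base-to-apex
    shortening -s*a because the apex arc of the curve is not aligned
    with the long axis.
    """
    cx, cy, cz = geometry.center
    # parameterize one limb by colatitude from apex pole to the basal plane
    phis_en = np.arccos(np.clip((cz - geometry.base_z) / geometry.c_endo, -1, 1))
    phis_ep = np.arccos(np.clip((cz - geometry.base_z) / geometry.c_epi, -1, 1))
    t = np.linspace(0.0, 1.0, n)
    # midpoints between matching-colatitude endo and epi points
    def shell(a, c, phimax):
        phi = t * phimax
        return np.stack(
            [cx + a * np.sin(phi), np.full(n, cy), cz - c * np.cos(phi)], axis=-1
        )
    mid = 0.5 * (
        shell(geometry.a_endo, geometry.c_endo, phis_en)
        + shell(geometry.a_epi, geometry.c_epi, phis_ep)
    )

    def curve_len(pts):
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))

    l0 = curve_len(mid)
    l1 = curve_len(forward_map(geometry, params, phase, mid))
    return l1 / l0


def ground_truth_strains(
    geometry: LVGeometry, params: MotionParams, phase: int
) -> tuple:
    """Analytic (e_r, e_c, e_l) at a cardiac phase.

    * e_l = -s a (engineering strain of the base-to-apex length),
    * e_c = r'_mw / r_mw - 1 for the material mid-wall ring at the
      equator (engineering strain of the mid-wall circumference),
    * e_r = mean radial Green-Lagrange component r^T E r over a lattice
      of wall quadrature points, with E from the analytic F.
    """
    a, g, k = _factors(params, phase)
    if a == 0.0:
        return 0.0, 0.0, 0.0
    e_l = -params.shortening * a

    r_mw = geometry.a_endo + geometry.wall_thickness / 2.0
    eq = np.array(
        [
            [
                geometry.center[0] + r_mw,
                geometry.center[1],
                geometry.center[2],
            ]
        ]
    )
    rp = np.hypot(*(forward_map(geometry, params, phase, eq)[0, :2] - np.asarray(geometry.center[:2])))
    e_c = rp / r_mw - 1.0

    pts = _wall_quadrature(geometry)
    F = deformation_gradient_analytic(geometry, params, phase, pts)
    E = 0.5 * (np.einsum("nji,njk->nik", F, F) - np.eye(3))
    rad = np.zeros_like(pts)
    rho = np.hypot(pts[:, 0] - geometry.center[0], pts[:, 1] - geometry.center[1])
    rad[:, 0] = (pts[:, 0] - geometry.center[0]) / rho
    rad[:, 1] = (pts[:, 1] - geometry.center[1]) / rho
    e_r = float(np.mean(np.einsum("ni,nij,nj->n", rad, E, rad)))
    return e_r, float(e_c), float(e_l)
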