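import warnings

import numpy as np
import pytest

from cardiotag.anatomy import LABEL_MYOCARDIUM, local_directions, voxelize_lv
from cardiotag.errors import DomainError
from cardiotag.grids import GridSpec
from cardiotag.motion import (
    MotionParams,
    PhaseField,
    ground_truth_strains,
    lv_displacement,
    midline_length_ratio,
    warp_labels,
)
from cardiotag.strain import (
    circumferential_strain,
    default_sax_slices,
    green_lagrange,
    longitudinal_strain,
    midwall_diameter,
    radial_strain,
    strain_curves,
    warp_mesh,
)


def _affine_field(grid, A):
    """u = (A - I) X on the whole grid."""
    x, y, z = grid.meshgrid()
    X = np.stack([x, y, z], axis=-1)
    u = X @ (A - np.eye(3)).T
    return PhaseField(grid, u.astype(np.float32), 1)


class TestGreenLagrange:
    def test_zero_field_zero_strain(self, voxelized):
        labels, _ = voxelized
        f = PhaseField(labels.grid, np.zeros(labels.grid.shape + (3,), np.float32), 0)
        E = green_lagrange(f, labels.mask(LABEL_MYOCARDIUM))
        assert np.abs(E.E).max() == 0.0

    @pytest.mark.parametrize(
        "A",
        [
            np.diag([1.1, 0.95, 1.02]),
            np.array([[1.0, 0.05, 0.0], [0.0, 1.0, 0.0], [0.02, 0.0, 0.97]]),
        ],
    )
    def test_affine_displacement_exact_tensor(self, voxelized, A):
        labels, _ = voxelized
        f = _affine_field(labels.grid, A)
        mask = labels.mask(LABEL_MYOCARDIUM)
        E = green_lagrange(f, mask)
        expected = 0.5 * (A.T @ A - np.eye(3))
        sel = E.valid
        err = np.abs(E.E[sel] - expected).max()
        assert err < 1e-5

    def test_matches_analytic_tensor_on_motion_field(self, geometry, motion, grid96, voxelized):
        from cardiotag.motion import deformation_gradient_analytic

        labels, _ = voxelized
        mask = labels.mask(LABEL_MYOCARDIUM)
        ph = motion.peak_phase
        f = lv_displacement(geometry, motion, ph, grid96, labels)
        E = green_lagrange(f, mask)
        # compare on interior voxels (central differences, away from the
        # one-sided boundary stencils)
        from scipy.ndimage import binary_erosion

        interior = binary_erosion(mask, iterations=2) & E.valid
        idx = np.argwhere(interior)
        pts = labels.grid.index_to_world(idx)
        rho = np.hypot(pts[:, 0], pts[:, 1])
        keep = rho > 2.0
        idx, pts = idx[keep], pts[keep]
        F = deformation_gradient_analytic(geometry, motion, ph, pts)
        Ea = 0.5 * (np.einsum("nji,njk->nik", F, F) - np.eye(3))
        Em = E.E[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert np.mean(np.abs(Em - Ea)) < 1e-3

    def test_empty_mask_rejected(self, grid96):
        f = PhaseField(grid96, np.zeros(grid96.shape + (3,), np.float32), 0)
        with pytest.raises(DomainError):
            green_lagrange(f, np.zeros(grid96.shape, bool))


class TestRadialStrain:
    def test_isotropic_expansion_closed_form(self, geometry, voxelized):
        labels, _ = voxelized
        lam = 1.08
        f = _affine_field(labels.grid, np.diag([lam, lam, 1.0]))
        mask = labels.mask(LABEL_MYOCARDIUM)
        E = green_lagrange(f, mask)
        dirs = local_directions(geometry, labels)
        e_r = radial_strain(E, dirs, mask)
        assert abs(e_r - (lam**2 - 1) / 2) < 1e-4

    def test_pipeline_matches_ground_truth(self, geometry, motion, grid96, voxelized):
        labels, _ = voxelized
        ph = motion.peak_phase
        f = lv_displacement(geometry, motion, ph, grid96, labels)
        mask = labels.mask(LABEL_MYOCARDIUM)
        E = green_lagrange(f, mask)
        dirs = local_directions(geometry, labels)
        e_r = radial_strain(E, dirs, mask)
        gt = ground_truth_strains(geometry, motion, ph)[0]
        assert abs(e_r - gt) < 0.02

    def test_rigid_translation_objectivity(self, geometry, voxelized):
        labels, _ = voxelized
        grid = labels.grid
        t = np.array([2.0, -1.0, 3.0], dtype=np.float32)
        u = np.broadcast_to(t, grid.shape + (3,)).copy()
        f = PhaseField(grid, u, 1)
        mask = labels.mask(LABEL_MYOCARDIUM)
        E = green_lagrange(f, mask)
        dirs = local_directions(geometry, labels)
        assert abs(radial_strain(E, dirs, mask)) < 1e-6


class TestCircumferential:
    def test_identical_masks_zero(self, voxelized):
        labels, _ = voxelized
        m = labels.mask(LABEL_MYOCARDIUM)
        sax = default_sax_slices(m)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e_c = circumferential_strain([m, m], sax)
        assert np.allclose(e_c, [0.0, 0.0])

    def test_uniform_scaling_gives_linear_strain(self):
        # synthetic annulus scaled in-plane by lambda: e_c = lambda - 1
        g = GridSpec((96, 96, 8), (1.0, 1.0, 1.0))
        x, y, _ = g.meshgrid()
        rho = np.hypot(x, y)
        masks = []
        for lam in (1.0, 0.85):
            masks.append((rho >= 25 * lam) & (rho <= 35 * lam))
        e_c = circumferential_strain(masks, np.array([4]))
        assert abs(e_c[1] - (0.85 - 1.0)) < 0.02

    def test_analytic_contraction_matches_closed_form(self, grid96):
        from cardiotag.anatomy import LVGeometry

        geo = LVGeometry(20.0, 8.0, 72.0, 0.6)
        p = MotionParams(contraction=0.2, twist_deg=0.0, shortening=0.0)
        labels, _ = voxelize_lv(geo, grid96)
        ph = p.peak_phase
        warped = [labels.mask(1), warp_labels(labels, geo, p, ph).mask(1)]
        sax = default_sax_slices(warped[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e_c = circumferential_strain(warped, sax)
        gt = ground_truth_strains(geo, p, ph)[1]
        assert abs(e_c[1] - gt) < 0.02

    def test_open_annulus_dropped(self):
        g = GridSpec((64, 64, 8), (1.0, 1.0, 1.0))
        x, y, _ = g.meshgrid()
        rho = np.hypot(x, y)
        ring = (rho >= 15) & (rho <= 22)
        ring_open = ring & ~((x > 0) & (np.abs(y) < 3))  # wall gap
        with pytest.raises(DomainError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                circumferential_strain([ring_open, ring_open], np.array([4]))

    def test_midwall_diameter_of_ring(self):
        g = GridSpec((96, 96, 8), (1.0, 1.0, 1.0))
        x, y, _ = g.meshgrid()
        rho = np.hypot(x, y)
        ring = ((rho >= 25) & (rho <= 35))[:, :, 4]
        D = midwall_diameter(ring, (1.0, 1.0))
        assert abs(D - 60.0) < 1.5  # mid-radius 30


class TestLongitudinal:
    def test_identical_masks_zero(self, geometry, voxelized):
        labels, _ = voxelized
        e_l = longitudinal_strain([labels, labels], labels.grid)
        assert np.allclose(e_l, [0.0, 0.0])

    def test_pure_shortening_matches_midline_oracle(self, geometry, grid96, voxelized):
        # the skeleton route measures the mid-wall contour length of the
        # LAX cut; compare against its exact deformed length
        labels, _ = voxelized
        p = MotionParams(contraction=0.0, twist_deg=0.0, shortening=0.2)
        ph = p.peak_phase
        warped = [labels, warp_labels(labels, geometry, p, ph)]
        e_l = longitudinal_strain(warped, grid96)[1]
        oracle = midline_length_ratio(geometry, p, ph) - 1.0
        assert abs(e_l - oracle) < 0.02
        assert e_l < -0.1  # substantial shortening is detected

    def test_quarter_turn_invariance(self, geometry, grid96, voxelized):
        # the two LAX planes swap under a 90 deg in-plane rotation of an
        # axisymmetric case; the averaged strain must be unchanged
        labels, _ = voxelized
        p = MotionParams(contraction=0.15, twist_deg=0.0, shortening=0.12)
        warped = [labels, warp_labels(labels, geometry, p, p.peak_phase)]
        e_l = longitudinal_strain(warped, grid96)[1]
        rot = []
        for lv in warped:
            r = lv.copy()
            r.labels = np.rot90(lv.labels, k=1, axes=(0, 1)).copy()
            rot.append(r)
        e_l_rot = longitudinal_strain(rot, grid96)[1]
        assert abs(e_l - e_l_rot) < 0.01


class TestMeshWarping:
    def test_zero_field_identity(self, voxelized):
        labels, mesh = voxelized
        f = PhaseField(labels.grid, np.zeros(labels.grid.shape + (3,), np.float32), 0)
        out = warp_mesh(mesh, f)
        assert np.allclose(out.vertices, mesh.vertices)

    def test_constant_field_rigid_translation(self, voxelized):
        labels, mesh = voxelized
        t = np.array([1.5, -2.0, 0.5], dtype=np.float32)
        u = np.broadcast_to(t, labels.grid.shape + (3,)).copy()
        out = warp_mesh(mesh, PhaseField(labels.grid, u, 1))
        assert np.allclose(out.vertices, mesh.vertices + t, atol=1e-6)
        assert (out.faces == mesh.faces).all()

    def test_analytic_field_tracks_forward_map(self, geometry, motion, grid96, voxelized):
        from cardiotag.motion import forward_map

        labels, mesh = voxelized
        ph = motion.peak_phase
        # the field is defined on myocardial voxels; probe mid-wall
        # vertices away from the surface-adjacent interpolation shell
        f = lv_displacement(geometry, motion, ph, grid96, labels)
        mid = 0.5 * (
            mesh.vertices[mesh.vertex_labels == 1][: 500]
            + mesh.vertices[mesh.vertex_labels == 2][: 500]
        )
        moved = warp_mesh(
            type(mesh)(mid, np.zeros((0, 3), int), np.ones(len(mid), np.int16)), f
        )
        expected = forward_map(geometry, motion, ph, mid)
        err = np.linalg.norm(moved.vertices - expected, axis=1)
        # trilinear interpolation error dominated by the field cutoff at
        # the wall surface; interior midpoints stay within 0.1 mm
        assert np.median(err) < 0.1


class TestStrainCurves:
    @pytest.fixture(scope="class")
    def case_curves(self, geometry, motion, grid96, voxelized):
        labels, mesh = voxelized
        # includes the activation peak (phase 9) among the sampled phases
        phases = list(range(0, motion.n_phases, 3))
        fields, warped = [], []
        remap = {}
        for i, ph in enumerate(phases):
            fields.append(lv_displacement(geometry, motion, ph, grid96, labels))
            warped.append(warp_labels(labels, geometry, motion, ph))
            remap[i] = ph
        dirs = local_directions(geometry, labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curves = strain_curves(fields, warped, dirs)
        return curves, remap

    def test_reference_phase_null(self, case_curves):
        curves, _ = case_curves
        assert curves.e_r[0] == 0.0 and curves.e_c[0] == 0.0 and curves.e_l[0] == 0.0

    def test_peak_systolic_sign_pattern(self, case_curves):
        curves, _ = case_curves
        ps = curves.peak_systolic
        assert ps["e_r_ps"] > 0 and ps["e_c_ps"] < 0 and ps["e_l_ps"] < 0

    def test_extrema_at_activation_peak(self, case_curves, motion):
        curves, remap = case_curves
        ps = curves.peak_systolic
        for key in ("phase_r", "phase_c", "phase_l"):
            assert remap[ps[key]] == motion.peak_phase

    def test_zero_motion_all_zero(self, geometry, grid96, voxelized):
        labels, _ = voxelized
        zero = PhaseField(grid96, np.zeros(grid96.shape + (3,), np.float32), 0)
        dirs = local_directions(geometry, labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curves = strain_curves([zero, zero], [labels, labels], dirs)
        assert np.allclose(curves.e_r, 0) and np.allclose(curves.e_c, 0)
        assert np.allclose(curves.e_l, 0)
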