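import numpy as np
import pytest

import cardiotag.network.layers as layers_mod
from cardiotag.errors import ConfigurationError
from cardiotag.network import (
    NetworkSpec,
    PatchSample,
    TrainConfig,
    build_network,
    extract_patches,
    infer_field,
    load_checkpoint,
    masked_mse,
    patch_corners,
    raised_cosine_window,
    save_checkpoint,
    split_cases,
    track_landmarks,
    train,
)
from cardiotag.network.layers import Conv3d, MaxPool3d, Upsample3d
from cardiotag.network.training import evaluate_loss

rng = np.random.default_rng(12345)


class TestLayers:
    def test_conv_paths_agree(self):
        """The numba stencil kernels and the im2col/BLAS fallback are two
        independent implementations of the same convolution."""
        conv = Conv3d(3, 5, 3, np.random.default_rng(0))
        x = rng.normal(size=(2, 6, 7, 8, 3)).astype(np.float32)
        g = rng.normal(size=(2, 6, 7, 8, 5)).astype(np.float32)
        out_a = conv.forward(x)
        gx_a = conv.backward(g)
        gW_a = conv.W.grad.copy()
        conv.W.grad[:] = 0
        conv.b.grad[:] = 0
        have = layers_mod._HAVE_NUMBA
        try:
            layers_mod._HAVE_NUMBA = False
            out_b = conv.forward(x)
            gx_b = conv.backward(g)
        finally:
            layers_mod._HAVE_NUMBA = have
        assert np.allclose(out_a, out_b, atol=1e-5)
        assert np.allclose(gx_a, gx_b, atol=1e-5)
        assert np.allclose(gW_a, conv.W.grad, rtol=1e-4, atol=1e-4)

    def test_conv_input_gradient_is_adjoint(self):
        # convolution is linear in its input: <conv(x) - conv(0), g> must
        # equal <x, backward(g)> exactly
        conv = Conv3d(2, 4, 3, np.random.default_rng(1))
        x = rng.normal(size=(1, 6, 6, 6, 2)).astype(np.float32)
        g = rng.normal(size=(1, 6, 6, 6, 4)).astype(np.float32)
        zero = np.zeros_like(x)
        lhs = float(np.sum((conv.forward(x, train=False) - conv.forward(zero)) * g))
        gx = conv.backward(g)
        rhs = float(np.sum(x * gx))
        assert abs(lhs - rhs) < 1e-3 * max(1.0, abs(lhs))

    def test_conv_weight_gradient_directional(self):
        # output is linear in W: finite difference is exact
        conv = Conv3d(2, 3, 3, np.random.default_rng(2))
        x = rng.normal(size=(1, 5, 5, 5, 2)).astype(np.float32)
        g = rng.normal(size=(1, 5, 5, 5, 3)).astype(np.float32)
        conv.forward(x)
        conv.backward(g)
        dW = rng.normal(size=conv.W.value.shape).astype(np.float32)
        ana = float(np.sum(conv.W.grad * dW))
        out0 = conv.forward(x, train=False)
        conv.W.value += dW
        out1 = conv.forward(x, train=False)
        num = float(np.sum((out1 - out0) * g))
        assert abs(ana - num) < 1e-3 * max(1.0, abs(num))

    def test_pool_upsample_adjoint(self):
        x = rng.normal(size=(1, 8, 8, 8, 3)).astype(np.float32)
        up = Upsample3d()
        y = rng.normal(size=(1, 16, 16, 16, 3)).astype(np.float32)
        lhs = np.sum(up.forward(x) * y)
        rhs = np.sum(x * up.backward(y))
        assert np.isclose(lhs, rhs, rtol=1e-5)
        pool = MaxPool3d()
        out = pool.forward(x)
        g = rng.normal(size=out.shape).astype(np.float32)
        gx = pool.backward(g)
        # max pool backward routes each gradient to its argmax voxel
        assert np.isclose(gx.sum(), g.sum(), rtol=1e-5)


class TestUNet:
    def test_forward_shape_and_channel_variants(self):
        x = rng.normal(size=(2, 16, 16, 16, 2)).astype(np.float32)
        for out_ch in (1, 2):
            net = build_network(NetworkSpec(4, 2, out_channels=out_ch), 0)
            y = net.forward(x, train=False)
            assert y.shape == (2, 16, 16, 16, out_ch)

    def test_channel_scaling_of_parameter_count(self):
        n8 = build_network(NetworkSpec(8, 4, out_channels=2), 0).n_parameters()
        n64 = build_network(NetworkSpec(64, 4, out_channels=2), 0).n_parameters()
        assert 0.9 < (n64 / n8) / (64 / 8) ** 2 < 1.1

    def test_output_head_is_only_difference(self):
        s2 = NetworkSpec(4, 2, out_channels=2)
        s1 = NetworkSpec(4, 2, out_channels=1)
        n2 = build_network(s2, 0).n_parameters()
        n1 = build_network(s1, 0).n_parameters()
        assert n2 - n1 == 4 + 1  # one extra 1x1-conv row + bias

    def test_incompatible_depth_rejected(self):
        with pytest.raises(ConfigurationError):
            build_network(NetworkSpec(4, 5, out_channels=1), 0, patch_size=16)
        net = build_network(NetworkSpec(4, 3, out_channels=1), 0)
        with pytest.raises(ConfigurationError):
            net.forward(np.zeros((1, 12, 12, 12, 2), np.float32))

    def test_masked_loss_ignores_outside_targets(self):
        net = build_network(NetworkSpec(2, 1, out_channels=2), 0)
        x = rng.normal(size=(1, 8, 8, 8, 2)).astype(np.float32)
        tgt = rng.normal(size=(1, 8, 8, 8, 2)).astype(np.float32)
        mask = np.zeros((1, 8, 8, 8), bool)
        mask[0, 2:6, 2:6, 2:6] = True
        pred = net.forward(x, train=False)
        loss0, _ = masked_mse(pred, tgt, mask)
        tgt2 = tgt.copy()
        tgt2[~mask] = 1e6  # garbage outside the myocardium
        loss1, _ = masked_mse(pred, tgt2, mask)
        assert loss0 == loss1


class TestSplits:
    def test_protocol_sized_split(self):
        m = split_cases(range(260), (0.8, 0.1, 0.1), seed=0)
        assert (len(m.train), len(m.val), len(m.test)) == (208, 26, 26)

    def test_small_split(self):
        m = split_cases(range(10), (0.8, 0.1, 0.1), seed=1)
        assert (len(m.train), len(m.val), len(m.test)) == (8, 1, 1)

    def test_disjoint_and_complete(self):
        m = split_cases(range(53), (0.8, 0.1, 0.1), seed=3)
        all_ids = set(m.train) | set(m.val) | set(m.test)
        assert len(all_ids) == 53
        assert not (set(m.train) & set(m.val))
        assert not (set(m.train) & set(m.test))
        assert not (set(m.val) & set(m.test))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            split_cases(range(10), (0.5, 0.2, 0.2), seed=0)
        with pytest.raises(ConfigurationError):
            split_cases(range(2), (0.8, 0.1, 0.1), seed=0)


class TestPatches:
    def test_corner_lattice_of_protocol_volume(self):
        corners = patch_corners((128, 128, 128), 64, 16)
        assert len(corners) == 125  # ((128-64)/16 + 1)^3
        assert corners[0] == (0, 0, 0) and corners[-1] == (64, 64, 64)
        assert corners == sorted(corners)

    def test_all_myocardium_retains_every_candidate(self):
        shape = (128, 128, 128)
        vol = np.zeros(shape, np.float32)
        field = np.zeros(shape + (3,), np.float32)
        mask = np.ones(shape, bool)
        out = extract_patches(vol, vol, field, mask, size=64, stride=16)
        assert len(out) == 125

    def test_empty_mask_retains_nothing(self):
        shape = (64, 64, 64)
        vol = np.zeros(shape, np.float32)
        field = np.zeros(shape + (3,), np.float32)
        out = extract_patches(vol, vol, field, np.zeros(shape, bool), size=32, stride=16)
        assert out == []

    def test_provenance_reconstructs_source_block(self):
        shape = (48, 48, 48)
        ed = rng.random(shape).astype(np.float32)
        ph = rng.random(shape).astype(np.float32)
        field = rng.random(shape + (3,)).astype(np.float32)
        mask = np.ones(shape, bool)
        out = extract_patches(ed, ph, field, mask, size=16, stride=16, case_id="c7", phase=3)
        s = out[len(out) // 2]
        sl = tuple(slice(o, o + 16) for o in s.corner)
        assert (s.image[..., 0] == ed[sl]).all()
        assert (s.image[..., 1] == ph[sl]).all()
        assert (s.target == field[sl]).all()
        assert s.case_id == "c7" and s.phase == 3

    def test_oversized_patch_rejected(self):
        vol = np.zeros((32, 32, 32), np.float32)
        with pytest.raises(ConfigurationError):
            extract_patches(vol, vol, np.zeros((32, 32, 32, 3), np.float32),
                            np.ones((32, 32, 32), bool), size=64, stride=16)


def _toy_samples(n, shape=(12, 12, 12), target_value=2.0, seed=0):
    r = np.random.default_rng(seed)
    out = []
    for i in range(n):
        img = r.random(shape + (2,)).astype(np.float32)
        tgt = np.full(shape + (3,), target_value, np.float32)
        out.append(PatchSample(img, tgt, np.ones(shape, bool), i, 1, (0, 0, 0)))
    return out


class TestTraining:
    def test_overfit_constant_translation(self):
        # capacity sanity check: a constant subvoxel translation target
        # must be fit to < 0.01 mm^2 within 200 optimizer steps (the
        # output bias moves by about one learning rate per Adam step, so
        # the reachable offset within the step budget is lr * steps)
        samples = _toy_samples(10, shape=(8, 8, 8), target_value=0.5)
        cfg = TrainConfig(epochs=100, batch_size=5, initial_lr=3e-3, seed=0)
        net, hist = train(samples, samples[:2], NetworkSpec(16, 2, out_channels=2), cfg)
        assert hist.train_loss.iloc[-1] < 0.01

    def test_fixed_seed_reproducible(self):
        samples = _toy_samples(6, seed=3)
        cfg = TrainConfig(epochs=3, batch_size=3, initial_lr=1e-3, seed=11)
        _, h1 = train(samples, samples[:2], NetworkSpec(2, 2, out_channels=1), cfg)
        _, h2 = train(samples, samples[:2], NetworkSpec(2, 2, out_channels=1), cfg)
        assert np.array_equal(h1.train_loss.values, h2.train_loss.values)
        assert np.array_equal(h1.val_loss.values, h2.val_loss.values)

    def test_lr_schedule_halves_at_most_three_times(self):
        samples = _toy_samples(8, seed=5)
        cfg = TrainConfig(epochs=12, batch_size=4, initial_lr=1e-3, seed=2)
        _, hist = train(samples, samples[:2], NetworkSpec(2, 1, out_channels=1), cfg)
        lrs = hist.lr.unique()
        allowed = {1e-3, 5e-4, 2.5e-4, 1.25e-4}
        assert set(np.round(lrs, 10)).issubset({round(v, 10) for v in allowed})
        assert (np.diff(hist.lr.values) <= 0).all()

    def test_best_validation_weights_kept(self):
        samples = _toy_samples(8, seed=6)
        cfg = TrainConfig(epochs=6, batch_size=4, initial_lr=3e-3, seed=4)
        net, hist = train(samples, samples[:2], NetworkSpec(2, 1, out_channels=1), cfg)
        final = evaluate_loss(net, samples[:2])
        assert final <= hist.val_loss.min() + 1e-6

    def test_empty_sets_rejected(self):
        samples = _toy_samples(4)
        cfg = TrainConfig(epochs=1, seed=0)
        with pytest.raises(ConfigurationError):
            train([], samples, NetworkSpec(2, 1, out_channels=1), cfg)
        with pytest.raises(ConfigurationError):
            train(samples, [], NetworkSpec(2, 1, out_channels=1), cfg)


class _ConstantNet:
    """Stub emitting a constant field; exercises the stitching path."""

    def __init__(self, values):
        self.values = np.asarray(values, np.float32)

        class _S:
            out_channels = len(self.values)

        self.spec = _S()

    def forward(self, x, train=False):
        out = np.empty(x.shape[:-1] + (len(self.values),), np.float32)
        out[:] = self.values
        return out


class TestInference:
    def test_window_strictly_positive(self):
        w = raised_cosine_window(16)
        assert w.min() > 0

    def test_stitching_partition_of_unity(self):
        # a constant-output network must blend to exactly that constant
        ed = rng.random((40, 40, 40)).astype(np.float32)
        f = infer_field(ed, ed, _ConstantNet([3.25, -0.5]), _ConstantNet([-1.5]),
                        patch_size=16, stride=8)
        # constant up to float32 roundoff of the weight normalization
        for c, v in enumerate([3.25, -0.5, -1.5]):
            dev = np.abs(f.vectors[..., c] - np.float32(v)).max()
            assert dev < 1e-5 * abs(v)

    def test_non_lattice_volume_covered(self):
        # 42 is not a multiple of the stride; the trailing corner clamps
        ed = rng.random((42, 42, 42)).astype(np.float32)
        f = infer_field(ed, ed, _ConstantNet([1.0, 1.0]), _ConstantNet([1.0]),
                        patch_size=16, stride=12)
        assert np.all(f.vectors == 1.0)

    def test_wrong_head_rejected(self):
        ed = rng.random((24, 24, 24)).astype(np.float32)
        with pytest.raises(ConfigurationError):
            infer_field(ed, ed, _ConstantNet([1.0]), _ConstantNet([1.0]),
                        patch_size=16, stride=8)


class TestLandmarks:
    def test_zero_fields_static_trajectories(self, grid96):
        from cardiotag.motion import PhaseField

        fields = [
            PhaseField(grid96, np.zeros(grid96.shape + (3,), np.float32), t)
            for t in range(3)
        ]
        pts = np.array([[0.0, 5.0, -10.0], [12.0, -3.0, 7.0]])
        traj = track_landmarks(pts, fields)
        assert traj.shape == (2, 3, 3)
        assert np.allclose(traj, pts[:, None, :])

    def test_analytic_fields_track_forward_map(self, geometry, motion, grid96, voxelized):
        from cardiotag.motion import forward_map, lv_displacement

        labels, _ = voxelized
        ph = motion.peak_phase
        fields = [lv_displacement(geometry, motion, p, grid96, labels) for p in (0, ph)]
        # mid-wall landmarks, clear of the field's surface cutoff
        r = geometry.endo_radius_eq + geometry.wall_thickness / 2
        ang = np.linspace(0, 2 * np.pi, 14, endpoint=False)
        pts = np.stack([r * np.cos(ang), r * np.sin(ang), np.full_like(ang, -4.0)], axis=-1)
        traj = track_landmarks(pts, fields)
        expected = forward_map(geometry, motion, ph, pts)
        assert np.linalg.norm(traj[:, 1] - expected, axis=1).max() < 0.1


class TestCheckpoint:
    def test_roundtrip_and_acq_guard(self, tmp_path):
        from cardiotag.tagging import AcqConfig

        net = build_network(NetworkSpec(2, 1, out_channels=2), 3)
        p = tmp_path / "w.npz"
        save_checkpoint(p, net, acq=AcqConfig(tag_distance=7.0), manifest={"k": 1})
        loaded, meta = load_checkpoint(p, expected_acq=AcqConfig(tag_distance=7.0))
        x = rng.random((1, 8, 8, 8, 2)).astype(np.float32)
        assert np.allclose(net.forward(x, train=False), loaded.forward(x, train=False))
        with pytest.raises(ConfigurationError):
            load_checkpoint(p, expected_acq=AcqConfig(tag_distance=4.0))
        # deliberate override stays possible
        load_checkpoint(p, expected_acq=AcqConfig(tag_distance=4.0), allow_mismatch=True)
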