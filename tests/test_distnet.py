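import numpy as np
import pytest

from istomo.distnet import (AugmentConfig, LossConfig, NetworkConfig,
                            SignedDistanceMap, TrainConfig, augment,
                            boundary_weighted_l1, boundary_weights,
                            build_network, build_signed_distance_target,
                            expected_parameter_count, infer, full_scale_config,
                            should_stop, train)
from istomo.io import CellMaskPair, ShapeError, Tomogram, ValidationError

PITCH = (218.5,) * 3


def brute_force_signed_edt(eff, tgt):
    """Exhaustive nearest-background-voxel search (the independent oracle)."""
    union = eff | tgt
    bg = np.argwhere(~union)
    out = np.zeros(union.shape, dtype=np.float64)
    for idx in np.argwhere(union):
        d = np.sqrt(((bg - idx) ** 2).sum(axis=1).min())
        out[tuple(idx)] = d if eff[tuple(idx)] else -d
    return out


class TestSignedDistanceTarget:
    def test_single_voxel(self):
        eff = np.zeros((5, 5, 5), bool)
        eff[2, 2, 2] = True
        y = build_signed_distance_target(CellMaskPair(eff, np.zeros_like(eff),
                                                      PITCH))
        assert y.values[2, 2, 2] == 1.0
        assert np.count_nonzero(y.values) == 1

    def test_cube_center_and_faces(self):
        """3-cube: faces at +1, center at +2 (nearest background search)."""
        eff = np.zeros((7, 7, 7), bool)
        eff[2:5, 2:5, 2:5] = True
        y = build_signed_distance_target(CellMaskPair(eff, np.zeros_like(eff),
                                                      PITCH)).values
        assert y[3, 3, 3] == 2.0
        assert y[2, 3, 3] == y[4, 3, 3] == y[3, 2, 3] == y[3, 3, 2] == 1.0

    def test_sign_antisymmetry(self, rng):
        eff = rng.random((8, 8, 8)) > 0.7
        tgt = ~eff & (rng.random((8, 8, 8)) > 0.7)
        a = build_signed_distance_target(CellMaskPair(eff, tgt, PITCH)).values
        b = build_signed_distance_target(CellMaskPair(tgt, eff, PITCH)).values
        np.testing.assert_array_equal(a, -b)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(5, 13, 3))
        eff = rng.random(shape) > 0.75
        tgt = ~eff & (rng.random(shape) > 0.75)
        if not (~(eff | tgt)).any():
            pytest.skip("no background in this draw")
        pair = CellMaskPair(eff, tgt, PITCH)
        got = build_signed_distance_target(pair).values
        np.testing.assert_allclose(got, brute_force_signed_edt(eff, tgt),
                                   atol=1e-5)


class TestBoundaryWeightedL1:
    def test_zero_at_identity(self, rng):
        y = rng.standard_normal((6, 6, 6)).astype(np.float32)
        assert boundary_weighted_l1(y, y) == 0.0

    def test_reduces_to_plain_l1(self):
        y_true = np.zeros((5, 5, 5), np.float32)
        y_pred = y_true + 1.0
        cfg = LossConfig(boundary_weight=0.0, boundary_sigma=1.0)
        assert boundary_weighted_l1(y_pred, y_true, cfg) == pytest.approx(1.0)

    def test_hand_enumerated_toy_grid(self):
        """5-cube with a single-voxel cell: loss equals the brute-force
        weighted sum computed voxel by voxel."""
        y_true = np.zeros((5, 5, 5), np.float32)
        y_true[2, 2, 2] = 1.0
        y_pred = y_true + 0.5
        cfg = LossConfig(boundary_weight=9.0, boundary_sigma=1.0)

        # oracle: boundary voxel set is the single cell voxel itself
        expected = 0.0
        for z in range(5):
            for y in range(5):
                for x in range(5):
                    d2 = (z - 2) ** 2 + (y - 2) ** 2 + (x - 2) ** 2
                    w = 1.0 + 9.0 * np.exp(-d2 / 2.0)
                    expected += w * 0.5
        expected /= 125.0
        got = boundary_weighted_l1(y_pred, y_true, cfg)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_weights_peak_on_boundary(self):
        y_true = np.zeros((7, 7, 7), np.float32)
        y_true[2:5, 2:5, 2:5] = 1.0
        w = boundary_weights(y_true, LossConfig())
        assert w[2, 3, 3] == w.max() == pytest.approx(10.0)  # boundary voxel
        # far corner: d = 2*sqrt(3) to the nearest boundary voxel
        d2 = 12.0
        assert w[0, 0, 0] == pytest.approx(1 + 9 * np.exp(-d2 / 8.0), rel=1e-5)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            boundary_weighted_l1(np.zeros((3, 3, 3)), np.zeros((4, 4, 4)))


class TestNetwork:
    TOY = NetworkConfig(levels=3, filters=(8, 16, 32),
                        gcn_kernel_sizes=(7, 5, 3), patch_shape=(32, 32, 32))

    def test_shape_contract(self):
        net = build_network(self.TOY, seed=0)
        out = net.forward(np.zeros((32, 32, 32), np.float32))
        assert out.shape == (32, 32, 32)

    def test_parameter_count_matches_formula(self):
        net = build_network(self.TOY, seed=0)
        assert net.n_parameters() == expected_parameter_count(self.TOY)

    def test_full_scale_config_validates(self):
        cfg = full_scale_config()
        assert cfg.levels == 5
        assert cfg.filters == (32, 64, 128, 256, 512)
        assert cfg.gcn_kernel_sizes == (13, 13, 9, 7, 5)
        assert expected_parameter_count(cfg) > 10**6

    def test_indivisible_patch_rejected(self):
        with pytest.raises(ShapeError):
            NetworkConfig(levels=3, filters=(4, 8, 16),
                          gcn_kernel_sizes=(3, 3, 3), patch_shape=(30, 32, 32))

    def test_mismatched_lists_rejected(self):
        with pytest.raises(ValidationError):
            NetworkConfig(levels=3, filters=(4, 8),
                          gcn_kernel_sizes=(3, 3, 3), patch_shape=(32, 32, 32))

    def test_even_gcn_kernel_rejected(self):
        with pytest.raises(ValidationError):
            NetworkConfig(levels=2, filters=(4, 8), gcn_kernel_sizes=(4, 3),
                          patch_shape=(16, 16, 16))

    def test_gradient_matches_finite_difference(self):
        """Backprop through the full net agrees with a numerical gradient."""
        cfg = NetworkConfig(levels=2, filters=(2, 4), gcn_kernel_sizes=(3, 3),
                            patch_shape=(8, 8, 8))
        net = build_network(cfg, seed=1)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((8, 8, 8)).astype(np.float32)
        target = rng.standard_normal((8, 8, 8)).astype(np.float32)

        def loss_of():
            return float(np.mean((net.forward(x) - target) ** 2))

        out = net.forward(x)
        net.zero_grad()
        net.backward((2.0 * (out - target) / out.size).astype(np.float32))
        params = net.params()
        grads = net.grads()
        eps = 1e-2  # float32 arithmetic limits the attainable FD accuracy
        rng2 = np.random.default_rng(5)
        for key in ["stem.w", "enc1.body.0.w", "skip0.body.1.w", "head.b"]:
            p = params[key]
            flat = rng2.integers(0, p.size)
            idx = np.unravel_index(flat, p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss_of()
            p[idx] = orig - eps
            lm = loss_of()
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[key][idx] == pytest.approx(num, rel=0.1, abs=1e-3)


class TestAugment:
    def setup_pair(self, rng, shape=(12, 12, 12)):
        eff = np.zeros(shape, bool)
        eff[3:7, 3:7, 3:7] = True
        tgt = np.zeros(shape, bool)
        tgt[7:10, 5:9, 5:9] = True
        pair = CellMaskPair(eff, tgt & ~eff, PITCH)
        y = build_signed_distance_target(pair).values
        vol = rng.random(shape).astype(np.float32)
        return vol, y

    def test_all_disabled_is_identity(self, rng):
        vol, y = self.setup_pair(rng)
        cfg = AugmentConfig(rotate=False, reflect=False, crop=None,
                            elastic=False)
        v2, y2 = augment(vol, y, seed=0, cfg=cfg)
        np.testing.assert_array_equal(v2, vol)
        np.testing.assert_array_equal(y2, y)

    def test_same_seed_same_output(self, rng):
        vol, y = self.setup_pair(rng)
        cfg = AugmentConfig(crop=(8, 8, 8), elastic=True)
        a = augment(vol, y, seed=42, cfg=cfg)
        b = augment(vol, y, seed=42, cfg=cfg)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_right_angle_rotation_preserves_counts(self, rng):
        """90-degree axial rotations and lateral flips permute voxels."""
        vol, y = self.setup_pair(rng)
        cfg = AugmentConfig(rotate=True, reflect=True, crop=None, elastic=False)
        for seed in range(6):
            v2, y2 = augment(vol, y, seed=seed, cfg=cfg)
            assert (y2 > 0).sum() == (y > 0).sum()
            assert (y2 < 0).sum() == (y < 0).sum()
            assert np.isclose(v2.sum(), vol.sum(), rtol=1e-6)

    def test_elastic_recomputes_distances(self, rng):
        """After an elastic warp the target is a valid signed EDT of the
        warped masks, not an interpolation of the old distances."""
        vol, y = self.setup_pair(rng, shape=(16, 16, 16))
        cfg = AugmentConfig(rotate=False, reflect=False, crop=None,
                            elastic=True, elastic_amplitude=2.0)
        _, y2 = augment(vol, y, seed=7, cfg=cfg)
        eff, tgt = y2 > 0, y2 < 0
        pair = CellMaskPair(eff, tgt, PITCH)
        np.testing.assert_allclose(
            y2, build_signed_distance_target(pair).values, atol=1e-5)

    def test_oversized_crop_rejected(self, rng):
        vol, y = self.setup_pair(rng)
        with pytest.raises(ShapeError):
            augment(vol, y, seed=0, cfg=AugmentConfig(crop=(20, 20, 20)))


def tiny_dataset(n, shape=(16, 16, 16), seed=0):
    """Small random two-blob volumes with their distance targets."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape],
                                 indexing="ij", sparse=True)
        c1 = rng.uniform(4, 6, 3)
        c2 = rng.uniform(9, 12, 3)
        eff = ((zz - c1[0]) ** 2 + (yy - c1[1]) ** 2 + (xx - c1[2]) ** 2) <= 9
        tgt = (((zz - c2[0]) ** 2 + (yy - c2[1]) ** 2 + (xx - c2[2]) ** 2) <= 9) & ~eff
        pair = CellMaskPair(eff, tgt, PITCH)
        y = build_signed_distance_target(pair)
        vol = (0.5 * eff + 0.25 * tgt
               + 0.01 * rng.standard_normal(shape)).astype(np.float32)
        out.append((vol, y.values))
    return out


TINY_NET = NetworkConfig(levels=2, filters=(4, 8), gcn_kernel_sizes=(3, 3),
                         patch_shape=(16, 16, 16))


class TestTraining:
    def test_loss_decreases_on_toy_problem(self):
        data = tiny_dataset(8)
        cfg = TrainConfig(max_epochs=8, batch_size=1, seed=0, augment=None,
                          input_scale=1.0, patience=8)
        model, hist = train(data[:6], TINY_NET, cfg, validation=data[6:])
        assert hist["val_loss"][-1] < hist["val_loss"][0]
        assert hist["n_train"] == 6 and hist["n_val"] == 2

    def test_constant_target_converges(self):
        rng = np.random.default_rng(0)
        shape = (16, 16, 16)
        data = [(rng.standard_normal(shape).astype(np.float32),
                 np.zeros(shape, np.float32)) for _ in range(4)]
        cfg = TrainConfig(max_epochs=20, batch_size=1, seed=0, augment=None,
                          input_scale=1.0, patience=20, learning_rate=5e-3)
        model, hist = train(data[:3], TINY_NET, cfg, validation=data[3:])
        assert hist["val_loss"][-1] < 0.05

    def test_plateau_stops_at_patience(self):
        """With a vanishing learning rate the validation loss plateaus, so
        training halts once ``patience`` consecutive epochs fail to improve
        on the best seen before them -- long before the epoch cap."""
        data = tiny_dataset(4)
        cfg = TrainConfig(max_epochs=50, batch_size=1, seed=0, augment=None,
                          learning_rate=1e-12, patience=4, input_scale=1.0)
        _, hist = train(data[:3], TINY_NET, cfg, validation=data[3:])
        losses = hist["val_loss"]
        assert hist.get("stopped_early", False)
        assert len(losses) <= 2 + cfg.patience          # plateau from the start
        # the early-stop postcondition: the final `patience` epochs all failed
        # to improve on the best validation loss seen before them
        best_before = min(losses[:-cfg.patience])
        assert all(v >= best_before for v in losses[-cfg.patience:])

    def test_should_stop_rule(self):
        assert not should_stop([3.0, 2.0, 1.9], patience=3)
        assert should_stop([3.0, 1.0, 1.1, 1.2, 1.3], patience=3)
        assert not should_stop([3.0, 1.0, 1.1, 0.9, 1.3], patience=3)

    def test_empty_split_rejected(self):
        with pytest.raises(ValidationError):
            train([], TINY_NET, TrainConfig(max_epochs=1))


class TestInference:
    def test_deterministic(self):
        data = tiny_dataset(2)
        net = build_network(TINY_NET, seed=3)
        tom = Tomogram(1.337 + data[0][0] * 0.01, pitch=PITCH)
        a = infer(net, tom, input_scale=1.0)
        b = infer(net, tom, input_scale=1.0)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.pitch == PITCH

    def test_tiled_matches_untiled(self):
        """Margin-discarding tiled inference reproduces whole-volume
        inference once the margin covers the receptive field."""
        rng = np.random.default_rng(2)
        vals = (1.337 + 0.01 * rng.random((32, 32, 32))).astype(np.float32)
        tom = Tomogram(vals, pitch=PITCH)
        cfg = NetworkConfig(levels=1, filters=(6,), gcn_kernel_sizes=(3,),
                            patch_shape=(16, 16, 16))
        net = build_network(cfg, seed=0)
        full = infer(net, tom, input_scale=1.0)
        tiled = infer(net, tom, tile_shape=(16, 16, 16), overlap=12,
                      input_scale=1.0)
        assert np.abs(full.values - tiled.values).max() < 1e-4

    def test_padding_for_odd_shapes(self):
        net = build_network(TINY_NET, seed=0)
        tom = Tomogram(np.full((18, 17, 19), 1.34, np.float32), pitch=PITCH)
        y = infer(net, tom, input_scale=1.0)
        assert y.shape == (18, 17, 19)


class TestCheckpointIO:
    def test_round_trip(self, tmp_path):
        from istomo.distnet import load_checkpoint, save_checkpoint

        net = build_network(TINY_NET, seed=4)
        save_checkpoint(tmp_path / "m.npz", net, history={"val_loss": [1.0]})
        back, hist = load_checkpoint(tmp_path / "m.npz")
        assert hist == {"val_loss": [1.0]}
        x = np.random.default_rng(0).standard_normal((16, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), back.forward(x))
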