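import numpy as np
import pytest

from avcalc.geometry import CylinderParams, GridCrop, reconstruct_cylinder_mask
from avcalc.nn.autodiff import Tensor, avg_pool3d, conv3d, dropout, layer_norm, upsample3d
from avcalc.nn.losses import LossWeights, combined_loss, dice_loss, soft_reconstruct
from avcalc.nn.network import (
    NetConfig,
    build_network,
    decode_params,
    decode_radius,
    encode_params,
    encode_radius,
)
from avcalc.nn.train import TrainConfig, predict_cylinder_crop, split_indices
from avcalc.volume import ImageVolume


def numeric_grad(f, x, eps=1e-3):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


class TestAutodiff:
    def _check(self, build, params, rtol=2e-2, atol=2e-3):
        """Compare backprop gradients against central differences."""
        loss = build()
        loss.backward()
        analytic = [p.grad.copy() for p in params]
        for p, g in zip(params, analytic):
            num = numeric_grad(lambda: float(build().data), p.data)
            np.testing.assert_allclose(g, num, rtol=rtol, atol=atol)

    def test_arithmetic_and_reductions(self):
        rng = np.random.default_rng(0)
        a = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        b = Tensor(rng.normal(size=(4,)), requires_grad=True)

        def build():
            a.grad = b.grad = None
            out = ((a * b + 1.0) / (b.pow(2) + 2.0) - a).tanh()
            return (out * out).mean()

        self._check(build, [a, b])

    def test_conv_pool_upsample_chain(self):
        rng = np.random.default_rng(1)
        x = Tensor(rng.normal(size=(1, 2, 4, 4, 4)), requires_grad=True)
        w = Tensor(rng.normal(size=(3, 2, 3, 3, 3)) * 0.3, requires_grad=True)
        b = Tensor(np.zeros(3), requires_grad=True)

        def build():
            for p in (x, w, b):
                p.grad = None
            h = conv3d(x, w, b).leaky_relu(0.1)
            h = upsample3d(avg_pool3d(h, 2), 2)
            return (h * h).sum() * 0.01

        # central differences are noisy across the leaky-relu kink
        self._check(build, [x, w, b], atol=1e-2)

    def test_layer_norm_and_matmul(self):
        rng = np.random.default_rng(2)
        x = Tensor(rng.normal(size=(3, 5)), requires_grad=True)
        w = Tensor(rng.normal(size=(5, 4)), requires_grad=True)
        g = Tensor(np.ones(4), requires_grad=True)
        be = Tensor(np.zeros(4), requires_grad=True)

        def build():
            for p in (x, w, g, be):
                p.grad = None
            return (layer_norm(x @ w, g, be).sigmoid()).sum()

        self._check(build, [x, w, g, be])

    def test_getitem_gradient(self):
        x = Tensor(np.arange(12, dtype=float).reshape(3, 4), requires_grad=True)
        loss = (x[:, 1:3] * 2.0).sum()
        loss.backward()
        expected = np.zeros((3, 4))
        expected[:, 1:3] = 2.0
        np.testing.assert_array_equal(x.grad, expected)

    def test_dropout_inference_identity(self):
        x = Tensor(np.ones((4, 4)), requires_grad=True)
        out = dropout(x, 0.5, np.random.default_rng(0), training=False)
        np.testing.assert_array_equal(out.data, x.data)


class TestRadiusEncoding:
    @pytest.mark.parametrize("r,v", [(20.0, 0.0), (40.0, 1.0), (10.0, -0.5)])
    def test_printed_map(self, r, v):
        assert encode_radius(r) == pytest.approx(v)
        assert decode_radius(v) == pytest.approx(r)

    @pytest.mark.parametrize("v", [-0.2, 0.1])
    def test_roundtrip_at_cohort_range(self, v):
        assert encode_radius(decode_radius(v)) == pytest.approx(v, abs=1e-12)

    @pytest.mark.parametrize("r", [0.0, -1.0, 41.0])
    def test_domain_errors(self, r):
        with pytest.raises(ValueError):
            encode_radius(r)

    def test_param_vector_roundtrip(self):
        extent = np.array([64.0, 64.0, 64.0])
        n = np.array([0.1, -0.05, 0.99])
        n /= np.linalg.norm(n)
        vec = encode_params(n, np.array([30.0, 28.0, 35.0]), 18.0, extent)
        n2, o2, r2 = decode_params(vec, extent)
        np.testing.assert_allclose(n2, n, atol=1e-6)
        np.testing.assert_allclose(o2, [30, 28, 35], atol=1e-6)
        assert r2 == pytest.approx(18.0, abs=1e-6)


class TestNetwork:
    def test_regression_head_is_seven_wide(self):
        net = build_network(NetConfig(input_shape=(32, 32, 32), channels=(4, 8), mlp_hidden=16))
        x = np.zeros((2, 1, 32, 32, 32), dtype=np.float32)
        logits, pvec = net.forward(x)
        assert pvec.shape == (2, 7)
        assert logits.shape == (2, 1, 32, 32, 32)
        assert np.all(np.isfinite(pvec.data)) and np.all(np.isfinite(logits.data))

    def test_full_size_latent_contract(self):
        cfg = NetConfig.full_size()
        cfg.check()
        assert cfg.latent_shape == (11, 11, 8)
        assert cfg.latent_channels == 256
        net_cfg_desk = NetConfig()
        assert build_network(net_cfg_desk).pooled_descriptor_length == net_cfg_desk.channels[-1]

    def test_incompatible_input_shape_raises(self):
        with pytest.raises(ValueError):
            build_network(NetConfig(input_shape=(60, 60, 60)))
        net = build_network(NetConfig(input_shape=(32, 32, 32), channels=(4, 8)))
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 1, 16, 16, 16), dtype=np.float32))

    def test_checkpoint_roundtrip(self, tmp_path):
        cfg = NetConfig(input_shape=(32, 32, 32), channels=(4, 8), mlp_hidden=8, seed=3)
        net = build_network(cfg)
        x = np.random.default_rng(0).normal(size=(1, 1, 32, 32, 32)).astype(np.float32)
        _, p1 = net.forward(x)
        path = tmp_path / "model.npz"
        net.save(str(path))
        from avcalc.nn.network import MultiTaskCylinderNet

        net2 = MultiTaskCylinderNet.load(str(path))
        _, p2 = net2.forward(x)
        np.testing.assert_allclose(p1.data, p2.data, atol=1e-7)


class TestSoftReconstruct:
    def test_matches_hard_voxelization(self):
        extent = np.array([64.0, 64.0, 64.0])
        n = np.array([0.05, -0.1, 0.99])
        n /= np.linalg.norm(n)
        p = CylinderParams(normal=n, origin_mm=(32, 30, 33), radius_mm=18, height_mm=40)
        vec = encode_params(p.normal, p.origin_mm, p.radius_mm, extent)
        soft = soft_reconstruct(Tensor(vec[None]), (64, 64, 64), extent, sharpness=50.0,
                                spacing_mm=1.0)
        hard = soft.data[0].reshape(64, 64, 64) >= 0.5
        grid = ImageVolume(np.zeros((64, 64, 64), dtype=np.float32), (1.0, 1.0, 1.0))
        exact = reconstruct_cylinder_mask(p, grid)
        inter = np.logical_and(hard, exact).sum()
        dice = 2 * inter / (hard.sum() + exact.sum())
        assert dice >= 0.995

    def test_axis_center_one_far_outside_zero(self):
        extent = np.array([64.0, 64.0, 64.0])
        vec = encode_params(np.array([0, 0, 1.0]), np.array([32.0, 32, 32]), 18.0, extent)
        soft = soft_reconstruct(Tensor(vec[None]), (64, 64, 64), extent, spacing_mm=1.0)
        m = soft.data[0].reshape(64, 64, 64)
        assert m[32, 32, 32] > 0.99
        assert m[0, 0, 0] < 1e-3

    def test_radius_gradient_nonzero_for_misfit(self):
        extent = np.array([64.0, 64.0, 64.0])
        p_true = CylinderParams(normal=(0, 0, 1), origin_mm=(32, 32, 32), radius_mm=20,
                                height_mm=40)
        grid = ImageVolume(np.zeros((32, 32, 32), dtype=np.float32), (2.0, 2.0, 2.0))
        target = reconstruct_cylinder_mask(p_true, grid).reshape(1, -1).astype(np.float32)
        vec = encode_params(np.array([0, 0, 1.0]), np.array([32.0, 32, 32]), 14.0, extent)
        t = Tensor(vec[None], requires_grad=True)
        loss = dice_loss(soft_reconstruct(t, (32, 32, 32), extent, spacing_mm=2.0), target)
        loss.backward()
        g_radius = t.grad[0, 6]
        assert abs(g_radius) > 1e-4
        # finite-difference cross-check of the sign and scale
        def f(v):
            tt = Tensor(np.array(v)[None])
            return float(dice_loss(soft_reconstruct(tt, (32, 32, 32), extent, spacing_mm=2.0),
                                   target).data)
        eps = 1e-3
        vp, vm = vec.copy(), vec.copy()
        vp[6] += eps
        vm[6] -= eps
        num = (f(vp) - f(vm)) / (2 * eps)
        assert np.sign(num) == np.sign(g_radius)
        assert g_radius == pytest.approx(num, rel=0.1)

    def test_nonfinite_params_raise(self):
        with pytest.raises(ValueError):
            soft_reconstruct(Tensor(np.full((1, 7), np.nan)), (8, 8, 8), np.ones(3) * 8)


class TestCombinedLoss:
    def _setup(self):
        rng = np.random.default_rng(0)
        logits = Tensor(rng.normal(size=(2, 1, 16, 16, 16)), requires_grad=True)
        target = (rng.random((2, 1, 16, 16, 16)) < 0.3).astype(np.float32)
        pvec = Tensor(rng.uniform(-0.5, 0.5, (2, 7)).astype(np.float32), requires_grad=True)
        return logits, target, pvec

    def test_identical_params_zero_mse(self):
        logits, target, pvec = self._setup()
        _, terms = combined_loss(logits, target, pvec, pvec.data.copy(),
                                 recon_grid_shape=(8, 8, 8), extent_mm=np.ones(3) * 16)
        assert terms["mse_origin"] == 0.0
        assert terms["mse_normal_radius"] == 0.0

    def test_branch1_only_ablation(self):
        logits, target, pvec = self._setup()
        w = LossWeights(alpha=1.0, beta=0.0, delta=0.0, gamma=0.0)
        total, terms = combined_loss(logits, target, pvec, np.zeros((2, 7), np.float32), w)
        assert set(terms) == {"dice_seg", "total"}
        assert total.data == pytest.approx(terms["dice_seg"])

    def test_branch23_only_ablation(self):
        logits, target, pvec = self._setup()
        w = LossWeights(alpha=0.0, beta=0.25, delta=0.25, gamma=0.25)
        _, terms = combined_loss(logits, target, pvec, np.zeros((2, 7), np.float32), w,
                                 recon_grid_shape=(8, 8, 8), extent_mm=np.ones(3) * 16)
        assert "dice_seg" not in terms
        assert {"mse_origin", "mse_normal_radius", "dice_recon"} <= set(terms)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-0.1)


class TestSplit:
    def test_default_rounding_covers_dataset(self):
        cfg = TrainConfig(seed=5)
        tr, va, te = split_indices(310, cfg)
        assert len(tr) + len(va) + len(te) == 310
        assert len(tr) == 201 and len(va) == 46 and len(te) == 63
        assert len(np.intersect1d(tr, va)) == 0

    def test_reference_counts_override(self):
        cfg = TrainConfig(split_counts=(200, 49, 61), seed=5)
        tr, va, te = split_indices(310, cfg)
        assert (len(tr), len(va), len(te)) == (200, 49, 61)

    def test_seed_fixed_reproducible(self):
        cfg = TrainConfig(seed=9)
        a = split_indices(40, cfg)
        b = split_indices(40, cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            TrainConfig(split_fractions=(0.5, 0.2, 0.2))


class FakeNet:
    """Stub exposing the forward contract: ideal mask logits, arbitrary params."""

    def __init__(self, mask, pvec):
        self._logits = np.where(mask, 10.0, -10.0)[None, None].astype(np.float32)
        self._pvec = pvec.astype(np.float32)

    def forward(self, x, training=False):
        return Tensor(self._logits), Tensor(self._pvec[None])


class TestCoMLinkage:
    def test_origin_from_ideal_mask_ignores_regression(self):
        grid = ImageVolume(np.zeros((64, 64, 64), dtype=np.float32), (1.0, 1.0, 1.0))
        p = CylinderParams(normal=(0, 0, 1), origin_mm=(30, 34, 32), radius_mm=16, height_mm=40)
        mask = reconstruct_cylinder_mask(p, grid)
        crop = GridCrop(crop_offset=(0, 0, 0), crop_shape=(64, 64, 64),
                        orig_shape=(64, 64, 64), orig_spacing=(1.0, 1.0, 1.0))
        bogus = encode_params(np.array([0, 0, 1.0]), np.array([5.0, 5, 5]), 20.0,
                              crop.crop_extent_mm)
        pred, fallback = predict_cylinder_crop(FakeNet(mask, bogus), np.zeros((64,) * 3,
                                               dtype=np.float32), crop)
        assert not fallback
        half_diag = np.sqrt(3) / 2
        assert np.linalg.norm(pred.origin_mm - p.origin_mm) <= half_diag

    def test_empty_segmentation_falls_back_to_regression(self):
        crop = GridCrop(crop_offset=(0, 0, 0), crop_shape=(64, 64, 64),
                        orig_shape=(64, 64, 64), orig_spacing=(1.0, 1.0, 1.0))
        vec = encode_params(np.array([0, 0, 1.0]), np.array([22.0, 24, 26]), 18.0,
                            crop.crop_extent_mm)
        empty = np.zeros((64, 64, 64), bool)
        pred, fallback = predict_cylinder_crop(FakeNet(empty, vec), np.zeros((64,) * 3,
                                               dtype=np.float32), crop)
        assert fallback
        np.testing.assert_allclose(pred.origin_mm, [22, 24, 26], atol=1e-5)
        assert np.linalg.norm(pred.normal) == pytest.approx(1.0)
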