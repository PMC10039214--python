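"""Registration network: architecture shapes, losses, invariants."""

import numpy as np
import pytest

from pelvreg._warp import warp_bicubic
from pelvreg.deform import DisplacementField
from pelvreg.io import ImageSlice
from pelvreg.regnet import (PairBatch, RegistrationNetwork, build_regressor,
                            combined_loss, mse, ncc, resample, soft_dice,
                            variant_config)


class TestVariantConfig:
    def test_table_rows(self):
        v1 = variant_config(1)
        assert (v1.n_conv_layers, v1.loss, v1.pooling) == (4, "NCC", True)
        v2 = variant_config(2)
        assert (v2.n_conv_layers, v2.loss, v2.pooling) == (4, "MSE", True)
        v3 = variant_config(3)
        assert (v3.n_conv_layers, v3.loss, v3.pooling) == (4, "NCC", False)
        v4 = variant_config(4)
        assert (v4.n_conv_layers, v4.loss, v4.pooling) == (8, "NCC", True)

    def test_unknown_variant_raises(self):
        with pytest.raises(ValueError):
            variant_config(5)

    def test_deeper_variant_has_more_parameters(self):
        n1 = build_regressor(1, seed=0).n_parameters()
        n4 = build_regressor(4, seed=0).n_parameters()
        assert n4 > n1


class TestRegressorShapes:
    def test_control_grid_resolution_256x512(self, rng):
        reg = build_regressor(1, seed=0)
        x = rng.random((1, 10, 256, 512))
        assert reg.forward(x).shape == (1, 2, 16, 32)

    def test_no_pooling_variant_strides_to_same_grid(self, rng):
        reg = build_regressor(3, seed=0)
        x = rng.random((1, 10, 64, 96))
        out = reg.forward(x)
        assert out.shape == (1, 2, 4, 6)

    def test_zero_weights_give_identity_transform(self, rng):
        net = RegistrationNetwork(1, image_shape=(32, 64), seed=0)
        fi = rng.random((1, 32, 64))
        mi = rng.random((1, 32, 64))
        masks = np.zeros((1, 4, 32, 64))
        dense = net.predict_field(PairBatch(fi, mi, masks, masks))
        assert np.abs(dense).max() == 0.0


class TestLosses:
    def test_ncc_identities(self, rng):
        img = rng.random((32, 32))
        assert ncc(img, img) == pytest.approx(1.0, abs=1e-12)
        assert ncc(img, 3.0 * img + 7.0) == pytest.approx(1.0, abs=1e-12)
        assert ncc(img, -img) == pytest.approx(-1.0, abs=1e-12)

    def test_ncc_zero_variance_is_zero_with_warning(self, rng):
        with pytest.warns(UserWarning):
            assert ncc(np.ones((8, 8)), rng.random((8, 8))) == 0.0

    def test_mse_identities(self, rng):
        img = rng.random((16, 16))
        assert mse(img, img) == 0.0
        assert mse(img, img + 1.0) == pytest.approx(1.0)
        other = rng.random((16, 16))
        assert mse(img, other) == pytest.approx(mse(other, img))

    def test_combined_loss_minimum_and_lambda_zero(self, rng):
        img = rng.random((16, 16))
        masks = {"bladder": (rng.random((16, 16)) > 0.6).astype(float)}
        cfg = variant_config(1)
        at_min = combined_loss(img, img, masks, masks, cfg, lambda_mask=1.0)
        assert at_min == pytest.approx(-1.0, abs=1e-6)
        plain = combined_loss(img, img * 2, masks, masks, cfg,
                              lambda_mask=0.0)
        assert plain == pytest.approx(-ncc(img, img * 2))

    def test_perturbing_warped_mask_increases_loss(self, rng):
        img = rng.random((16, 16))
        mask = np.zeros((16, 16))
        mask[4:12, 4:12] = 1.0
        cfg = variant_config(1)
        base = combined_loss(img, img, {"rectum": mask}, {"rectum": mask},
                             cfg)
        worse = mask.copy()
        worse[4:8, 4:8] = 0.0
        perturbed = combined_loss(img, img, {"rectum": mask},
                                  {"rectum": worse}, cfg)
        assert perturbed > base

    def test_soft_dice_range(self, rng):
        a = (rng.random((12, 12)) > 0.5).astype(float)
        assert soft_dice(a, a) == pytest.approx(1.0, abs=1e-5)
        assert 0.0 <= soft_dice(a, 1 - a) <= 0.2


class TestResampler:
    def test_zero_field_identity(self, rng):
        img = rng.random((16, 24))
        f = DisplacementField.zeros((16, 24))
        np.testing.assert_array_equal(resample(img, f, "image"), img)
        mask = (img > 0.5).astype(np.uint8)
        np.testing.assert_array_equal(resample(mask, f, "mask"), mask)

    def test_matches_bilinear_warp_on_integer_shifts(self, rng):
        from pelvreg.deform import warp_image
        img = rng.random((12, 18)) * 100
        f = DisplacementField(np.full((12, 18), 2.0), np.full((12, 18), -1.0))
        got = resample(img, f, "image")
        ref = warp_image(ImageSlice(img), f, "bilinear").pixels
        np.testing.assert_allclose(got, ref, atol=1e-9)

    def test_bicubic_reproduces_quadratic_at_half_pixel(self):
        # Keys bicubic (a=-0.5) reproduces quadratics exactly
        x = np.arange(24.0)
        img = np.tile(0.5 * x ** 2 - 3 * x + 1, (8, 1))
        f = DisplacementField(np.zeros((8, 24)), np.full((8, 24), 0.5))
        out = resample(img, f, "image")
        xs = x[2:-3] + 0.5
        expected = 0.5 * xs ** 2 - 3 * xs + 1
        np.testing.assert_allclose(out[4, 2:-3], expected, atol=1e-6)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            resample(rng.random((8, 8)), DisplacementField.zeros((4, 4)))


@pytest.fixture(scope="module")
def tiny_net():
    return RegistrationNetwork(1, image_shape=(32, 64), seed=3)


class TestRegisterPair:

    def test_zero_weight_model_returns_moving(self, tiny_net, small_pair,
                                              rng):
        px = rng.random((32, 64)) * 100
        fixed = ImageSlice(px)
        moving = ImageSlice(rng.random((32, 64)) * 100)
        fld, warped, _ = tiny_net.register(fixed, moving)
        assert np.abs(fld.dy).max() == 0.0
        np.testing.assert_array_equal(warped.pixels, moving.pixels)

    def test_inference_is_deterministic(self, tiny_net, rng):
        fixed = ImageSlice(rng.random((32, 64)))
        moving = ImageSlice(rng.random((32, 64)))
        f1, w1, _ = tiny_net.register(fixed, moving)
        f2, w2, _ = tiny_net.register(fixed, moving)
        np.testing.assert_array_equal(f1.dy, f2.dy)
        np.testing.assert_array_equal(w1.pixels, w2.pixels)

    def test_shape_mismatch_raises(self, tiny_net, rng):
        fixed = ImageSlice(rng.random((16, 16)))
        with pytest.raises(ValueError):
            tiny_net.register(fixed, fixed)


class TestGradientFlow:
    def test_every_parameter_gets_gradient(self, rng):
        """No dead branches: on a nondegenerate pair every trainable
        parameter receives a nonzero gradient (final layer randomized so
        gradients reach the hidden layers)."""
        net = RegistrationNetwork(1, image_shape=(32, 64), seed=1)
        for p in net.regressor.net.params():
            p += rng.normal(0, 0.05, p.shape)
        fi = rng.random((2, 32, 64))
        mi = rng.random((2, 32, 64))
        fm = (rng.random((2, 4, 32, 64)) > 0.7).astype(float)
        mm = (rng.random((2, 4, 32, 64)) > 0.7).astype(float)
        net.regressor.net.train(True)
        net.regressor.net.zero_grad()
        net.loss_and_grad(PairBatch(fi, mi, fm, mm))
        for layer in net.regressor.net.layers:
            for g in layer.grads():
                assert np.abs(g).max() > 0.0 or g.size == 0 or \
                    _is_bias_behind_bn(layer, g)


def _is_bias_behind_bn(layer, g):
    """Conv bias gradients are structurally ~0 when BN follows the conv."""
    from pelvreg import nn
    return isinstance(layer, nn.Conv2d) and g.shape == layer.b.shape


def test_true_field_beats_identity_on_simulated_pair(small_pair):
    """Evaluating the combined loss at the ground-truth registration
    field (the inverse of the simulated deformation, approximated by its
    negation) improves on the identity field."""
    from pelvreg.regnet import INPUT_MASKS, normalize_hu, image_loss
    from pelvreg._warp import warp_bilinear
    p = small_pair
    cfg = variant_config(1)
    fixed = normalize_hu(p.fixed.pixels)
    moving = normalize_hu(p.moving.pixels)
    fmasks = {o: p.fixed_masks[o].astype(float) for o in INPUT_MASKS}

    def loss_at(dy, dx):
        warped = warp_bicubic(moving, dy, dx)
        wmasks = {o: warp_bilinear(p.moving_masks[o].astype(float), dy, dx)
                  for o in INPUT_MASKS}
        return combined_loss(fixed, warped, fmasks, wmasks, cfg)

    identity = loss_at(np.zeros(p.fixed.shape), np.zeros(p.fixed.shape))
    truth = loss_at(-p.field.dy, -p.field.dx)
    assert truth < identity
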