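"""Deformation simulation: GRF statistics, modulation, warping."""

import numpy as np
import pytest

from pelvreg import deform
from pelvreg.deform import (DeformationConfig, DisplacementField, GRFParams,
                            compose_deformation, grf_covariance_matrix,
                            make_training_pair, sample_grf,
                            sample_organ_expansion, warp_image, warp_mask)
from pelvreg.io import ImageSlice, OrganMaskSet
from pelvreg import metrics


class TestGRF:
    def test_zero_sigma_gives_constant_mean(self):
        f = sample_grf((16, 16), GRFParams(mean=2.5, sigma=0.0), seed=0)
        np.testing.assert_array_equal(f, np.full((16, 16), 2.5))

    def test_deterministic_under_seed(self):
        p = GRFParams(sigma=10.0, correlation_length=5.0)
        a = sample_grf((32, 32), p, seed=9)
        b = sample_grf((32, 32), p, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_marginal_sd_matches(self):
        p = GRFParams(sigma=10.0, correlation_length=4.0)
        fields = np.stack([sample_grf((48, 48), p, seed=s)
                           for s in range(60)])
        assert fields.std() == pytest.approx(10.0, rel=0.05)
        assert fields.mean() == pytest.approx(0.0, abs=0.5)

    def test_autocorrelation_matches_kernel(self):
        ell = 6.0
        p = GRFParams(sigma=10.0, correlation_length=ell)
        fields = np.stack([sample_grf((48, 48), p, seed=s)
                           for s in range(80)])
        lag = int(ell)
        num = np.mean(fields[:, :, :-lag] * fields[:, :, lag:])
        rho = num / np.mean(fields ** 2)
        assert rho == pytest.approx(np.exp(-0.5), abs=0.05)

    def test_matches_dense_covariance_oracle(self):
        """Convolution synthesis agrees statistically with direct sampling
        from the Cholesky factor of the dense correlation matrix."""
        shape = (12, 12)
        p = GRFParams(sigma=4.0, correlation_length=3.0)
        M = grf_covariance_matrix(shape, p)
        assert M[0, 0] == pytest.approx(p.sigma ** 2)
        L = np.linalg.cholesky(M + 1e-9 * np.eye(M.shape[0]))
        rng = np.random.default_rng(0)
        ref = np.stack([(L @ rng.standard_normal(M.shape[0])).reshape(shape)
                        for _ in range(400)])
        got = np.stack([sample_grf(shape, p, seed=s) for s in range(400)])
        # same marginal SD and same lag-1 correlation
        assert got.std() == pytest.approx(ref.std(), rel=0.08)
        def lag1(f):
            return np.mean(f[:, :, :-1] * f[:, :, 1:]) / np.mean(f ** 2)
        assert lag1(got) == pytest.approx(lag1(ref), abs=0.03)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            GRFParams(sigma=-1.0)
        with pytest.raises(ValueError):
            GRFParams(correlation_length=0.0)
        with pytest.raises(ValueError):
            GRFParams(covariance_kind="matern")


class TestCorrectionMap:
    def test_all_body_no_bone_is_one_inside(self, cropped_slice):
        sl, _ = cropped_slice
        masks = OrganMaskSet({"body": np.ones(sl.shape, np.uint8),
                              "bone": np.zeros(sl.shape, np.uint8)})
        cmap = deform.build_correction_map(masks, DeformationConfig(),
                                           spacing_mm=sl.spacing_y)
        H, W = sl.shape
        assert cmap[H // 2, W // 2] == pytest.approx(1.0, abs=1e-6)

    def test_bone_and_air_levels(self, cropped_slice):
        from scipy import ndimage
        sl, masks = cropped_slice
        cfg = DeformationConfig()
        cmap = deform.build_correction_map(masks, cfg,
                                           spacing_mm=sl.spacing_y)
        smooth_px = int(np.ceil(cfg.correction_smoothing / sl.spacing_y))
        deep_bone = ndimage.binary_erosion(masks["bone"].astype(bool),
                                           iterations=3 * smooth_px)
        assert deep_bone.any()
        np.testing.assert_allclose(cmap[deep_bone], 0.3, atol=0.02)
        far_outside = ndimage.binary_erosion(~masks["body"].astype(bool),
                                             iterations=3 * smooth_px)
        np.testing.assert_allclose(cmap[far_outside], 0.0, atol=0.01)

    def test_missing_masks_raise(self):
        with pytest.raises(ValueError):
            deform.build_correction_map(
                OrganMaskSet({"body": np.ones((8, 8), np.uint8)}),
                DeformationConfig())


class TestOrganExpansion:
    def test_zero_amplitude_gives_zero_field(self):
        mask = np.zeros((32, 32), np.uint8)
        mask[10:20, 10:20] = 1
        f = sample_organ_expansion(mask, (0.0, 0.0), seed=0)
        assert np.abs(f.dy).max() == 0.0

    def test_empty_mask_warns_and_zeroes(self, caplog):
        f = sample_organ_expansion(np.zeros((16, 16), np.uint8), (100, 500),
                                   seed=0)
        assert np.abs(f.magnitude()).max() == 0.0

    def test_radial_direction_outward(self):
        """The physical motion (negated backward field) points away from
        the centroid at every organ pixel."""
        yy, xx = np.mgrid[0:64, 0:64]
        mask = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 15 ** 2).astype(np.uint8)
        f = sample_organ_expansion(mask, (500, 500), seed=1)
        inner = mask.astype(bool) & (f.magnitude() > 1e-3)
        uy = (yy - 32)[inner]
        ux = (xx - 32)[inner]
        r = np.hypot(uy, ux)
        sel = r > 3
        dot = (-f.dy[inner][sel] * uy[sel] - f.dx[inner][sel] * ux[sel]) \
            / (r[sel] * f.magnitude()[inner][sel])
        assert (dot > 0.95).all()

    def test_warped_mask_expands(self):
        yy, xx = np.mgrid[0:64, 0:64]
        mask = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 12 ** 2).astype(np.uint8)
        f = sample_organ_expansion(mask, (600, 600), seed=2)
        warped = warp_mask(mask, f)
        assert warped.sum() > mask.sum()


class TestCompose:
    def test_all_zero_config_gives_zero_field(self, cropped_slice):
        sl, masks = cropped_slice
        cfg = DeformationConfig(offset_sigma=0.0, bone_sigma=0.0,
                                rectum_amplitude_range=(0.0, 0.0),
                                bladder_amplitude_range=(0.0, 0.0))
        f = compose_deformation(sl.shape, masks, cfg, seed=0,
                                spacing_mm=sl.spacing_y)
        assert np.abs(f.magnitude()).max() == 0.0

    def test_deterministic(self, cropped_slice):
        sl, masks = cropped_slice
        a = compose_deformation(sl.shape, masks, DeformationConfig(), seed=5,
                                spacing_mm=sl.spacing_y)
        b = compose_deformation(sl.shape, masks, DeformationConfig(), seed=5,
                                spacing_mm=sl.spacing_y)
        np.testing.assert_array_equal(a.dy, b.dy)

    def test_amplitude_ordering_and_bone_suppression(self, cropped_slice):
        """Pooled over seeds, the mean displacement is ordered
        rectum > bladder > bone, and bone stays strongly suppressed.
        (The per-seed ordering fraction is a statistical property and is
        checked at its stated sample size in the acceptance suite.)"""
        from scipy import ndimage
        sl, masks = cropped_slice
        bone_in = ndimage.binary_erosion(masks["bone"].astype(bool),
                                         iterations=8)
        mr, mb, mbone = [], [], []
        for s in range(20):
            f = compose_deformation(sl.shape, masks, DeformationConfig(),
                                    seed=s, spacing_mm=sl.spacing_y)
            mag = f.magnitude()
            mr.append(mag[masks["rectum"].astype(bool)].mean())
            mb.append(mag[masks["bladder"].astype(bool)].mean())
            mbone.append(mag[bone_in].mean())
        assert np.mean(mr) > np.mean(mb) > np.mean(mbone)
        assert np.mean(mbone) < 0.3 * np.mean(mb)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            DeformationConfig(bone_sigma=20.0)
        with pytest.raises(ValueError):
            DeformationConfig(rectum_amplitude_range=(500.0, 100.0))


class TestWarping:
    def test_zero_field_identity(self, cropped_slice):
        sl, masks = cropped_slice
        zero = DisplacementField.zeros(sl.shape)
        out = warp_image(sl, zero)
        np.testing.assert_array_equal(out.pixels, sl.pixels)
        np.testing.assert_array_equal(warp_mask(masks["bladder"], zero),
                                      masks["bladder"])

    def test_integer_shift_indexes_exactly(self, rng):
        img = ImageSlice(rng.random((12, 16)) * 100)
        f = DisplacementField(np.zeros((12, 16)), np.ones((12, 16)))
        out = warp_image(img, f)
        np.testing.assert_array_equal(out.pixels[:, :-1], img.pixels[:, 1:])
        np.testing.assert_array_equal(out.pixels[:, -1], img.pixels[:, -1])

    def test_integer_shift_on_mask(self, rng):
        mask = (rng.random((12, 16)) > 0.5).astype(np.uint8)
        f = DisplacementField(np.ones((12, 16)), np.zeros((12, 16)))
        out = warp_mask(mask, f)
        np.testing.assert_array_equal(out[:-1], mask[1:])

    def test_half_pixel_shift_on_ramp(self):
        ramp = np.tile(np.arange(16.0), (8, 1))
        f = DisplacementField(np.zeros((8, 16)), np.full((8, 16), 0.5))
        out = warp_image(ImageSlice(ramp), f)
        np.testing.assert_allclose(out.pixels[:, :-1],
                                   ramp[:, :-1] + 0.5, atol=1e-12)

    def test_bilinear_linearity(self, rng):
        a = rng.random((10, 10))
        b = rng.random((10, 10))
        f = DisplacementField(rng.normal(0, 1, (10, 10)),
                              rng.normal(0, 1, (10, 10)))
        lhs = warp_image(ImageSlice(2 * a + 3 * b), f).pixels
        rhs = 2 * warp_image(ImageSlice(a), f).pixels \
            + 3 * warp_image(ImageSlice(b), f).pixels
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_mask_warp_is_binary(self, rng):
        mask = (rng.random((20, 20)) > 0.5).astype(np.uint8)
        f = DisplacementField(rng.normal(0, 3, (20, 20)),
                              rng.normal(0, 3, (20, 20)))
        out = warp_mask(mask, f)
        assert set(np.unique(out)) <= {0, 1}

    def test_shape_mismatch_raises(self, cropped_slice):
        sl, masks = cropped_slice
        with pytest.raises(ValueError):
            warp_image(sl, DisplacementField.zeros((8, 8)))
        with pytest.raises(ValueError):
            warp_mask(masks["bone"], DisplacementField.zeros((8, 8)))


class TestTrainingPair:
    def test_reproducible(self, cropped_slice):
        sl, masks = cropped_slice
        p1 = make_training_pair(sl, masks, DeformationConfig(), seed=3)
        p2 = make_training_pair(sl, masks, DeformationConfig(), seed=3)
        np.testing.assert_array_equal(p1.moving.pixels, p2.moving.pixels)

    def test_bone_barely_moves_rectum_moves_most(self, cropped_slice):
        sl, masks = cropped_slice
        bone_d, rect_d = [], []
        for s in range(5):
            p = make_training_pair(sl, masks, DeformationConfig(), seed=s)
            bone_d.append(metrics.dice(p.fixed_masks["bone"],
                                       p.moving_masks["bone"]))
            rect_d.append(metrics.dice(p.fixed_masks["rectum"],
                                       p.moving_masks["rectum"]))
        assert np.mean(bone_d) >= 0.95
        assert np.mean(rect_d) < np.mean(bone_d)
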