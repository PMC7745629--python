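"""Occlusion perturbation mapping: patch filling, map construction against a
naive oracle, sensitivity variants and overlay rendering."""

import numpy as np
import pytest

from retmap import occlusion as occ
from retmap import registration as reg
from retmap import regressor as rgr

from .conftest import make_constant_image, make_untrained_ensemble

SMALL_ARCH = rgr.Architecture(conv_channels=(2, 4), dense_width=4,
                              input_shape=(32, 16))


def small_image(seed=0, height=64, width=48):
    rng = np.random.default_rng(seed)
    pixels = rng.integers(0, 256, size=(height, width), dtype=np.uint8)
    return reg.BScanImage(pixels=pixels, fovea_col=width // 2,
                          lateral_scale_mm_per_px=0.015,
                          axial_scale_mm_per_px=0.0039,
                          patient_id="P", eye_id="OD", volume_id="V")


def small_spec():
    return reg.WindowSpec(0.0, width_px=16, height_px=32)


def naive_map(ensemble, image, spec, cfg):
    """Independent per-pixel reference: occlude the full image, re-extract
    the fixed-placement window, predict, one center at a time."""
    img = image.pixels.astype(float)
    r0, c0 = reg.window_placement(image, spec)
    h, w = img.shape
    wh, ww = spec.height_px, spec.width_px
    base = rgr.predict_rit(ensemble, img[r0:r0 + wh, c0:c0 + ww] / 255.0)
    rows = np.arange(0, h, cfg.stride_px)
    cols = np.arange(0, w, cfg.stride_px)
    delta = np.zeros((len(rows), len(cols)))
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            perturbed = occ.occlude_patch(img, (int(r), int(c)), cfg)
            window = perturbed[r0:r0 + wh, c0:c0 + ww] / 255.0
            delta[i, j] = rgr.predict_rit(ensemble, window) - base
    return delta


class TestOccludePatch:
    def test_constant_image_mean_fill_identity(self):
        img = np.full((20, 20), 37.0)
        out = occ.occlude_patch(img, (10, 10), occ.OcclusionConfig())
        np.testing.assert_array_equal(out, img)

    def test_mean_of_checkerboard(self):
        img = np.array([[0.0, 255.0], [0.0, 255.0]])
        cfg = occ.OcclusionConfig(patch_w_px=2, patch_h_px=2)
        out = occ.occlude_patch(img, (1, 1), cfg)
        np.testing.assert_array_equal(out, np.full((2, 2), 127.5))

    def test_zero_fill_complement_untouched(self):
        img = np.arange(100.0).reshape(10, 10)
        cfg = occ.OcclusionConfig(patch_w_px=4, patch_h_px=2, fill="zero")
        out = occ.occlude_patch(img, (5, 5), cfg)
        assert (out[4:6, 3:7] == 0).all()
        mask = np.ones_like(img, dtype=bool)
        mask[4:6, 3:7] = False
        np.testing.assert_array_equal(out[mask], img[mask])

    def test_border_crop_statistics(self):
        img = np.arange(36.0).reshape(6, 6)
        cfg = occ.OcclusionConfig(patch_w_px=4, patch_h_px=4)
        out = occ.occlude_patch(img, (0, 0), cfg)
        cropped = img[0:2, 0:2]  # patch cropped at the top-left corner
        assert (out[0:2, 0:2] == cropped.mean()).all()

    def test_center_outside_error(self):
        with pytest.raises(occ.OcclusionRangeError):
            occ.occlude_patch(np.zeros((5, 5)), (7, 0),
                              occ.OcclusionConfig())

    def test_permute_preserves_multiset_and_is_seeded(self):
        img = np.arange(64.0).reshape(8, 8)
        cfg = occ.OcclusionConfig(patch_w_px=4, patch_h_px=4, fill="permute",
                                  permute_seed=5)
        out1 = occ.occlude_patch(img, (4, 4), cfg)
        out2 = occ.occlude_patch(img, (4, 4), cfg)
        np.testing.assert_array_equal(out1, out2)
        patch_old = np.sort(img[2:6, 2:6].ravel())
        patch_new = np.sort(out1[2:6, 2:6].ravel())
        np.testing.assert_array_equal(patch_old, patch_new)

    def test_output_is_float_not_requantized(self):
        img = np.array([[0, 255], [0, 254]], dtype=np.uint8)
        cfg = occ.OcclusionConfig(patch_w_px=2, patch_h_px=2)
        out = occ.occlude_patch(img, (1, 1), cfg)
        assert out.dtype == np.float64
        assert (out == 127.25).all()


class TestOcclusionMap:
    def test_constant_image_zero_map(self):
        image = make_constant_image(90, height=64, width=48, fovea_col=24)
        ens = make_untrained_ensemble(SMALL_ARCH)
        omap = occ.occlusion_map(ens, image, small_spec(),
                                 occ.OcclusionConfig(stride_px=2))
        np.testing.assert_array_equal(omap.delta_rit_minutes, 0.0)

    def test_out_of_support_is_exact_zero_and_unevaluated(self):
        image = small_image(1)
        ens = make_untrained_ensemble(SMALL_ARCH)
        cfg = occ.OcclusionConfig(patch_w_px=4, patch_h_px=4)
        omap = occ.occlusion_map(ens, image, small_spec(), cfg)
        r0, c0 = omap.window_origin
        far = ~omap.evaluated
        assert far.any()
        assert (omap.delta_rit_minutes[far] == 0).all()
        # any evaluated center's patch must intersect the window footprint
        rows, cols = np.where(omap.evaluated)
        for r, c in zip(omap.rows[rows], omap.cols[cols]):
            assert (r0 - 2 <= r < r0 + 32 + 2) and (c0 - 2 <= c < c0 + 16 + 2)

    @pytest.mark.parametrize("fill", ["mean", "zero", "permute"])
    def test_matches_naive_oracle(self, fill):
        image = small_image(2)
        ens = make_untrained_ensemble(SMALL_ARCH, n=2)
        cfg = occ.OcclusionConfig(patch_w_px=6, patch_h_px=4, fill=fill,
                                  stride_px=3, permute_seed=9)
        omap = occ.occlusion_map(ens, image, small_spec(), cfg)
        expected = naive_map(ens, image, small_spec(), cfg)
        np.testing.assert_allclose(omap.delta_rit_minutes, expected,
                                   atol=1e-9)

    def test_delta_is_forty_times_normalized_difference(self):
        image = small_image(3)
        ens = make_untrained_ensemble(SMALL_ARCH)
        cfg = occ.OcclusionConfig(patch_w_px=6, patch_h_px=4)
        spec = small_spec()
        omap = occ.occlusion_map(ens, image, spec, cfg)
        r0, c0 = omap.window_origin
        center = (r0 + 16, c0 + 8)
        img = image.pixels.astype(float)
        perturbed = occ.occlude_patch(img, center, cfg)
        raw_base = float(ens.models[0].forward(
            (img[r0:r0 + 32, c0:c0 + 16] / 255.0)[None, None])[0, 0])
        raw_pert = float(ens.models[0].forward(
            (perturbed[r0:r0 + 32, c0:c0 + 16] / 255.0)[None, None])[0, 0])
        gi = center[0] // cfg.stride_px
        gj = center[1] // cfg.stride_px
        assert omap.delta_rit_minutes[gi, gj] == \
            pytest.approx(40.0 * (raw_pert - raw_base))

    def test_sliding_window_full_width(self):
        image = small_image(4)
        ens = make_untrained_ensemble(SMALL_ARCH)
        cfg = occ.OcclusionConfig(patch_w_px=4, patch_h_px=4, stride_px=4,
                                  inference_mode="sliding_window")
        omap = occ.occlusion_map(ens, image, small_spec(), cfg)
        assert omap.evaluated.all()

    def test_shape_mismatch_error(self):
        image = small_image(5)
        ens = make_untrained_ensemble(SMALL_ARCH)
        with pytest.raises(ValueError, match="does not match"):
            occ.occlusion_map(ens, image, reg.WindowSpec(0.0, 16, 64),
                              occ.OcclusionConfig())


class TestSensitivitySuite:
    def test_self_correlation_is_one(self):
        image = small_image(6)
        ens = make_untrained_ensemble(SMALL_ARCH)
        cfg = occ.OcclusionConfig(patch_w_px=4, patch_h_px=4, stride_px=2)
        omap = occ.occlusion_map(ens, image, small_spec(), cfg)
        from scipy import stats
        vals = np.abs(omap.delta_rit_minutes[omap.evaluated])
        assert stats.spearmanr(vals, vals).statistic == pytest.approx(1.0)

    def test_report_structure(self):
        image = small_image(7)
        ens = make_untrained_ensemble(SMALL_ARCH)
        cfg = occ.OcclusionConfig(patch_w_px=4, patch_h_px=4, stride_px=4)
        report = occ.sensitivity_suite(ens, [image], small_spec(), cfg)
        # 3 fills at base size + 2 extra sizes -> C(5,2) pairs
        assert len(report) == 10
        assert {"variant_a", "variant_b",
                "spearman_abs_delta"} <= set(report.columns)

    def test_constant_images_degenerate(self):
        image = make_constant_image(90, height=64, width=48, fovea_col=24)
        ens = make_untrained_ensemble(SMALL_ARCH)
        cfg = occ.OcclusionConfig(patch_w_px=4, patch_h_px=4, stride_px=4)
        report = occ.sensitivity_suite(ens, [image], small_spec(), cfg)
        assert report["degenerate"].all()
        assert report["spearman_abs_delta"].isna().all()


class TestRenderOverlay:
    def _map_for(self, image, delta):
        evaluated = np.ones_like(delta, dtype=bool)
        return occ.OcclusionMap(delta_rit_minutes=delta,
                                rows=np.arange(delta.shape[0]),
                                cols=np.arange(delta.shape[1]),
                                evaluated=evaluated,
                                baseline_rit_minutes=10.0,
                                config=occ.OcclusionConfig(),
                                window_origin=(0, 0),
                                image_shape=image.pixels.shape)

    def test_zero_map_identity(self):
        image = small_image(8)
        delta = np.zeros(image.pixels.shape)
        out = occ.render_overlay(self._map_for(image, delta), image)
        expected = np.stack([image.pixels] * 3, axis=-1)
        np.testing.assert_array_equal(out, expected)

    def test_positive_delta_is_red(self):
        image = small_image(9)
        delta = np.zeros(image.pixels.shape)
        delta[10, 10] = 2.0
        out = occ.render_overlay(self._map_for(image, delta), image)
        assert out[10, 10, 0] > out[10, 10, 2]

    def test_sign_flip_swaps_channels(self):
        image = small_image(10)
        delta = np.zeros(image.pixels.shape)
        delta[10, 10] = 2.0
        delta[20, 20] = -1.0
        out_pos = occ.render_overlay(self._map_for(image, delta), image)
        out_neg = occ.render_overlay(self._map_for(image, -delta), image)
        np.testing.assert_array_equal(out_pos[10, 10, 0], out_neg[10, 10, 2])
        np.testing.assert_array_equal(out_pos[20, 20, 2], out_neg[20, 20, 0])

    def test_misaligned_shapes_error(self):
        image = small_image(11)
        delta = np.zeros((10, 10))
        omap = self._map_for(image, delta)
        omap.image_shape = (10, 10)
        with pytest.raises(ValueError, match="shape"):
            occ.render_overlay(omap, image)
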