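import math

import numpy as np
import pytest

from terralabel import masking
from terralabel.io_core import RasterGrid, block_mean
from terralabel.masking import (MaskingConfig, build_cloud_mask, compute_cdi,
                                extend_shadow_ddt, finalize_mask, mask_scene)


def windowed_variance_oracle(x, window):
    """Brute-force population variance over window x window with reflect edges."""
    pad = window // 2
    xp = np.pad(x, pad, mode="symmetric")  # edge-repeating reflection
    out = np.empty_like(x, dtype=float)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            w = xp[i:i + window, j:j + window]
            out[i, j] = w.var()
    return out


def ray_cast_oracle(cloud, azimuth_deg, distance_m, pixel_size):
    """Per-pixel ray walk: p is shadow iff a cloud pixel lies at p minus the
    rounded anti-solar displacement for some whole-pixel step within range."""
    theta = math.radians((azimuth_deg + 180.0) % 360.0)
    de, dn = math.sin(theta), math.cos(theta)
    n_steps = int(math.floor(distance_m / pixel_size + 1e-9))
    nr, nc = cloud.shape
    out = np.zeros_like(cloud, dtype=bool)
    for r in range(nr):
        for c in range(nc):
            for t in range(1, n_steps + 1):
                dr, dc = round(-t * dn), round(t * de)
                rr, cc = r - dr, c - dc
                if 0 <= rr < nr and 0 <= cc < nc and cloud[rr, cc]:
                    out[r, c] = True
                    break
    return out


class TestCDI:
    def test_constant_bands_give_zero(self):
        g = lambda v: RasterGrid(np.full((9, 9), v), 20.0)
        cdi = compute_cdi(g(0.3), g(0.5), g(0.4), window=3)
        np.testing.assert_allclose(cdi.values, 0.0)

    def test_identical_ratio_fields_give_zero(self):
        rng = np.random.default_rng(1)
        b = rng.uniform(0.1, 0.5, size=(9, 9))
        b8a = RasterGrid(np.full((9, 9), 1.0), 20.0)
        cdi = compute_cdi(RasterGrid(b, 20.0), RasterGrid(b, 20.0), b8a, window=3)
        np.testing.assert_allclose(cdi.values, 0.0, atol=1e-12)

    def test_matches_formula_with_variance_oracle(self):
        rng = np.random.default_rng(2)
        b7 = rng.uniform(0.1, 0.6, size=(11, 11))
        b8 = rng.uniform(0.1, 0.6, size=(11, 11))
        b8a = rng.uniform(0.2, 0.8, size=(11, 11))
        cdi = compute_cdi(RasterGrid(b7, 20.0), RasterGrid(b8, 20.0),
                          RasterGrid(b8a, 20.0), window=5)
        v1 = windowed_variance_oracle(b7 / b8a, 5)
        v2 = windowed_variance_oracle(b8 / b8a, 5)
        expect = np.where(v1 + v2 > 0, (v2 - v1) / (v1 + v2), 0.0)
        np.testing.assert_allclose(cdi.values, expect, atol=1e-8)

    def test_constructed_ratio_variances_give_minus_half(self):
        # center pixel with V(r2) = 1 and V(r1) = 3 -> CDI = (1-3)/(1+3) = -0.5
        b8a = np.ones((3, 3))
        pat = np.array([[1.0, -1.0, 1.0], [-1.0, 1.0, -1.0], [1.0, -1.0, 0.0]])
        r2 = 5.0 + pat / pat.std()            # population variance exactly 1
        r1 = 5.0 + pat * (np.sqrt(3.0) / pat.std())   # variance exactly 3
        cdi = compute_cdi(RasterGrid(r1, 20.0), RasterGrid(r2, 20.0),
                          RasterGrid(b8a, 20.0), window=3)
        assert cdi.values[1, 1] == pytest.approx(-0.5, abs=1e-9)

    def test_zero_denominator_marked_invalid(self):
        b8a = np.ones((5, 5))
        b8a[2, 2] = 0.0
        cdi = compute_cdi(RasterGrid(np.ones((5, 5)), 20.0),
                          RasterGrid(np.ones((5, 5)), 20.0),
                          RasterGrid(b8a, 20.0), window=3)
        assert cdi.nodata[2, 2]
        assert np.isfinite(cdi.values).all()


class TestBuildCloudMask:
    def test_clear_scene_gives_empty_mask(self, rendered_scene):
        mask = build_cloud_mask(rendered_scene)
        assert not mask.values.any()

    def test_bright_building_excluded(self, cloudy_package):
        mask = build_cloud_mask(cloudy_package.scene)
        building20 = block_mean(cloudy_package.building_mask.astype(float), 2) > 0.5
        commission = (mask.values & building20).sum() / max(building20.sum(), 1)
        assert commission <= 0.05

    def test_cloud_recall_high(self, cloudy_package):
        mask = build_cloud_mask(cloudy_package.scene)
        cloud20 = block_mean(cloudy_package.cloud_mask.astype(float), 2) > 0.5
        recall = (mask.values & cloud20).sum() / cloud20.sum()
        assert recall >= 0.95

    def test_opening_removes_isolated_pixel(self):
        from scipy import ndimage
        toy = np.zeros((5, 5), bool)
        toy[2, 2] = True
        opened = ndimage.binary_opening(toy, structure=masking._disk(1))
        assert not opened.any()
        # and a solid 3x3 block survives
        toy2 = np.zeros((5, 5), bool)
        toy2[1:4, 1:4] = True
        opened2 = ndimage.binary_opening(toy2, structure=masking._disk(1))
        assert opened2[2, 2]

    def test_s2c_threshold_monotone_before_opening(self, cloudy_package):
        # lowering the threshold never removes pixels from the pre-opening mask
        scene = cloudy_package.scene
        masks = {}
        for thr in (0.5, 0.65, 0.8):
            cfg = MaskingConfig(s2c_threshold=thr, opening_radius=1)
            from terralabel.io_core import resample_nearest
            s2c = resample_nearest(scene.s2c, cfg.compute_pixel_size)
            masks[thr] = s2c.values >= thr
        assert np.all(masks[0.5] >= masks[0.65])
        assert np.all(masks[0.65] >= masks[0.8])


class TestShadowDDT:
    def test_empty_cloud_empty_shadow(self):
        cloud = RasterGrid(np.zeros((16, 16), bool), 20.0)
        assert not extend_shadow_ddt(cloud, 135.0).values.any()

    def test_single_pixel_sun_south_gives_250_pixel_strip_north(self):
        n = 300
        cloud = np.zeros((n, n), bool)
        cloud[n - 1, 150] = True
        shadow = extend_shadow_ddt(RasterGrid(cloud, 20.0), 180.0).values
        # 5000 m / 20 m = 250 one-pixel steps due north
        assert shadow.sum() == 250
        assert shadow[n - 251:n - 1, 150].all()

    def test_sweep_matches_ray_casting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(15):
            cloud = rng.random((64, 64)) < 0.01
            az = float(rng.uniform(0, 360))
            cfg = MaskingConfig(shadow_distance_m=300.0)
            got = extend_shadow_ddt(RasterGrid(cloud, 20.0), az, cfg).values
            expect = ray_cast_oracle(cloud, az, 300.0, 20.0)
            np.testing.assert_array_equal(got, expect)

    def test_every_shadow_pixel_within_range_of_cloud(self):
        rng = np.random.default_rng(7)
        cloud = rng.random((64, 64)) < 0.02
        az = 217.0
        cfg = MaskingConfig(shadow_distance_m=600.0)
        shadow = extend_shadow_ddt(RasterGrid(cloud, 20.0), az, cfg).values
        offsets = masking.shadow_offsets(az, 600.0, 20.0)
        rr, cc = np.nonzero(shadow)
        for r, c in zip(rr, cc):
            assert any(0 <= r - dr < 64 and 0 <= c - dc < 64
                       and cloud[r - dr, c - dc] for dr, dc in offsets)


class TestFinalize:
    def test_empty_masks_give_empty_final(self):
        z = RasterGrid(np.zeros((10, 10), bool), 20.0)
        fm = finalize_mask(z, z)
        assert not fm.combined_final.values.any()
        assert fm.combined_final.pixel_size == 100.0

    def test_single_pixel_flags_single_cell(self):
        cloud = np.zeros((10, 10), bool)
        cloud[7, 2] = True
        fm = finalize_mask(RasterGrid(cloud, 20.0),
                           RasterGrid(np.zeros((10, 10), bool), 20.0))
        assert fm.combined_final.values.sum() == 1

    def test_flagged_area_never_decreases(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            cloud = rng.random((10, 10)) < 0.1
            shadow = rng.random((10, 10)) < 0.1
            fm = finalize_mask(RasterGrid(cloud, 20.0), RasterGrid(shadow, 20.0))
            area20 = (cloud | shadow).sum() * 20.0 ** 2
            area100 = fm.combined_final.values.sum() * 100.0 ** 2
            assert area100 >= area20

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(masking.MaskingError):
            finalize_mask(RasterGrid(np.zeros((10, 10), bool), 20.0),
                          RasterGrid(np.zeros((5, 5), bool), 20.0))


def test_mask_scene_covers_synthetic_contamination(cloudy_package):
    fm = mask_scene(cloudy_package.scene)
    contam20 = block_mean(
        cloudy_package.truth_contamination.values.astype(float), 2) > 0.5
    flagged = fm.cloud.values | fm.shadow.values
    recall = (flagged & contam20).sum() / contam20.sum()
    assert recall >= 0.95
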