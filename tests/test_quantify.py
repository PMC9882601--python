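"""Segmentation and thickness quantification: shortest-path contracts,
pixel-to-micron scaling, ONH masking, fovea finding, phantom recovery."""

import numpy as np
import pytest

from roboct.acquisition import NoiseConfig, acquire, make_scan_pattern
from roboct.phantom import PathologySpec, add_pathology, build_phantom
from roboct.quantify import (
    FoveaDetectionError,
    build_thickness_map,
    central_foveal_thickness,
    find_fovea,
    segment_bscan,
    segment_surface,
    thickness_from_pixels,
)


def _two_band_image(n_rows=120, n_cols=80, boundary=None):
    """Dark-above/bright-below synthetic image with a known boundary."""
    if boundary is None:
        boundary = 50 + 10 * np.sin(np.linspace(0, 2 * np.pi, n_cols))
    img = np.full((n_rows, n_cols), 0.05)
    rows = np.arange(n_rows)[:, None]
    img[rows >= np.asarray(boundary)[None, :]] = 0.8
    return img, np.asarray(boundary, float)


class TestSegmentSurface:
    def test_recovers_known_boundary_within_half_pixel(self):
        img, boundary = _two_band_image()
        path = segment_surface(img, "dark_to_bright")
        assert np.all(np.abs(path - boundary) <= 1.0)
        assert np.sqrt(np.mean((path - boundary) ** 2)) < 0.5

    def test_constant_image_flat_path_lowest_row(self):
        path = segment_surface(np.full((40, 30), 0.3), "dark_to_bright")
        assert np.allclose(path, 0.0)

    def test_step_beyond_limit_cannot_be_followed_immediately(self):
        """A 4 px jump between adjacent columns exceeds the +/-2 px step
        limit, so the path needs more than one column to catch up."""
        n_cols = 40
        boundary = np.full(n_cols, 30.0)
        boundary[20:] = 34.0 + 2.0  # jump of 6 px
        img, _ = _two_band_image(80, n_cols, boundary)
        path = segment_surface(img, "dark_to_bright")
        assert np.all(np.abs(np.diff(path)) <= 2.5)  # step limit + refinement
        assert abs(path[20] - boundary[20]) > 0.5  # deviates at the jump
        assert abs(path[-1] - boundary[-1]) <= 1.0  # recovers by the end

    def test_empty_band_rejected(self):
        img, _ = _two_band_image()
        with pytest.raises(ValueError, match="empty"):
            segment_surface(img, "dark_to_bright", search_band=(50, 50))

    def test_translation_equivariance(self):
        img, _ = _two_band_image()
        k = 7
        shifted = np.roll(img, k, axis=0)
        shifted[:k] = img[0]
        a = segment_surface(img, "dark_to_bright")
        b = segment_surface(shifted, "dark_to_bright")
        assert np.allclose(b, a + k, atol=1e-9)


class TestSegmentBscan:
    def test_noiseless_phantom_within_one_pixel(
        self, healthy_phantom, still_noiseless_volume
    ):
        vol = still_noiseless_volume
        j = 30
        ilm, rpe, ok, conf = segment_bscan(vol.intensity[:, :, j])
        assert ok
        n_a, n_b = vol.intensity.shape[1:]
        da, db = vol.lateral_pitch_mm()
        x = (np.arange(n_a) - (n_a - 1) / 2) * da
        y = (j - (n_b - 1) / 2) * db
        pitch_t = vol.depth_pixel_pitch_tissue_um
        ilm_true = healthy_phantom.ilm(x, y) / pitch_t + vol.z_reference_px
        rpe_true = healthy_phantom.rpe(x, y) / pitch_t + vol.z_reference_px
        out = ~healthy_phantom.mask(x, np.full_like(x, y))
        # exclude a guard band around the ONH where paths bridge the disc
        assert np.percentile(np.abs(ilm[out] - ilm_true[out]), 95) < 1.5
        assert np.percentile(np.abs(rpe[out] - rpe_true[out]), 95) < 1.5

    def test_all_dark_image_fails_qc(self):
        _, _, ok, _ = segment_bscan(np.zeros((128, 64)))
        assert not ok

    def test_onh_columns_have_low_rpe_confidence(
        self, healthy_phantom, still_noiseless_volume
    ):
        vol = still_noiseless_volume
        n_a, n_b = vol.intensity.shape[1:]
        j = n_b // 2   # slow-axis centre crosses the ONH
        _, _, _, conf = segment_bscan(vol.intensity[:, :, j])
        da, _ = vol.lateral_pitch_mm()
        x = (np.arange(n_a) - (n_a - 1) / 2) * da
        in_onh = np.abs(x - 4.0) < 0.6
        assert np.median(conf[in_onh]) < 0.5 * np.median(conf[~in_onh])


class TestThicknessScaling:
    def test_zero_and_linear(self):
        assert thickness_from_pixels(0.0, 3.71) == 0.0
        assert thickness_from_pixels(1.37, 1.0) == pytest.approx(1.0)

    def test_100px_at_3p71(self):
        assert thickness_from_pixels(100, 3.71) == pytest.approx(270.8, abs=0.05)

    def test_homogeneous(self, rng):
        px = rng.uniform(0, 200, 20)
        a = thickness_from_pixels(px, 3.71)
        b = thickness_from_pixels(2 * px, 3.71)
        assert np.allclose(b, 2 * a)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            thickness_from_pixels(-1.0, 3.71)


class TestThicknessMap:
    def test_healthy_map_matches_ground_truth(
        self, healthy_phantom, still_noiseless_volume
    ):
        tmap = build_thickness_map(still_noiseless_volume)
        assert tmap.usable
        n_a, n_b = tmap.thickness_um.shape
        ii, jj = np.meshgrid(np.arange(n_a), np.arange(n_b), indexing="ij")
        x = (ii - (n_a - 1) / 2) * tmap.pitch_mm[0]
        y = (jj - (n_b - 1) / 2) * tmap.pitch_mm[1]
        truth = healthy_phantom.thickness(x, y)
        sel = ~tmap.mask & np.isfinite(truth)
        rms = np.sqrt(np.mean((tmap.thickness_um[sel] - truth[sel]) ** 2))
        assert rms < 5.0

    def test_onh_disc_detected_at_true_location(self, still_noiseless_volume):
        tmap = build_thickness_map(still_noiseless_volume)
        (ci, cj), radius = tmap.meta["onh_disc"]
        n_a, n_b = tmap.thickness_um.shape
        x = (ci - (n_a - 1) / 2) * tmap.pitch_mm[0]
        y = (cj - (n_b - 1) / 2) * tmap.pitch_mm[1]
        # the disc straddles the FOV edge, so the fitted centre is pulled
        # inward; it must still cover the true disc
        assert abs(y) < 0.5
        assert x + radius > 4.0
        assert 0.5 < radius < 1.6

    def test_phantom_without_onh_has_empty_mask(self):
        from roboct.phantom import PhantomConfig

        ph = build_phantom(PhantomConfig(onh_center_mm=(8.0, 8.0)), seed=2)
        pat = make_scan_pattern("volume", n_ascans_per_bscan=120, n_bscans=24)
        vol = acquire(ph, None, pat,
                      NoiseConfig(speckle=False, noise_floor_sd=0.0), n_depth=384)
        tmap = build_thickness_map(vol)
        assert not tmap.onh_mask.any()

    def test_macular_hole_wall_thickness_recovered(self, healthy_phantom):
        """At the clinical fast-axis density (900 A-scans over 30 deg) the
        +/-2 px per-column step limit is wide enough for the path to follow
        the hole wall down to the 50 um residual tissue."""
        ph = add_pathology(
            healthy_phantom,
            PathologySpec("macular_hole", (0.0, 0.0), extent=0.6, magnitude=50.0),
        )
        pat = make_scan_pattern("volume", n_ascans_per_bscan=900, n_bscans=17)
        vol = acquire(ph, None, pat,
                      NoiseConfig(speckle=False, noise_floor_sd=0.0), n_depth=512)
        j = 8   # central B-scan, y = 0
        ilm, rpe, ok, _ = segment_bscan(vol.intensity[:, :, j])
        assert ok
        da, _ = vol.lateral_pitch_mm()
        x = (np.arange(900) - 899 / 2) * da
        wall = (np.abs(x) > 0.33) & (np.abs(x) < 0.42)
        thick = (rpe - ilm) * vol.depth_pixel_pitch_air_um / 1.37
        assert np.median(thick[wall]) == pytest.approx(50.0, abs=10.0)


class TestFovea:
    def test_healthy_fovea_within_02mm(self, still_noiseless_volume):
        tmap = build_thickness_map(still_noiseless_volume)
        i, j = find_fovea(tmap)
        n_a, n_b = tmap.thickness_um.shape
        x = (i - (n_a - 1) / 2) * tmap.pitch_mm[0]
        y = (j - (n_b - 1) / 2) * tmap.pitch_mm[1]
        assert np.hypot(x, y) < 0.2

    def test_override_returned_verbatim(self, still_noiseless_volume):
        tmap = build_thickness_map(still_noiseless_volume)
        assert find_fovea(tmap, override=(10, 11)) == (10, 11)

    def test_filled_pit_requires_override(self, healthy_phantom):
        ph = add_pathology(
            healthy_phantom,
            PathologySpec("cystoid_edema", (0.0, 0.0), extent=3.0, magnitude=60.0),
        )
        pat = make_scan_pattern("volume", n_ascans_per_bscan=120, n_bscans=24)
        vol = acquire(ph, None, pat,
                      NoiseConfig(speckle=False, noise_floor_sd=0.0), n_depth=512)
        tmap = build_thickness_map(vol)
        with pytest.raises(FoveaDetectionError):
            find_fovea(tmap, search_radius_mm=1.0)


class TestCentralFovealThickness:
    def test_uniform_map(self):
        from roboct.quantify import ThicknessMap

        tmap = ThicknessMap(
            thickness_um=np.full((101, 101), 300.0),
            onh_mask=np.zeros((101, 101), bool),
            qc_mask=np.zeros((101, 101), bool),
            pitch_mm=(0.05, 0.05),
        )
        assert central_foveal_thickness(tmap, (50, 50)) == pytest.approx(300.0)

    def test_healthy_phantom_disc_mean(self, healthy_phantom, still_noiseless_volume):
        tmap = build_thickness_map(still_noiseless_volume)
        cft = central_foveal_thickness(tmap, find_fovea(tmap))
        xs = np.linspace(-0.5, 0.5, 101)
        xx, yy = np.meshgrid(xs, xs)
        disc = np.hypot(xx, yy) <= 0.5
        truth = healthy_phantom.thickness(xx, yy)[disc].mean()
        assert cft == pytest.approx(truth, abs=5.0)

    def test_masked_disc_rejected(self):
        from roboct.quantify import ThicknessMap

        mask = np.zeros((101, 101), bool)
        mask[:60] = True
        tmap = ThicknessMap(
            thickness_um=np.full((101, 101), 300.0),
            onh_mask=mask,
            qc_mask=np.zeros((101, 101), bool),
            pitch_mm=(0.05, 0.05),
        )
        with pytest.raises(ValueError, match="coverage"):
            central_foveal_thickness(tmap, (55, 50))


class TestEndToEnd:
    def test_healthy_still_eye_280um(self, still_speckle_volume):
        """simulate -> segment -> central foveal thickness recovers the
        280 um design value within 5 um, speckle included."""
        tmap = build_thickness_map(still_speckle_volume)
        cft = central_foveal_thickness(tmap, find_fovea(tmap))
        assert cft == pytest.approx(280.0, abs=5.0)
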