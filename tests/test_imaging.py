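"""Tests for focus detection, average panels, radial profiles and colocalization."""

import math

import numpy as np
import pytest

from ervkit.imaging import (
    AverageImagePanel,
    Focus,
    ImageStack,
    average_signal_at_foci,
    detect_foci,
    droplet_partition_ratio,
    fraction_within,
    nearest_cluster_distance,
    pixel_coloc_stats,
    radial_profile,
    random_centered_panel,
    spearman_coloc,
    DistanceRecord,
)
from ervkit.simulate import simulate_droplet_image, simulate_two_channel_stack


def stack_with_spot(center=(32.0, 30.0, 5.0), sigma=1.23, amp=1000.0, dims=(11, 64, 64)):
    """One noiseless Gaussian spot; sigma in px (1.23 px = 80 nm at 65 nm/px)."""
    nz, ny, nx = dims
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    cx, cy, cz = center
    data = 100.0 + amp * np.exp(
        -(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2) + (zz - cz) ** 2 / 2.0)
    )
    return ImageStack(data, pixel_size_xy=65.0, z_step=300.0)


class TestDetectFoci:
    def test_single_spot_centroid_within_half_pixel(self):
        center = (32.3, 30.7, 5.2)
        (f,) = detect_foci(stack_with_spot(center), threshold=400, min_voxels=4)
        assert abs(f.x - center[0]) <= 0.5
        assert abs(f.y - center[1]) <= 0.5
        assert abs(f.z - center[2]) <= 0.5

    def test_uniform_stack_below_threshold_gives_no_foci(self):
        stack = ImageStack(np.full((5, 32, 32), 50.0), 65.0, 300.0)
        assert detect_foci(stack, threshold=100, min_voxels=1) == []

    def test_two_spots_10px_apart_are_two_foci(self):
        a = stack_with_spot((20.0, 30.0, 5.0))
        b = stack_with_spot((30.0, 30.0, 5.0))
        stack = ImageStack(a.data + b.data - 100.0, 65.0, 300.0)
        assert len(detect_foci(stack, threshold=400, min_voxels=4)) == 2

    def test_focus_count_monotone_in_threshold_for_resolved_spots(self):
        # monotonicity holds when spots are well separated (merging of nearby
        # components at low thresholds is the one generic exception)
        nz, ny, nx = 9, 128, 128
        zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
        data = np.full((nz, ny, nx), 100.0)
        rng = np.random.default_rng(41)
        for gy in range(20, 128, 28):
            for gx in range(20, 128, 28):
                amp = rng.uniform(300, 1000)
                data += amp * np.exp(
                    -(((xx - gx) ** 2 + (yy - gy) ** 2) / (2 * 1.5**2)
                      + (zz - 4) ** 2 / 2.0)
                )
        stack = ImageStack(data, 65.0, 300.0)
        counts = [
            len(detect_foci(stack, threshold=t, min_voxels=1))
            for t in (150, 250, 400, 700, 1200)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_min_voxels_drops_small_components(self):
        data = np.full((3, 16, 16), 0.0)
        data[1, 5, 5] = 10.0
        stack = ImageStack(data, 65.0, 300.0)
        assert detect_foci(stack, threshold=5, min_voxels=2) == []
        assert len(detect_foci(stack, threshold=5, min_voxels=1)) == 1


class TestAveragePanels:
    def test_self_centered_panel_peaks_at_center(self):
        stack = stack_with_spot()
        foci = detect_foci(stack, threshold=400, min_voxels=4)
        panel = average_signal_at_foci(stack, foci)
        c = panel.side // 2
        assert np.unravel_index(np.argmax(panel.data), panel.data.shape) == (c, c)

    def test_constant_signal_gives_constant_panel(self):
        stack = ImageStack(np.full((11, 64, 64), 7.0), 65.0, 300.0)
        foci = [Focus(0, (32.0, 32.0, 5.0), 1, 7.0)]
        panel = average_signal_at_foci(stack, foci)
        assert np.allclose(panel.data, 7.0)

    def test_if_spots_at_fixed_offset_shift_panel_peak(self):
        fish_foci = [
            Focus(i, (float(x), float(y), 5.0), 1, 1.0)
            for i, (x, y) in enumerate([(20, 20), (40, 20), (20, 44), (40, 44)])
        ]
        nz, ny, nx = 11, 64, 64
        data = np.zeros((nz, ny, nx))
        zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
        for f in fish_foci:  # IF spot 3 px right of every FISH focus
            data += 100 * np.exp(
                -(((xx - f.x - 3) ** 2 + (yy - f.y) ** 2) / (2 * 1.5**2)
                  + (zz - f.z) ** 2 / 2.0)
            )
        panel = average_signal_at_foci(ImageStack(data, 65.0, 300.0), fish_foci)
        c = panel.side // 2
        peak = np.unravel_index(np.argmax(panel.data), panel.data.shape)
        assert peak == (c, c + 3)

    def test_panel_averaging_is_linear(self):
        rng = np.random.default_rng(0)
        a = ImageStack(rng.uniform(0, 1, (7, 48, 48)), 65.0, 300.0)
        b = ImageStack(rng.uniform(0, 1, (7, 48, 48)), 65.0, 300.0)
        combo = ImageStack(2.0 * a.data + 3.0 * b.data, 65.0, 300.0)
        foci = [Focus(0, (24.0, 24.0, 3.0), 1, 1.0), Focus(1, (20.0, 30.0, 4.0), 1, 1.0)]
        pa = average_signal_at_foci(a, foci).data
        pb = average_signal_at_foci(b, foci).data
        pc = average_signal_at_foci(combo, foci).data
        assert np.allclose(pc, 2.0 * pa + 3.0 * pb)

    def test_all_border_foci_is_an_error(self):
        stack = ImageStack(np.zeros((5, 64, 64)), 65.0, 300.0)
        with pytest.raises(ValueError, match="border"):
            average_signal_at_foci(stack, [Focus(0, (1.0, 1.0, 2.0), 1, 0.0)])

    def test_no_foci_is_an_error(self):
        stack = ImageStack(np.zeros((5, 64, 64)), 65.0, 300.0)
        with pytest.raises(ValueError, match="focus"):
            average_signal_at_foci(stack, [])


class TestRandomPanels:
    def test_same_seed_gives_identical_panels(self):
        sim = simulate_two_channel_stack(43, n_foci=30, dims=(11, 256, 256))
        p1 = random_centered_panel(sim.if_channel, sim.nucleus_mask, n=50, seed=7)
        p2 = random_centered_panel(sim.if_channel, sim.nucleus_mask, n=50, seed=7)
        assert np.array_equal(p1.data, p2.data)

    def test_constant_signal_gives_flat_panel(self):
        stack = ImageStack(np.full((7, 64, 64), 3.0), 65.0, 300.0)
        mask = np.ones((7, 64, 64), bool)
        panel = random_centered_panel(stack, mask, n=20, seed=1)
        assert np.allclose(panel.data, 3.0)

    def test_uncorrelated_spots_give_flat_panel_within_3se(self):
        sim = simulate_two_channel_stack(44, n_foci=120, coloc_fraction=0.0,
                                         noise_sd=0.0, dims=(11, 320, 320))
        panel = random_centered_panel(sim.if_channel, sim.nucleus_mask, n=500, seed=2)
        values = panel.data.ravel()
        se = values.std(ddof=1) / math.sqrt(len(values))
        # no radial structure: center pixel consistent with the global mean
        c = panel.side // 2
        assert abs(panel.data[c, c] - values.mean()) <= 3 * values.std(ddof=1)

    def test_empty_mask_is_an_error(self):
        stack = ImageStack(np.zeros((5, 64, 64)), 65.0, 300.0)
        with pytest.raises(ValueError, match="mask"):
            random_centered_panel(stack, np.zeros((5, 64, 64), bool), n=5, seed=0)


class TestRadialProfile:
    def test_gaussian_panel_matches_closed_form_within_5pct(self, gaussian_panel):
        panel, sigma, amp = gaussian_panel
        prof = radial_profile(panel, n_bins=8)
        analytic = amp * np.exp(-((prof.r / panel.pixel_size_xy) ** 2) / (2 * sigma**2))
        assert np.all(np.abs(prof.intensity - analytic) / analytic < 0.05)

    def test_constant_panel_gives_flat_profile(self):
        panel = AverageImagePanel(np.full((23, 23), 4.0), 1, 65.0)
        prof = radial_profile(panel, n_bins=8)
        assert np.allclose(prof.intensity, 4.0)

    def test_single_center_pixel_signal_only_in_first_bin(self):
        data = np.zeros((23, 23))
        data[11, 11] = 10.0
        prof = radial_profile(AverageImagePanel(data, 1, 65.0), n_bins=8)
        assert prof.intensity[0] > 0
        assert np.all(prof.intensity[1:] == 0)

    def test_too_many_bins_rejected(self):
        panel = AverageImagePanel(np.zeros((23, 23)), 1, 65.0)
        with pytest.raises(ValueError, match="n_bins"):
            radial_profile(panel, n_bins=12)


class TestSpearman:
    def _panel(self, data):
        return AverageImagePanel(np.asarray(data, float), 1, 65.0)

    def test_identity_and_monotone_transform_give_r1(self, gaussian_panel):
        panel, _, _ = gaussian_panel
        assert spearman_coloc(panel, panel) == pytest.approx(1.0)
        transformed = self._panel(np.log1p(panel.data) ** 2)
        assert spearman_coloc(panel, transformed) == pytest.approx(1.0)

    def test_negation_gives_minus_1(self, gaussian_panel):
        panel, _, _ = gaussian_panel
        neg = self._panel(-panel.data)
        assert spearman_coloc(panel, neg) == pytest.approx(-1.0)

    def test_constant_panel_undefined(self, gaussian_panel):
        panel, _, _ = gaussian_panel
        flat = self._panel(np.full_like(panel.data, 2.0))
        assert math.isnan(spearman_coloc(panel, flat))


class TestPixelColoc:
    def test_identical_channels_give_unity(self):
        sim = simulate_two_channel_stack(45, n_foci=20, dims=(9, 192, 192))
        stats = pixel_coloc_stats(sim.fish, sim.fish, sim.nucleus_mask, 300, 300)
        assert stats.manders_moc == pytest.approx(1.0)
        assert stats.pearson_r == pytest.approx(1.0)

    def test_disjoint_supports_give_zero_moc(self):
        a = np.zeros((3, 32, 32))
        b = np.zeros((3, 32, 32))
        a[1, 5:8, 5:8] = 100
        b[1, 20:23, 20:23] = 100
        stats = pixel_coloc_stats(
            ImageStack(a, 65, 300), ImageStack(b, 65, 300),
            np.ones(a.shape, bool), 50, 50,
        )
        assert stats.manders_moc == 0.0

    def test_planted_30pct_overlap_recovered(self):
        # 10 equal spots in ch1; ch2 shares exactly 3 and has 7 elsewhere
        a = np.zeros((3, 96, 96))
        b = np.zeros((3, 96, 96))
        spots = [(1, 10 + 8 * i, 10) for i in range(10)]
        for i, (z, y, x) in enumerate(spots):
            a[z, y : y + 2, x : x + 2] = 100
            if i < 3:
                b[z, y : y + 2, x : x + 2] = 100
            else:
                b[z, y : y + 2, x + 40 : x + 42] = 100
        stats = pixel_coloc_stats(
            ImageStack(a, 65, 300), ImageStack(b, 65, 300),
            np.ones(a.shape, bool), 50, 50,
        )
        assert stats.manders_moc == pytest.approx(0.30, abs=0.05)

    def test_empty_mask_is_an_error(self):
        s = ImageStack(np.zeros((2, 8, 8)), 65, 300)
        with pytest.raises(ValueError, match="mask"):
            pixel_coloc_stats(s, s, np.zeros((2, 8, 8), bool), 1, 1)


class TestNearestCluster:
    def test_cluster_at_focus_gives_near_zero_distance(self):
        stack = stack_with_spot((30.0, 30.0, 5.0))
        focus = Focus(0, (30.0, 30.0, 5.0), 1, 1.0)
        rec = nearest_cluster_distance(focus, stack, threshold=400)
        assert rec.distance_nm <= 65.0

    def test_planted_300nm_offset_recovered_within_one_pixel(self):
        sim = simulate_two_channel_stack(46, n_foci=1, coloc_fraction=1.0,
                                         offset_nm=300.0, noise_sd=0.0)
        (f,) = detect_foci(sim.fish, threshold=400, min_voxels=4)
        rec = nearest_cluster_distance(f, sim.if_channel, threshold=400)
        assert rec.distance_nm == pytest.approx(300.0, abs=65.0)

    def test_empty_if_channel_flagged(self):
        stack = ImageStack(np.zeros((11, 64, 64)), 65.0, 300.0)
        rec = nearest_cluster_distance(Focus(0, (30.0, 30.0, 5.0), 1, 1.0), stack,
                                       threshold=100)
        assert rec.no_cluster and math.isnan(rec.distance_nm)

    def test_fraction_within_trivial_cases(self):
        zeros = [DistanceRecord(i, 0.0, 5) for i in range(4)]
        fars = [DistanceRecord(i, 900.0, 5) for i in range(4)]
        assert fraction_within(zeros) == 1.0
        assert fraction_within(fars) == 0.0
        with pytest.raises(ValueError):
            fraction_within([])


class TestDroplets:
    def test_uniform_10x_interior_gives_ratio_10(self):
        droplet = np.zeros((64, 64))
        droplet[20:30, 20:30] = 1000
        measure = np.full((64, 64), 10.0)
        measure[20:30, 20:30] = 100.0
        (ratio,) = droplet_partition_ratio(measure, droplet, min_area=10, threshold=500)
        assert ratio == pytest.approx(10.0)

    def test_uniform_measure_gives_ratio_1(self):
        droplet = np.zeros((64, 64))
        droplet[20:30, 20:30] = 1000
        ratios = droplet_partition_ratio(np.full((64, 64), 7.0), droplet,
                                         min_area=10, threshold=500)
        assert ratios == [pytest.approx(1.0)]

    def test_no_droplet_gives_empty_list(self):
        assert droplet_partition_ratio(np.ones((32, 32)), np.zeros((32, 32)),
                                       threshold=10) == []

    def test_planted_ratios_recovered_within_10pct(self):
        measure, droplet, truth = simulate_droplet_image(47)
        ratios = sorted(droplet_partition_ratio(measure, droplet))
        assert len(ratios) == 3
        for got, want in zip(ratios, sorted(truth["ratios"])):
            assert got == pytest.approx(want, rel=0.10)
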