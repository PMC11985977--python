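"""Unit and property tests for the stretch-series analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from skinqa.preprocessing import RoiMask
from skinqa.stretching import (
    StretchState,
    analyse_stretch_series,
    area_ratio_from_rois,
    bhattacharyya_distance,
    compare_histograms,
    elongation,
    joint_histogram_range,
    mean_removed_histogram,
    thickness_volume_conserved,
    trend_vs_elongation,
    zone_partition,
)
from skinqa.synthetic import make_stretch_scene, make_stretch_series


def _rect_roi(shape, r0, r1, c0, c1):
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return RoiMask(mask=mask, contour=np.array([[0.0, 0.0]]))


class TestElongation:
    def test_one_cm_step_on_50_mm_skin(self):
        assert elongation(50.0, 60.0) == pytest.approx(20.0)

    def test_no_stretch_is_zero(self):
        assert elongation(37.0, 37.0) == 0.0

    def test_rupture_point_inverse(self):
        assert elongation(50.0, 110.0) == pytest.approx(120.0)

    def test_compression_rejected(self):
        with pytest.raises(ValueError):
            elongation(50.0, 40.0)


class TestThickness:
    def test_unit_area_ratio_returns_t0(self):
        assert thickness_volume_conserved(0.5, 1.0) == 0.5

    def test_double_area_halves_thickness(self):
        assert thickness_volume_conserved(0.5, 2.0) == 0.25

    def test_printed_endpoint_round_trip(self):
        # 0.5 mm thinning to 0.26 mm implies an area ratio of 0.5/0.26
        ratio = 0.5 / 0.26
        assert thickness_volume_conserved(0.5, ratio) == pytest.approx(0.26)
        assert ratio == pytest.approx(1.923, abs=1e-3)

    def test_shrinking_skin_flagged(self):
        with pytest.raises(ValueError):
            thickness_volume_conserved(0.5, 0.9)


class TestAreaRatio:
    def test_identical_masks(self):
        roi = _rect_roi((50, 50), 10, 40, 10, 40)
        assert area_ratio_from_rois(roi, roi) == 1.0

    def test_axial_scaling_by_1_2(self):
        roi0 = _rect_roi((80, 160), 20, 60, 30, 130)  # 40 x 100
        roi1 = _rect_roi((80, 160), 20, 60, 20, 140)  # 40 x 120
        assert area_ratio_from_rois(roi0, roi1) == pytest.approx(1.2, rel=0.01)

    def test_biaxial_scaling_product(self):
        # 1.2 axial x 0.913 lateral ~ 1.096
        roi0 = _rect_roi((200, 200), 50, 150, 40, 160)  # 100 x 120
        roi1 = _rect_roi((200, 200), 54, 145, 28, 172)  # 91 x 144
        assert area_ratio_from_rois(roi0, roi1) == pytest.approx(
            1.2 * 0.913, rel=0.01
        )

    def test_volume_conservation_round_trip(self):
        roi0 = _rect_roi((100, 100), 10, 60, 10, 60)
        roi1 = _rect_roi((100, 100), 10, 70, 10, 80)
        ratio = area_ratio_from_rois(roi0, roi1)
        t = thickness_volume_conserved(0.5, ratio)
        assert t * ratio == pytest.approx(0.5, rel=1e-12)


class TestMeanRemovedHistogram:
    def test_constant_image_occupies_single_bin_at_zero(self):
        roi = _rect_roi((20, 20), 2, 18, 2, 18)
        img = np.full((20, 20), 321.0)
        hist = mean_removed_histogram(img, roi, n_bins=11, value_range=(-1, 1))
        assert hist.sum() == pytest.approx(1.0)
        assert hist[5] == 1.0  # central bin holds the zero

    def test_offset_invariance(self):
        rng = np.random.default_rng(8)
        roi = _rect_roi((30, 30), 5, 25, 5, 25)
        img = rng.normal(1000, 20, size=(30, 30))
        rng_pair = joint_histogram_range(
            img[roi.mask] - img[roi.mask].mean(),
            img[roi.mask] - img[roi.mask].mean(),
        )
        h1 = mean_removed_histogram(img, roi, 64, rng_pair)
        h2 = mean_removed_histogram(img + 100.0, roi, 64, rng_pair)
        assert np.array_equal(h1, h2)

    def test_gaussian_pixels_match_density(self):
        rng = np.random.default_rng(9)
        roi = _rect_roi((320, 320), 10, 310, 10, 310)
        img = rng.normal(0, 10, size=(320, 320))
        hist = mean_removed_histogram(img, roi, n_bins=21, value_range=(-30, 30))
        from scipy.stats import norm

        edges = np.linspace(-30, 30, 22)
        expected = np.diff(norm.cdf(edges, scale=10))
        expected /= expected.sum()
        n = roi.area_px
        # within a few multinomial standard errors per bin
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(hist - expected) < 5 * se + 1e-4)

    def test_degenerate_range_rejected(self):
        roi = _rect_roi((10, 10), 1, 9, 1, 9)
        with pytest.raises(ValueError):
            mean_removed_histogram(np.ones((10, 10)), roi, 8, (1.0, 1.0))


class TestBhattacharyya:
    def test_identical_histograms_are_zero(self):
        p = np.array([0.25, 0.5, 0.25])
        assert bhattacharyya_distance(p, p) == 0.0

    def test_disjoint_supports_are_infinite_and_flagged(self):
        cmp = compare_histograms(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert np.isinf(cmp.bhattacharyya)
        assert cmp.disjoint
        assert cmp.disjoint_mass == pytest.approx(2.0)

    def test_hand_evaluated_half_overlap(self):
        d = bhattacharyya_distance(np.array([1.0, 0.0]), np.array([0.5, 0.5]))
        assert d == pytest.approx(-np.log(np.sqrt(0.5)), abs=1e-12)
        assert d == pytest.approx(0.346574, abs=1e-6)

    def test_unnormalised_input_rejected(self):
        with pytest.raises(ValueError):
            bhattacharyya_distance(np.array([0.5, 0.4]), np.array([0.5, 0.5]))

    @given(
        arrays(np.float64, 16, elements=st.floats(0.01, 1.0)),
        arrays(np.float64, 16, elements=st.floats(0.01, 1.0)),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_symmetry_and_nonnegativity(self, a, b):
        p, q = a / a.sum(), b / b.sum()
        d_pq = bhattacharyya_distance(p, q)
        d_qp = bhattacharyya_distance(q, p)
        assert d_pq == pytest.approx(d_qp, abs=1e-12)
        assert d_pq >= 0.0


class TestTrendFit:
    def test_exact_linear_decline(self):
        e = [0, 20, 40, 60]
        mpv = [2000 - 5 * x for x in e]
        fit = trend_vs_elongation(e, mpv)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(-5.0)
        assert not fit.degenerate

    def test_constant_metric_is_degenerate(self):
        fit = trend_vs_elongation([0, 20, 40], [7.0, 7.0, 7.0])
        assert fit.degenerate
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            trend_vs_elongation([0, 20], [1.0, 2.0])


class TestZonePartition:
    @staticmethod
    def _disc_roi(radius=40, pad=8):
        n = 2 * (radius + pad)
        yy, xx = np.mgrid[:n, :n]
        mask = (yy - n / 2) ** 2 + (xx - n / 2) ** 2 <= radius**2
        return RoiMask(mask=mask, contour=np.array([[0.0, 0.0]]))

    def test_single_zone_is_the_roi(self):
        roi = self._disc_roi()
        zones = zone_partition(roi, 1)
        assert len(zones) == 1
        assert np.array_equal(zones[0], roi.mask)

    def test_two_zone_split_of_disc(self):
        roi = self._disc_roi()
        inner_ring, core = zone_partition(roi, 2)
        # distance-percentile split at the median: equal areas within 10 %
        assert inner_ring.sum() == pytest.approx(roi.area_px / 2, rel=0.1)
        assert core.sum() == pytest.approx(roi.area_px / 2, rel=0.1)
        # the core zone is farther from the border than the ring
        from scipy.ndimage import distance_transform_edt

        dist = distance_transform_edt(roi.mask)
        assert dist[core].min() >= dist[inner_ring].max() - 1e-9

    @pytest.mark.parametrize("n_zones", [2, 3, 5])
    def test_zones_partition_the_roi(self, n_zones):
        roi = self._disc_roi()
        zones = zone_partition(roi, n_zones)
        union = np.zeros_like(roi.mask)
        for z in zones:
            assert not (union & z).any()  # pairwise disjoint
            union |= z
        assert np.array_equal(union, roi.mask)

    def test_tiny_roi_rejected(self):
        roi = _rect_roi((10, 10), 4, 6, 4, 6)
        with pytest.raises(ValueError):
            zone_partition(roi, 5)


class TestStretchStateInvariants:
    def test_volume_identity(self):
        state = StretchState.from_lengths(50.0, 80.0, t0_mm=0.5, area_ratio=1.4)
        assert state.elongation_pct == pytest.approx(60.0)
        assert state.thickness_est_mm * state.area_ratio == pytest.approx(0.5)
        assert state.thickness_est_mm <= state.t0_mm


class TestEndToEndRecovery:
    def test_generator_slope_and_thinning_recovered(self, config):
        scene = make_stretch_scene(config)
        series = make_stretch_series(
            scene, [0, 25, 50, 75, 100], seed=12, config=config
        )
        table, trends = analyse_stretch_series(series)
        # generator MPV slope: 2000 DN amplitude declining 25 % per 100 %
        true_slope = -scene.response_slope * 0.8 * 0.25 / 100.0
        fit = trends["mpv"]
        assert fit.slope == pytest.approx(true_slope, rel=0.02)
        assert fit.r_squared > 0.99
        for step, thickness in zip(series.steps, table["thickness_est_mm"]):
            assert thickness == pytest.approx(step.thickness_true_mm, rel=0.02)
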