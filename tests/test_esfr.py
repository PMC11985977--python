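"""Unit tests for the slanted-edge SFR chain."""

import warnings

import numpy as np
import pytest
from scipy.special import ndtr

from skinqa.config import DetectorConfig
from skinqa.esfr import (
    EdgeNotFoundError,
    EdgeRoi,
    InsufficientSlantError,
    SfrCurve,
    build_esf,
    compute_sfr,
    esf_to_sfr,
    estimate_edge_line,
    extract_edge_roi,
    sfr_summary,
    validate_edge_roi,
)
from skinqa.synthetic import (
    gaussian_mtf_reference,
    make_frame_stack,
    make_slanted_edge_scene,
)

PITCH = 0.051


def synthetic_edge_roi(
    angle_deg, sigma_mm=0.1, seed=11, height=200, width=192, noiseless=False
):
    """Rendered edge ROI cropped from a full synthetic scene."""
    cfg = DetectorConfig()
    kw = dict(read_noise_sd=0.0, poisson_scale=None) if noiseless else {}
    scene = make_slanted_edge_scene(angle_deg, sigma_mm, 0.05, cfg, **kw)
    stack = make_frame_stack(scene, cfg, 0.8, seed)
    mean = stack.frames.mean(axis=0)
    return extract_edge_roi(mean, (160, 160), height, width, PITCH)


def ramp_edge_roi(shift_per_row, n_rows=40, n_cols=64, col0=30.0):
    """Sharp step (pixel-aperture rendered) drifting linearly with the row."""
    cols = np.arange(n_cols, dtype=float)
    img = np.empty((n_rows, n_cols))
    for r in range(n_rows):
        edge = col0 + shift_per_row * r
        img[r] = 1000.0 * np.clip(cols + 0.5 - edge, 0.0, 1.0)
    return EdgeRoi(pixels=img, pitch_mm=PITCH)


class TestValidateEdgeRoi:
    def test_five_degree_edge_is_valid(self):
        report = validate_edge_roi(synthetic_edge_roi(5.0))
        assert report.valid
        assert report.angle_deg == pytest.approx(5.0, abs=0.2)

    @pytest.mark.parametrize("angle", [2.0, 7.0])
    def test_window_boundary_angles_accepted(self, angle):
        report = validate_edge_roi(synthetic_edge_roi(angle))
        assert report.valid, report.reasons

    def test_ten_degree_edge_flagged(self):
        report = validate_edge_roi(synthetic_edge_roi(10.0))
        assert not report.valid
        assert any("angle" in r for r in report.reasons)

    def test_side_imbalance_flagged(self):
        # step at column 80 of 100: only 20 % of the ROI is bright
        roi = ramp_edge_roi(0.1, n_cols=100, col0=80.0)
        report = validate_edge_roi(roi)
        assert not report.valid
        assert any("imbalance" in r for r in report.reasons)

    def test_flat_roi_has_no_edge(self):
        with pytest.raises(EdgeNotFoundError):
            validate_edge_roi(EdgeRoi(pixels=np.ones((32, 32)), pitch_mm=PITCH))


class TestEstimateEdgeLine:
    def test_half_pixel_shift_per_row(self):
        line = estimate_edge_line(ramp_edge_roi(0.5))
        assert line.slope == pytest.approx(0.5, abs=0.01)
        assert line.residual_rms < 0.1

    def test_vertical_step_constant_position(self):
        line = estimate_edge_line(ramp_edge_roi(0.0))
        assert line.slope == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(line.positions, line.positions[0])

    def test_noisy_four_degree_angle_recovered(self):
        line = estimate_edge_line(synthetic_edge_roi(4.0, sigma_mm=0.2, seed=9))
        assert line.angle_deg == pytest.approx(4.0, abs=0.3)


class TestBuildEsf:
    def test_ideal_step_esf_transitions_at_zero(self):
        roi = synthetic_edge_roi(5.0, sigma_mm=0.0, noiseless=True)
        line = estimate_edge_line(roi)
        esf = build_esf(roi, line)
        lo, hi = esf.values.min(), esf.values.max()
        mid = 0.5 * (lo + hi)
        crossing = esf.distances_px[np.argmax(esf.values > mid)]
        assert abs(crossing) <= 0.5 / esf.oversample + 0.25

    def test_gaussian_blurred_esf_matches_cdf(self):
        sigma_mm = 0.2
        roi = synthetic_edge_roi(5.0, sigma_mm=sigma_mm, noiseless=True)
        line = estimate_edge_line(roi)
        esf = build_esf(roi, line)
        sigma_px = sigma_mm / PITCH
        lo, hi = esf.values.min(), esf.values.max()
        ref = lo + (hi - lo) * ndtr(esf.distances_px / sigma_px)
        keep = np.abs(esf.distances_px) < 40
        err = np.abs(esf.values - ref)[keep] / (hi - lo)
        assert err.max() < 0.02

    def test_zero_slant_has_no_phase_diversity(self):
        roi = ramp_edge_roi(0.0, n_rows=64, n_cols=64)
        line = estimate_edge_line(roi)
        with pytest.raises(InsufficientSlantError):
            build_esf(roi, line)


class TestEsfToSfr:
    def test_delta_lsf_gives_flat_sfr(self):
        # a step ESF differentiates to an impulse: flat spectrum
        values = np.where(np.arange(256) >= 128, 1000.0, 0.0)
        esf = _fake_esf(values)
        curve = esf_to_sfr(esf, PITCH)
        assert curve.values[0] == pytest.approx(1.0)
        assert np.all(curve.values > 0.9)

    def test_gaussian_psf_matches_analytic_mtf(self):
        sigma = 0.2
        roi = synthetic_edge_roi(4.5, sigma_mm=sigma, noiseless=True)
        curve = _chain(roi)
        ref = gaussian_mtf_reference(sigma, curve.frequencies)
        keep = curve.frequencies <= 0.8 / (2 * PITCH)
        assert np.abs(curve.values - ref)[keep].max() < 0.02

    def test_ideal_step_follows_aperture_sinc(self):
        roi = synthetic_edge_roi(5.0, sigma_mm=0.0, noiseless=True)
        curve = _chain(roi)
        sinc = np.abs(np.sinc(curve.frequencies * PITCH))
        assert np.abs(curve.values - sinc).max() < 0.03
        assert np.all(curve.values <= sinc + 1e-6)

    def test_short_esf_rejected(self):
        with pytest.raises(ValueError):
            esf_to_sfr(_fake_esf(np.linspace(0, 1, 32)), PITCH)


class TestSfrSummary:
    def test_gaussian_sigma_02_closed_form(self):
        roi = synthetic_edge_roi(4.5, sigma_mm=0.2, noiseless=True)
        curve = _chain(roi)
        f50 = np.sqrt(np.log(2) / (2 * np.pi**2 * 0.2**2))
        assert curve.sfr50 == pytest.approx(f50, rel=0.03)
        assert curve.sfr10 > curve.sfr50

    def test_exact_grid_crossing_returned_exactly(self):
        f = np.linspace(0, 5, 11)
        v = np.linspace(1.0, 0.0, 11)  # crosses 0.5 exactly at f = 2.5
        curve = SfrCurve(frequencies=f, values=v)
        sfr50, sfr10 = sfr_summary(curve)
        assert sfr50 == pytest.approx(2.5)
        assert sfr10 == pytest.approx(4.5)

    def test_flat_curve_is_beyond_nyquist(self):
        curve = SfrCurve(
            frequencies=np.linspace(0, 9.8, 50), values=np.ones(50)
        )
        assert sfr_summary(curve) == (None, None)


class TestChainInvariants:
    def test_pitch_rescaling_scales_frequencies(self):
        roi = synthetic_edge_roi(4.5, sigma_mm=0.2, noiseless=True)
        c1 = _chain(roi)
        roi_half = EdgeRoi(pixels=roi.pixels, pitch_mm=PITCH / 2)
        c2 = _chain(roi_half)
        # halving the pitch doubles every reported frequency
        assert c2.sfr50 == pytest.approx(2 * c1.sfr50, rel=1e-6)
        assert c2.sfr10 == pytest.approx(2 * c1.sfr10, rel=1e-6)

    def test_orientation_symmetry(self):
        roi = synthetic_edge_roi(4.5, sigma_mm=0.2, seed=13)
        flipped = EdgeRoi(
            pixels=roi.pixels.T, pitch_mm=roi.pitch_mm, orientation="horizontal"
        )
        c1, c2 = _chain(roi), _chain(flipped)
        assert c2.sfr50 == pytest.approx(c1.sfr50, rel=0.01)
        assert c2.sfr10 == pytest.approx(c1.sfr10, rel=0.01)

    def test_blur_monotonically_degrades_resolution(self):
        summaries = []
        for sigma in (0.1, 0.2, 0.4):
            curve = _chain(synthetic_edge_roi(4.5, sigma_mm=sigma, noiseless=True))
            summaries.append((curve.sfr50, curve.sfr10))
        sfr50s, sfr10s = zip(*summaries)
        assert sfr50s[0] > sfr50s[1] > sfr50s[2]
        assert sfr10s[0] > sfr10s[1] > sfr10s[2]

    def test_normalisation_at_zero_frequency(self):
        for sigma in (0.0, 0.2):
            curve = _chain(synthetic_edge_roi(5.0, sigma_mm=sigma, seed=17))
            assert curve.values[0] == pytest.approx(1.0, abs=1e-9)

    def test_strict_mode_raises_on_invalid_angle(self):
        roi = synthetic_edge_roi(10.0)
        with pytest.raises(ValueError):
            compute_sfr(roi, strict=True)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            compute_sfr(roi, strict=False)
        assert any("angle" in str(w.message) for w in caught)


def _chain(roi: EdgeRoi) -> SfrCurve:
    line = estimate_edge_line(roi)
    esf = build_esf(roi, line)
    return esf_to_sfr(esf, roi.pitch_mm)


def _fake_esf(values):
    from skinqa.esfr import Esf

    n = len(values)
    return Esf(
        values=np.asarray(values, dtype=float),
        distances_px=(np.arange(n) - n / 2) / 4,
        oversample=4,
        empty_bin_fraction=0.0,
    )
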