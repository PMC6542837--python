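"""Squeeze-video measurement chain: segmentation, equivalent diameter,
time series, wettability indexes, oscillation estimate."""

import math

import numpy as np
import pytest

from biofilmwet import (
    AnalysisWindows,
    DiameterSeries,
    GrayImage,
    diameter_from_mask,
    diameter_series,
    mean_squeezed_diameter,
    oscillation_frequency,
    residual_diameter,
    segment_squeezed_region,
)
from biofilmwet.errors import AnalysisError, ConfigError, InputError, ParameterError
from biofilmwet.io import manifest_from_spec
from biofilmwet.phantoms import make_squeeze_video, study_condition_spec

from conftest import render_and_measure


def _series(times, diams, fps=60.0, jet_off=1.0):
    return DiameterSeries(
        time_s=np.asarray(times),
        diameter_mm=np.asarray(diams),
        jet_on_s=0.0,
        jet_off_s=jet_off,
        scale_mm_per_px=0.05,
        frame_rate_hz=fps,
    )


class TestDiameterFromMask:
    def test_disc_measures_its_diameter(self):
        rows, cols = np.ogrid[:256, :256]
        mask = (rows - 128) ** 2 + (cols - 128) ** 2 <= 100**2
        assert diameter_from_mask(mask, 0.05) == pytest.approx(10.0, rel=0.01)

    def test_empty_mask_is_zero(self):
        assert diameter_from_mask(np.zeros((10, 10), bool), 0.05) == 0.0

    def test_square_equivalent_diameter(self):
        mask = np.ones((100, 100), bool)
        expected = 2 * math.sqrt(10000 / math.pi) * 0.1
        assert diameter_from_mask(mask, 0.1) == pytest.approx(expected, rel=1e-6)

    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ParameterError):
            diameter_from_mask(np.ones((4, 4), bool), 0.0)


class TestSegmentation:
    def test_identical_frame_gives_empty_mask(self, flat_image):
        mask = segment_squeezed_region(flat_image, flat_image, (32, 32))
        assert not mask.any()

    def test_rendered_disc_area_recovered(self):
        base = np.full((256, 256), 90.0)
        frame = base.copy()
        rows, cols = np.ogrid[:256, :256]
        frame[(rows - 128) ** 2 + (cols - 128) ** 2 <= 60**2] += 80
        mask = segment_squeezed_region(GrayImage(frame), GrayImage(base), (128, 128))
        assert abs(mask.sum() - math.pi * 60**2) <= 0.03 * math.pi * 60**2

    def test_component_containing_nozzle_axis_wins(self):
        base = np.full((128, 128), 90.0)
        frame = base.copy()
        frame[10:30, 10:30] += 80  # small blob, nozzle inside
        frame[60:120, 60:120] += 80  # larger blob elsewhere
        mask = segment_squeezed_region(GrayImage(frame), GrayImage(base), (20, 20))
        assert mask[15, 15] and not mask[90, 90]

    def test_shape_mismatch_rejected(self, flat_image):
        with pytest.raises(InputError):
            segment_squeezed_region(flat_image, np.zeros((8, 8)), (0, 0))


class TestDiameterSeries:
    def test_fast_rise_video_recovered_frame_by_frame(self):
        spec, truth, series, _ = render_and_measure("PS_14d", seed=11)
        tol = np.maximum(2 * spec.scale_mm_per_px, 0.03 * truth.diameter_mm)
        assert np.all(np.abs(series.diameter_mm - truth.diameter_mm) <= tol)
        assert series.time_s[0] == pytest.approx(-spec.jet_on_s)

    def test_all_liquid_video_is_identically_zero(self):
        spec = study_condition_spec(
            "PS_14d", plateau_diameter_mm=0.0, noise_sd=3.0, frame_shape=(64, 64)
        )
        frames, _ = make_squeeze_video(spec)
        series = diameter_series(frames, manifest_from_spec(spec))
        assert np.all(series.diameter_mm == 0.0)

    def test_oscillatory_mean_close_to_spec(self):
        spec, truth, series, idx = render_and_measure("VGP_initial", seed=12)
        assert idx.mean_squeezed_diameter_mm == pytest.approx(
            spec.plateau_diameter_mm, abs=0.2
        )

    def test_missing_manifest_field_is_config_error(self, flat_image):
        with pytest.raises(ConfigError):
            diameter_series([flat_image], {"frame_rate_hz": 60.0})

    def test_requires_pre_jet_frame(self, flat_image):
        manifest = dict(frame_rate_hz=60.0, scale_mm_per_px=0.05, jet_on_s=0.0, jet_off_s=1.0)
        with pytest.raises(ConfigError):
            diameter_series([flat_image, flat_image], manifest)


class TestIndexes:
    def test_constant_series_mean(self):
        t = np.arange(0, 1.6, 1 / 60)
        s = _series(t, np.full(t.size, 6.0))
        assert mean_squeezed_diameter(s) == pytest.approx(6.0)

    def test_sinusoid_mean_near_carrier(self):
        t = np.arange(0, 1.0, 1 / 60)
        s = _series(t, 6.0 + 1.0 * np.sin(2 * np.pi * 6 * t))
        assert mean_squeezed_diameter(s) == pytest.approx(6.0, abs=0.3)

    def test_ramp_sampled_at_window_endpoints(self):
        s = _series([0.63, 0.9], [6.3, 9.0])
        assert mean_squeezed_diameter(s) == pytest.approx(7.65)

    def test_residual_exactly_zero_on_full_recovery(self):
        _, _, series, idx = render_and_measure("VGP_14d", seed=13)
        assert idx.residual_diameter_mm == 0.0
        assert residual_diameter(series) == 0.0

    def test_residual_of_unrecovered_plateau(self):
        t = np.arange(0, 1.6, 1 / 60)
        s = _series(t, np.full(t.size, 17.0))
        assert residual_diameter(s) == pytest.approx(17.0)
        s5 = _series(t, np.full(t.size, 5.0))
        assert residual_diameter(s5) == pytest.approx(5.0)

    def test_empty_window_error_names_the_window(self):
        s = _series([0.0, 0.1], [1.0, 1.0])
        with pytest.raises(AnalysisError, match="0.63"):
            mean_squeezed_diameter(s)
        with pytest.raises(AnalysisError, match="1.23"):
            residual_diameter(s)

    def test_indexes_stable_under_finer_resampling(self):
        spec = study_condition_spec("VGP_initial", noise_sd=0.0)
        from biofilmwet.phantoms import trajectory_diameter

        for fps in (60.0, 120.0):
            t = np.arange(0, 1.7, 1 / fps)
            s = _series(t, trajectory_diameter(spec, t), fps=fps)
            if fps == 60.0:
                ref_mean = mean_squeezed_diameter(s)
                ref_res = residual_diameter(s)
            else:
                assert mean_squeezed_diameter(s) == pytest.approx(ref_mean, abs=0.1)
                assert residual_diameter(s) == pytest.approx(ref_res, abs=0.1)


class TestOscillation:
    def test_pure_sinusoid_recovered_within_one_bin(self):
        t = np.arange(0, 1.0, 1 / 60)
        s = _series(t, 6.0 + np.sin(2 * np.pi * 6 * t))
        freq = oscillation_frequency(s, window=(0.0, 1.0))
        assert freq is not None
        assert abs(freq - 6.0) <= 60.0 / t.size

    def test_constant_series_has_no_oscillation(self):
        t = np.arange(0, 1.0, 1 / 60)
        s = _series(t, np.full(t.size, 6.0))
        assert oscillation_frequency(s, window=(0.0, 1.0)) is None

    def test_sub_nyquist_frame_rate_rejected(self):
        t = np.arange(0, 1.0, 1 / 8)
        s = _series(t, 6.0 + np.sin(2 * np.pi * 6 * t), fps=8.0)
        with pytest.raises(AnalysisError):
            oscillation_frequency(s, window=(0.0, 1.0))

    def test_too_few_samples_rejected(self):
        s = _series([0.0, 0.2, 0.4], [6.0, 7.0, 6.0])
        with pytest.raises(AnalysisError):
            oscillation_frequency(s, window=(0.0, 1.0))


class TestSeriesValidation:
    def test_non_increasing_times_rejected(self):
        with pytest.raises(InputError):
            _series([0.0, 0.0, 0.1], [1.0, 1.0, 1.0])

    def test_negative_diameters_rejected(self):
        with pytest.raises(InputError):
            _series([0.0, 0.1], [1.0, -1.0])

    def test_windows_validate_against_jet_interval(self):
        with pytest.raises(ParameterError):
            AnalysisWindows(mean_window=(0.63, 1.2), jet_duration_s=1.0)
        with pytest.raises(ParameterError):
            AnalysisWindows(residual_window=(0.8, 1.5), jet_duration_s=1.0)
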