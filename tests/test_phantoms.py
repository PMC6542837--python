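"""Synthetic-data generators: encode/decode identity, regime semantics,
cap geometry, determinism."""

import math

import numpy as np
import pytest

from biofilmwet import (
    BubblePhantomSpec,
    SqueezeTrajectorySpec,
    StainPhantomSpec,
    decompensate,
    diameter_from_mask,
    make_bubble_image,
    make_coverage_phantom,
    make_squeeze_video,
    make_stained_dish_image,
    study_condition_spec,
    trajectory_diameter,
)
from biofilmwet.errors import ConfigError, GeometryError, ParameterError


def _dish_spec(od_field, **kw):
    shape = np.asarray(od_field).shape
    kw.setdefault("dish_center", ((shape[0] - 1) / 2, (shape[1] - 1) / 2))
    kw.setdefault("dish_radius_px", min(shape) / 2 - 2)
    return StainPhantomSpec(true_od_field=np.asarray(od_field, float), **kw)


class TestStainPhantom:
    def test_zero_od_renders_full_scale_white(self):
        image, _ = make_stained_dish_image(_dish_spec(np.zeros((32, 32))))
        assert np.all(image.intensity == 255)

    def test_scanner_gamma_encodes_tenth_reflectance(self):
        # I'/gamma = 1 means a 10% reflectance fraction: counts = round(25.5)
        image, _ = make_stained_dish_image(_dish_spec(np.full((16, 16), 1.8)))
        assert np.all(image.intensity == 26)

    def test_encode_decode_round_trip_within_quantization(self, rng):
        od_true = rng.uniform(0.0, 1.5, size=(40, 40))
        spec = _dish_spec(od_true, seed=7)
        image, truth = make_stained_dish_image(spec)
        od = decompensate(image, spec.gamma)
        # exact per-pixel bound for a half-count rounding error:
        # |delta I'| <= (gamma/ln10) * ln(I / (I - 0.5))
        counts = np.maximum(image.intensity, 1.0)
        bound = (spec.gamma / math.log(10)) * np.log(counts / (counts - 0.5))
        assert np.all(np.abs(od.i_prime - truth) <= bound + 1e-12)

    def test_rejects_od_darker_than_one_count(self):
        dark = np.full((16, 16), 5.0)  # counts would round to 0
        with pytest.raises(ParameterError):
            make_stained_dish_image(_dish_spec(dark))

    def test_rejects_dish_outside_frame(self):
        spec = _dish_spec(np.zeros((32, 32)), dish_center=(2, 2), dish_radius_px=20)
        with pytest.raises(GeometryError):
            make_stained_dish_image(spec)

    def test_deterministic_for_equal_seed(self):
        od = np.random.default_rng(1).uniform(0, 1, (24, 24))
        a, _ = make_stained_dish_image(_dish_spec(od, seed=5, noise_sd=4.0))
        b, _ = make_stained_dish_image(_dish_spec(od, seed=5, noise_sd=4.0))
        assert np.array_equal(a.intensity, b.intensity)

    def test_coverage_phantom_hits_requested_fraction(self):
        rows, cols = np.ogrid[:120, :120]
        roi = (rows - 60) ** 2 + (cols - 60) ** 2 <= 40**2
        spec, realised = make_coverage_phantom(
            0.3, roi, seed=2, dish_center=(60, 60), dish_radius_px=55
        )
        assert realised == pytest.approx(0.3, abs=0.01)
        assert spec.true_od_field.shape == (120, 120)


class TestSqueezeTrajectories:
    def test_full_recovery_time_course(self):
        spec = SqueezeTrajectorySpec(
            regime="fast_rise_full_recovery",
            plateau_diameter_mm=6.0,
            rise_time_s=0.1,
            recovery_time_s=0.1,
        )
        t = np.array([-0.1, 0.05, 0.1, 0.5, 1.0, 1.05, 1.11, 1.5])
        d = trajectory_diameter(spec, t)
        assert d[0] == 0.0
        assert d[1] == pytest.approx(3.0)
        assert np.allclose(d[2:5], 6.0)
        assert 0 < d[5] < 6.0
        assert d[6] == 0.0 and d[7] == 0.0  # back to zero within 0.1 s

    def test_two_step_shoulder_then_spread_without_recovery(self):
        spec = SqueezeTrajectorySpec(
            regime="two_step_no_recovery",
            plateau_diameter_mm=17.0,
            first_step_diameter_mm=5.0,
        )
        t = np.array([0.15, 0.19, 0.5, 1.0, 1.5, 10.0])
        d = trajectory_diameter(spec, t)
        assert d[0] == pytest.approx(5.0)  # shoulder at ~5 mm before 0.2 s
        assert d[1] == pytest.approx(5.0)
        assert np.allclose(d[2:], 17.0)  # spread and never recovered

    def test_oscillation_dominates_periodogram_at_6hz(self):
        from scipy.signal import periodogram

        spec = study_condition_spec("VGP_initial")
        t = np.arange(0.2, 1.0, 1 / 60.0)
        d = trajectory_diameter(spec, t)
        freqs, power = periodogram(d - d.mean(), fs=60.0)
        peak = freqs[1:][np.argmax(power[1:])]
        assert abs(peak - 6.0) <= 60.0 / len(t)

    def test_zero_plateau_renders_all_liquid(self):
        spec = SqueezeTrajectorySpec(
            regime="fast_rise_full_recovery",
            plateau_diameter_mm=0.0,
            duration_s=0.5,
            jet_on_s=0.1,
            jet_off_s=0.4,
            frame_shape=(64, 64),
        )
        frames, truth = make_squeeze_video(spec)
        assert np.all(truth.diameter_mm == 0.0)
        assert all(np.ptp(f.intensity) == 0 for f in frames)

    def test_rendered_diameter_matches_truth(self):
        spec = study_condition_spec("PS_14d", noise_sd=0.0)
        frames, truth = make_squeeze_video(spec)
        k = int((spec.jet_on_s + 0.5) * spec.frame_rate_hz)  # mid-jet frame
        mask = frames[k].intensity > spec.liquid_level + spec.contrast_step / 2
        d = diameter_from_mask(mask, spec.scale_mm_per_px)
        assert abs(d - truth.diameter_mm[k]) <= 2 * spec.scale_mm_per_px

    def test_diameter_exceeding_field_of_view_rejected(self):
        spec = study_condition_spec("PS_initial", frame_shape=(100, 100))
        with pytest.raises(GeometryError):
            make_squeeze_video(spec)

    def test_oscillatory_nyquist_guard(self):
        with pytest.raises(ConfigError):
            study_condition_spec("VGP_initial", frame_rate_hz=8.0).validate()

    def test_full_recovery_requires_zero_residual(self):
        with pytest.raises(ParameterError):
            study_condition_spec("PS_14d", residual_diameter_mm=1.0).validate()

    def test_deterministic_frames_for_equal_seed(self):
        a, _ = make_squeeze_video(study_condition_spec("VGP_14d", seed=9, noise_sd=3.0))
        b, _ = make_squeeze_video(study_condition_spec("VGP_14d", seed=9, noise_sd=3.0))
        assert all(np.array_equal(x.intensity, y.intensity) for x, y in zip(a, b))


class TestBubblePhantom:
    @pytest.mark.parametrize("angle", [90.0, 120.0, 60.0])
    def test_analytic_cap_angles(self, angle):
        image, truth = make_bubble_image(BubblePhantomSpec(contact_angle_deg=angle))
        assert truth == angle
        # hemisphere: cap width at the baseline equals the diameter
        if angle == 90.0:
            cap = image.intensity < 100
            width = cap[41, :].sum()
            assert width == pytest.approx(2 * 60, abs=2)

    def test_angle_range_enforced(self):
        with pytest.raises(ParameterError):
            make_bubble_image(BubblePhantomSpec(contact_angle_deg=5.0))

    def test_cap_must_fit_in_frame(self):
        spec = BubblePhantomSpec(contact_angle_deg=150.0, bubble_radius_px=200.0)
        with pytest.raises(GeometryError):
            make_bubble_image(spec)
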