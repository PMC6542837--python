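"""Seeded synthetic fixtures: stained-dish scans, squeeze videos, bubble stills.

Every generator stores its ground truth alongside the rendered pixels so each
analysis stage can be validated end to end without any raw laboratory data.
The phantoms are phenomenological: stained dishes encode a known OD field
through the scanner's gamma model, squeeze videos render a dry disc whose
diameter follows one of three trajectory regimes observed for polystyrene
dishes under an air-jet, and bubble stills are exact circular caps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import ConfigError, GeometryError, ParameterError
from .squeeze import DiameterSeries
from .stain import GrayImage

Regime = Literal[
    "two_step_no_recovery", "oscillatory_partial_recovery", "fast_rise_full_recovery"
]


# ---------------------------------------------------------------------------
# stained-dish phantoms


@dataclass
class StainPhantomSpec:
    """A dish scan with a known stain-density field.

    ``true_od_field`` is the per-pixel stain density over the whole frame
    (zero where unstained); ``c0``/``c1`` place it on the calibration line
    ``d = c1 * I' + c0`` before gamma encoding, so re-fitting a calibration
    from rendered standards must recover them.
    """

    dish_center: tuple[float, float]
    dish_radius_px: float
    true_od_field: np.ndarray
    gamma: float = 1.8
    bit_depth: int = 8
    noise_sd: float = 0.0
    seed: int = 0
    c0: float = 0.0
    c1: float = 1.0

    def validate(self) -> None:
        if self.gamma <= 0:
            raise ParameterError("gamma must be positive")
        if self.bit_depth not in (8, 16):
            raise ParameterError("bit_depth must be 8 or 16")
        field_arr = np.asarray(self.true_od_field, dtype=float)
        if field_arr.ndim != 2 or field_arr.size == 0:
            raise ParameterError("true_od_field must be a non-empty 2-D grid")
        if field_arr.min() < 0:
            raise ParameterError("true_od_field must be non-negative")
        nrow, ncol = field_arr.shape
        cr, cc = self.dish_center
        r = self.dish_radius_px
        if r <= 0 or cr - r < 0 or cc - r < 0 or cr + r > nrow - 1 or cc + r > ncol - 1:
            raise GeometryError("dish circle must lie inside the image frame")


def make_stained_dish_image(spec: StainPhantomSpec) -> tuple[GrayImage, np.ndarray]:
    """Render a gamma-encoded scan of a dish with a known OD field.

    Inverts the decompensation chain: density ``d`` maps to
    ``I' = (d - c0)/c1`` and then to counts ``I = (2**b - 1) * 10**(-I'/gamma)``.
    Densities so dark that the ideal counts would round below one are
    rejected, because the logarithmic decoding diverges at zero counts.
    """
    spec.validate()
    d = np.asarray(spec.true_od_field, dtype=float)
    i_prime = (d - spec.c0) / spec.c1
    if i_prime.min() < 0:
        raise ParameterError("calibration maps some densities to negative I'")
    full_scale = 2**spec.bit_depth - 1
    ideal = full_scale * np.power(10.0, -i_prime / spec.gamma)
    if ideal.min() < 0.5:
        raise ParameterError(
            "OD field too dark: encoded intensity would round below 1 count"
        )
    rng = np.random.default_rng(spec.seed)
    counts = ideal
    if spec.noise_sd > 0:
        counts = counts + rng.normal(0.0, spec.noise_sd, size=counts.shape)
    counts = np.clip(np.rint(counts), 0, full_scale)
    image = GrayImage(intensity=counts, bit_depth=spec.bit_depth)
    return image, d.copy()


def make_coverage_phantom(
    coverage_fraction: float,
    roi_mask: np.ndarray,
    od_background: float = 0.1,
    od_stained: float = 0.8,
    correlation_px: float = 6.0,
    seed: int = 0,
    **spec_kwargs,
) -> tuple[StainPhantomSpec, float]:
    """Bimodal OD field with an exact stained-pixel fraction inside the ROI.

    A smoothed Gaussian random field is thresholded at the quantile that puts
    exactly the requested fraction of ROI pixels at ``od_stained``; blobs are
    spatially correlated like real biofilm patches. Returns the spec and the
    realised (pixel-exact) coverage fraction.
    """
    if not 0.0 <= coverage_fraction <= 1.0:
        raise ParameterError("coverage_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(roi_mask.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=correlation_px)
    field_arr = np.full(roi_mask.shape, od_background, dtype=float)
    roi_vals = smooth[roi_mask]
    if coverage_fraction >= 1.0:
        stained = roi_mask
    elif coverage_fraction <= 0.0:
        stained = np.zeros_like(roi_mask)
    else:
        cut = np.quantile(roi_vals, 1.0 - coverage_fraction)
        stained = roi_mask & (smooth > cut)
    field_arr[stained] = od_stained
    realised = float(stained[roi_mask].sum() / roi_mask.sum())
    spec = StainPhantomSpec(true_od_field=field_arr, seed=seed, **spec_kwargs)
    return spec, realised


# ---------------------------------------------------------------------------
# liquid-squeezing videos


@dataclass
class SqueezeTrajectorySpec:
    """Parameters of one synthetic liquid-squeezing experiment.

    The three regimes mirror the behaviours seen on differently conditioned
    dishes: two-step spreading without any liquid recovery (hydrophobic bare
    polystyrene), a ~6 Hz oscillation with partial recovery (plasma-treated
    polystyrene), and a fast rise to a small constant diameter with full
    recovery within ~0.1 s (biofilm-covered dishes).
    """

    regime: Regime
    plateau_diameter_mm: float
    first_step_diameter_mm: float = 5.0
    first_step_until_s: float = 0.2
    spread_ramp_s: float = 0.2
    osc_freq_hz: float = 6.0
    osc_amplitude_mm: float = 0.0
    rise_time_s: float = 0.1
    recovery_time_s: float = 0.1
    residual_diameter_mm: float = 0.0
    jet_on_s: float = 0.3
    jet_off_s: float = 1.3
    duration_s: float = 2.0
    frame_rate_hz: float = 60.0
    scale_mm_per_px: float = 0.05
    frame_shape: tuple[int, int] = (380, 380)
    liquid_level: float = 90.0
    contrast_step: float = 80.0
    noise_sd: float = 0.0
    bit_depth: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.jet_on_s >= self.jet_off_s:
            raise ParameterError("jet_on_s must precede jet_off_s")
        lengths = (
            self.plateau_diameter_mm,
            self.first_step_diameter_mm,
            self.osc_amplitude_mm,
            self.residual_diameter_mm,
        )
        if any(v < 0 for v in lengths):
            raise ParameterError("all lengths must be non-negative")
        if self.regime == "oscillatory_partial_recovery":
            if self.frame_rate_hz <= 2.0 * self.osc_freq_hz:
                raise ConfigError(
                    "frame rate must exceed twice the oscillation frequency"
                )
        if self.regime == "fast_rise_full_recovery" and self.residual_diameter_mm != 0:
            raise ParameterError("full-recovery regime requires zero residual diameter")
        if self.scale_mm_per_px <= 0 or self.frame_rate_hz <= 0:
            raise ParameterError("scale and frame rate must be positive")


def trajectory_diameter(spec: SqueezeTrajectorySpec, t_jet: np.ndarray) -> np.ndarray:
    """Ground-truth dry-area diameter (mm) at times relative to jet onset."""
    t = np.asarray(t_jet, dtype=float)
    d = np.zeros_like(t)
    jet_len = spec.jet_off_s - spec.jet_on_s
    rise = max(spec.rise_time_s, 1e-9)

    if spec.regime == "two_step_no_recovery":
        t1 = min(spec.rise_time_s, spec.first_step_until_s)
        ramp1 = (t >= 0) & (t < t1)
        d[ramp1] = spec.first_step_diameter_mm * t[ramp1] / max(t1, 1e-9)
        hold1 = (t >= t1) & (t < spec.first_step_until_s)
        d[hold1] = spec.first_step_diameter_mm
        t2 = spec.first_step_until_s + max(spec.spread_ramp_s, 1e-9)
        ramp2 = (t >= spec.first_step_until_s) & (t < t2)
        frac = (t[ramp2] - spec.first_step_until_s) / max(spec.spread_ramp_s, 1e-9)
        d[ramp2] = spec.first_step_diameter_mm + frac * (
            spec.plateau_diameter_mm - spec.first_step_diameter_mm
        )
        d[t >= t2] = spec.plateau_diameter_mm  # no recovery after jet off
        return d

    # shared rise for the other two regimes
    ramp = (t >= 0) & (t < rise)
    d[ramp] = spec.plateau_diameter_mm * t[ramp] / rise
    during = (t >= rise) & (t <= jet_len)
    d[during] = spec.plateau_diameter_mm
    if spec.regime == "oscillatory_partial_recovery":
        d[during] += spec.osc_amplitude_mm * np.sin(
            2 * np.pi * spec.osc_freq_hz * (t[during] - rise)
        )
        d_end = spec.plateau_diameter_mm + spec.osc_amplitude_mm * math.sin(
            2 * math.pi * spec.osc_freq_hz * (jet_len - rise)
        )
        target = spec.residual_diameter_mm
    else:  # fast_rise_full_recovery
        d_end = spec.plateau_diameter_mm
        target = 0.0
    rec = max(spec.recovery_time_s, 1e-9)
    after = t > jet_len
    frac = np.clip((t[after] - jet_len) / rec, 0.0, 1.0)
    d[after] = d_end + frac * (target - d_end)
    return np.clip(d, 0.0, None)


def make_squeeze_video(
    spec: SqueezeTrajectorySpec,
) -> tuple[list[GrayImage], DiameterSeries]:
    """Render the frame sequence and its ground-truth diameter series.

    Each frame shows a dry circular region (brighter than the surrounding
    liquid by ``contrast_step`` counts) whose equivalent diameter equals the
    regime trajectory at that frame's timestamp. Times in the returned series
    are anchored so t = 0 is jet onset.
    """
    spec.validate()
    n_frames = int(round(spec.duration_s * spec.frame_rate_hz))
    t_video = np.arange(n_frames) / spec.frame_rate_hz
    t_jet = t_video - spec.jet_on_s
    diam_mm = trajectory_diameter(spec, t_jet)

    nrow, ncol = spec.frame_shape
    max_r_px = diam_mm.max() / (2.0 * spec.scale_mm_per_px)
    if 2 * max_r_px >= min(nrow, ncol) - 4:
        raise GeometryError(
            f"dry-region diameter {diam_mm.max():.1f} mm exceeds the field of view"
        )
    cr, cc = (nrow - 1) / 2.0, (ncol - 1) / 2.0
    rows, cols = np.ogrid[:nrow, :ncol]
    dist2 = (rows - cr) ** 2 + (cols - cc) ** 2

    rng = np.random.default_rng(spec.seed)
    full_scale = 2**spec.bit_depth - 1
    frames: list[GrayImage] = []
    for k in range(n_frames):
        r_px = diam_mm[k] / (2.0 * spec.scale_mm_per_px)
        frame = np.full((nrow, ncol), spec.liquid_level, dtype=float)
        if r_px > 0:
            frame[dist2 <= r_px**2] += spec.contrast_step
        if spec.noise_sd > 0:
            frame += rng.normal(0.0, spec.noise_sd, size=frame.shape)
        frame = np.clip(np.rint(frame), 0, full_scale)
        frames.append(
            GrayImage(frame, bit_depth=spec.bit_depth, scale_mm_per_px=spec.scale_mm_per_px)
        )
    truth = DiameterSeries(
        time_s=t_jet,
        diameter_mm=diam_mm,
        jet_on_s=0.0,
        jet_off_s=spec.jet_off_s - spec.jet_on_s,
        scale_mm_per_px=spec.scale_mm_per_px,
        frame_rate_hz=spec.frame_rate_hz,
    )
    return frames, truth


#: Generator settings reproducing the four experimental conditions of the
#: study: bare polystyrene (PS) and plasma-treated polystyrene (VGP-PS), each
#: at the initial state and after 14 days of biofilm-forming incubation.
#: Plateaus encode the reported group means (17, 6.8, 6.0, 5.6 mm), the
#: oscillation the reported ~6 Hz, and the residuals 17 / 5.0 / 0 / 0 mm.
STUDY_CONDITIONS: dict[str, dict] = {
    "PS_initial": dict(
        regime="two_step_no_recovery",
        plateau_diameter_mm=17.0,
        first_step_diameter_mm=5.0,
    ),
    "VGP_initial": dict(
        regime="oscillatory_partial_recovery",
        plateau_diameter_mm=6.8,
        osc_freq_hz=6.0,
        osc_amplitude_mm=1.0,
        residual_diameter_mm=5.0,
        recovery_time_s=0.2,
    ),
    "PS_14d": dict(
        regime="fast_rise_full_recovery",
        plateau_diameter_mm=6.0,
        rise_time_s=0.1,
        recovery_time_s=0.1,
    ),
    "VGP_14d": dict(
        regime="fast_rise_full_recovery",
        plateau_diameter_mm=5.6,
        rise_time_s=0.1,
        recovery_time_s=0.1,
    ),
}


def study_condition_spec(
    condition: str, seed: int = 0, **overrides
) -> SqueezeTrajectorySpec:
    """Trajectory spec for one of the four study conditions."""
    if condition not in STUDY_CONDITIONS:
        raise ParameterError(
            f"unknown condition {condition!r}; choose from {sorted(STUDY_CONDITIONS)}"
        )
    kwargs = {**STUDY_CONDITIONS[condition], **overrides}
    return SqueezeTrajectorySpec(seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# captive-bubble stills


@dataclass
class BubblePhantomSpec:
    """A circular-cap bubble silhouette below a flat solid baseline.

    ``contact_angle_deg`` is measured through the bubble at the contact line;
    a hemisphere gives 90 deg, a centre offset ``h`` into the bubble phase
    gives ``90 + asin(h/r)`` degrees.
    """

    contact_angle_deg: float
    bubble_radius_px: float = 60.0
    baseline_row: int = 40
    noise_sd: float = 0.0
    seed: int = 0
    frame_shape: tuple[int, int] = (240, 320)
    center_col: float | None = None
    bubble_level: float = 40.0
    background_level: float = 200.0
    bit_depth: int = 8

    def validate(self) -> None:
        if not 10.0 <= self.contact_angle_deg <= 170.0:
            raise ParameterError("contact angle must lie in [10, 170] degrees")
        if self.bubble_radius_px <= 0:
            raise ParameterError("bubble radius must be positive")
        nrow, ncol = self.frame_shape
        r = self.bubble_radius_px
        h = r * math.sin(math.radians(self.contact_angle_deg - 90.0))
        cc = self.center_col if self.center_col is not None else (ncol - 1) / 2.0
        center_row = self.baseline_row + h
        if not (1 <= self.baseline_row < nrow - 2):
            raise GeometryError("baseline row outside the frame")
        if center_row + r > nrow - 2 or cc - r < 1 or cc + r > ncol - 2:
            raise GeometryError("bubble cap does not fit inside the frame")


def make_bubble_image(spec: BubblePhantomSpec) -> tuple[GrayImage, float]:
    """Render a circular-cap bubble and return the analytic contact angle.

    The bubble occupies the rows below ``baseline_row`` (the solid surface is
    viewed from the side with the specimen facing down, as in a captive-bubble
    cell). If the circle does not intersect the baseline the cap is
    degenerate and a geometry error is raised.
    """
    spec.validate()
    nrow, ncol = spec.frame_shape
    r = spec.bubble_radius_px
    h = r * math.sin(math.radians(spec.contact_angle_deg - 90.0))
    if abs(h) >= r:
        raise GeometryError("circle does not intersect the baseline")
    cc = spec.center_col if spec.center_col is not None else (ncol - 1) / 2.0
    center_row = spec.baseline_row + h
    rows, cols = np.ogrid[:nrow, :ncol]
    inside = (rows - center_row) ** 2 + (cols - cc) ** 2 <= r**2
    cap = inside & (rows > spec.baseline_row)
    frame = np.full((nrow, ncol), spec.background_level, dtype=float)
    frame[cap] = spec.bubble_level
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        frame += rng.normal(0.0, spec.noise_sd, size=frame.shape)
    full_scale = 2**spec.bit_depth - 1
    frame = np.clip(np.rint(frame), 0, full_scale)
    return GrayImage(frame, bit_depth=spec.bit_depth), float(spec.contact_angle_deg)
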