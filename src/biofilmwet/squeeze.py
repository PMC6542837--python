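"""Liquid-squeezing wettability analysis from video frames.

An air-jet applied for 1 s to a water-covered dish squeezes the liquid away
from the surface; the diameter of the resulting dry area tracks surface
wettability (smaller diameter = more wettable surface). This module segments
the dry region frame by frame, builds the diameter time series, and computes
the two wettability indexes:

* mean squeezed diameter — arithmetic mean over t = 0.63 to 0.9 s of the jet
  phase (the late, settled part of squeezing);
* residual diameter — arithmetic mean over t = 1.23 to 1.5 s, after the jet
  stops; exactly 0 when the liquid fully re-covers the surface.

An optional periodogram step estimates the squeezing-oscillation frequency
seen on partially wetting surfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from skimage import filters, measure, morphology

from .errors import AnalysisError, ConfigError, InputError, ParameterError
from .stain import GrayImage

_TIME_TOL = 1e-9  # timestamp comparison tolerance for closed windows


@dataclass
class DiameterSeries:
    """Dry-area diameter vs time, with t = 0 anchored to jet onset."""

    time_s: np.ndarray
    diameter_mm: np.ndarray
    jet_on_s: float
    jet_off_s: float
    scale_mm_per_px: float
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.diameter_mm = np.asarray(self.diameter_mm, dtype=float)
        if self.time_s.shape != self.diameter_mm.shape:
            raise InputError("time and diameter arrays must align")
        if self.time_s.size and np.any(np.diff(self.time_s) <= 0):
            raise InputError("timestamps must be strictly increasing")
        if self.diameter_mm.size and self.diameter_mm.min() < -_TIME_TOL:
            raise InputError("diameters must be non-negative")
        if self.jet_on_s >= self.jet_off_s:
            raise InputError("jet_on_s must precede jet_off_s")

    def in_window(self, lo: float, hi: float) -> np.ndarray:
        """Diameters of samples whose timestamps fall in the closed window."""
        sel = (self.time_s >= lo - _TIME_TOL) & (self.time_s <= hi + _TIME_TOL)
        return self.diameter_mm[sel]


@dataclass
class AnalysisWindows:
    """Index-averaging windows in jet-anchored seconds."""

    mean_window: tuple[float, float] = (0.63, 0.9)
    residual_window: tuple[float, float] = (1.23, 1.5)
    jet_duration_s: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_window[0] >= self.mean_window[1]:
            raise ParameterError("mean window must be non-empty")
        if self.residual_window[0] >= self.residual_window[1]:
            raise ParameterError("residual window must be non-empty")
        if self.mean_window[1] > self.jet_duration_s + _TIME_TOL:
            raise ParameterError("mean window must lie inside the jet-on interval")
        if self.residual_window[0] < self.jet_duration_s - _TIME_TOL:
            raise ParameterError("residual window must start after jet-off")


@dataclass
class WettabilityIndexes:
    """Per-experiment wettability summary."""

    mean_squeezed_diameter_mm: float
    residual_diameter_mm: float
    oscillation_freq_hz: float | None = None
    n_frames_mean_window: int = 0
    n_frames_residual_window: int = 0


def segment_squeezed_region(
    frame: GrayImage,
    baseline: GrayImage | np.ndarray,
    nozzle_axis: tuple[float, float],
    threshold: float | None = None,
    closing_radius: int = 2,
    min_contrast: float = 4.0,
    threshold_floor: float = 0.0,
    min_object_px: int = 16,
) -> np.ndarray:
    """Segment the dry (liquid-squeezed) area by differencing against a
    pre-jet baseline frame.

    The absolute difference image is thresholded (Otsu by default, manual
    override via ``threshold``), morphologically closed, and the connected
    component containing — or nearest to — the nozzle axis is returned.
    An all-false mask is a valid result meaning "no squeezed area".

    On frames with no dry region the difference image is pure sensor noise,
    which Otsu would happily split; callers that can estimate the noise
    level (``diameter_series`` measures it on the pre-jet frames) should
    pass it as ``threshold_floor``. Specks below ``min_object_px`` are
    discarded.
    """
    base = baseline.intensity if isinstance(baseline, GrayImage) else np.asarray(baseline)
    if base.shape != frame.shape:
        raise InputError(f"frame {frame.shape} and baseline {base.shape} differ")
    diff = np.abs(frame.intensity - base)
    if threshold is None:
        if diff.max() <= max(min_contrast, threshold_floor):
            return np.zeros(frame.shape, dtype=bool)
        threshold = max(filters.threshold_otsu(diff), threshold_floor)
    mask = diff > threshold
    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius))
    if min_object_px > 0:
        mask = morphology.remove_small_objects(mask, max_size=min_object_px - 1)
    if not mask.any():
        return mask
    labels = measure.label(mask)
    r0 = int(round(nozzle_axis[0]))
    c0 = int(round(nozzle_axis[1]))
    nrow, ncol = mask.shape
    if 0 <= r0 < nrow and 0 <= c0 < ncol and labels[r0, c0] > 0:
        keep = labels[r0, c0]
    else:
        # nearest component by centroid-free minimum pixel distance
        best, keep = math.inf, 0
        axis = np.array(nozzle_axis, dtype=float)
        for region in measure.regionprops(labels):
            dmin = np.min(np.linalg.norm(region.coords - axis, axis=1))
            if dmin < best:
                best, keep = dmin, region.label
    return labels == keep


def diameter_from_mask(mask: np.ndarray, scale_mm_per_px: float) -> float:
    """Equivalent-circle diameter of a pixel mask, in millimetres.

    ``2 * sqrt(area / pi) * scale``; an empty mask measures 0 mm.
    """
    if scale_mm_per_px <= 0:
        raise ParameterError("scale must be positive")
    area = int(np.count_nonzero(mask))
    if area == 0:
        return 0.0
    return 2.0 * math.sqrt(area / math.pi) * scale_mm_per_px


def max_feret_diameter(mask: np.ndarray, scale_mm_per_px: float) -> float:
    """Maximum caliper (Feret) diameter, the alternative size convention."""
    if scale_mm_per_px <= 0:
        raise ParameterError("scale must be positive")
    if not np.any(mask):
        return 0.0
    props = measure.regionprops(mask.astype(np.uint8))
    return float(props[0].feret_diameter_max) * scale_mm_per_px


def diameter_series(
    frames: list[GrayImage],
    manifest: dict,
    nozzle_axis: tuple[float, float] | None = None,
    threshold: float | None = None,
    use_feret: bool = False,
) -> DiameterSeries:
    """Measure the dry-area diameter on every frame of one experiment.

    The manifest must supply ``frame_rate_hz``, ``scale_mm_per_px``,
    ``jet_on_s`` and ``jet_off_s`` (video-timeline seconds). Frames earlier
    than jet onset are averaged into the still-liquid baseline; output
    timestamps are shifted so t = 0 is jet onset.

    The pre-jet frames double as a noise probe: the segmentation threshold
    is floored at 1.3 times the largest pre-jet |frame - baseline|
    difference, so frames where the liquid has fully recovered segment to an
    empty mask instead of speckled noise.
    """
    for key in ("frame_rate_hz", "scale_mm_per_px", "jet_on_s", "jet_off_s"):
        if key not in manifest or manifest[key] is None:
            raise ConfigError(f"manifest is missing required field {key!r}")
    fps = float(manifest["frame_rate_hz"])
    scale = float(manifest["scale_mm_per_px"])
    jet_on = float(manifest["jet_on_s"])
    jet_off = float(manifest["jet_off_s"])
    if not frames:
        raise ConfigError("no frames supplied")

    t_video = np.arange(len(frames)) / fps
    pre = [f.intensity for f, t in zip(frames, t_video) if t < jet_on - _TIME_TOL]
    if not pre:
        raise ConfigError("at least one pre-jet frame is required for the baseline")
    baseline = np.mean(pre, axis=0)
    floor = 1.3 * max(float(np.abs(p - baseline).max()) for p in pre) if len(pre) > 1 else 0.0
    if nozzle_axis is None:
        nrow, ncol = frames[0].shape
        nozzle_axis = ((nrow - 1) / 2.0, (ncol - 1) / 2.0)

    measure_fn = max_feret_diameter if use_feret else diameter_from_mask
    diam = np.empty(len(frames))
    for k, frame in enumerate(frames):
        mask = segment_squeezed_region(
            frame, baseline, nozzle_axis, threshold=threshold, threshold_floor=floor
        )
        diam[k] = measure_fn(mask, scale)
    return DiameterSeries(
        time_s=t_video - jet_on,
        diameter_mm=diam,
        jet_on_s=0.0,
        jet_off_s=jet_off - jet_on,
        scale_mm_per_px=scale,
        frame_rate_hz=fps,
    )


def _window_mean(series: DiameterSeries, lo: float, hi: float, name: str) -> tuple[float, int]:
    vals = series.in_window(lo, hi)
    if vals.size == 0:
        raise AnalysisError(f"no samples in the {name} window [{lo}, {hi}] s")
    return float(vals.mean()), int(vals.size)


def mean_squeezed_diameter(
    series: DiameterSeries, windows: AnalysisWindows | None = None
) -> float:
    """Arithmetic mean diameter over the late jet-application window."""
    windows = windows or AnalysisWindows()
    value, _ = _window_mean(series, *windows.mean_window, name="mean-diameter")
    return value


def residual_diameter(
    series: DiameterSeries, windows: AnalysisWindows | None = None
) -> float:
    """Mean diameter after the jet stops; exactly 0 under full recovery."""
    windows = windows or AnalysisWindows()
    vals = series.in_window(*windows.residual_window)
    if vals.size == 0:
        lo, hi = windows.residual_window
        raise AnalysisError(f"no samples in the residual window [{lo}, {hi}] s")
    if np.all(vals == 0.0):  # every in-window mask was empty: full recovery
        return 0.0
    return float(vals.mean())


def oscillation_frequency(
    series: DiameterSeries,
    window: tuple[float, float] | None = None,
    power_gate: float = 4.0,
    band_max_hz: float = 8.0,
    min_samples: int = 8,
    min_std_mm: float = 0.0,
) -> float | None:
    """Dominant oscillation frequency of the in-window diameter, if any.

    The mean-detrended samples are passed through a periodogram; the
    strongest nonzero-frequency peak is reported when its power exceeds
    ``power_gate`` times the median spectral power, otherwise ``None``
    (no meaningful oscillation). Sampling must resolve the physically
    expected squeezing-oscillation band (default up to 8 Hz): slower frame
    rates cannot distinguish the oscillation from its aliases and raise an
    analysis error.
    """
    if series.frame_rate_hz < 2.0 * band_max_hz:
        raise AnalysisError(
            f"frame rate {series.frame_rate_hz} Hz cannot resolve oscillations "
            f"up to {band_max_hz} Hz (sub-Nyquist)"
        )
    lo, hi = window if window is not None else (0.0, series.jet_off_s)
    vals = series.in_window(lo, hi)
    if vals.size < min_samples:
        raise AnalysisError(
            f"need at least {min_samples} samples in the window, got {vals.size}"
        )
    detrended = vals - vals.mean()
    if detrended.std() < min_std_mm:  # flat within measurement noise
        return None
    freqs, power = signal.periodogram(detrended, fs=series.frame_rate_hz)
    freqs, power = freqs[1:], power[1:]  # drop the DC bin
    if power.max() <= 0:
        return None
    peak = int(np.argmax(power))
    med = float(np.median(power))
    if med > 0 and power[peak] < power_gate * med:
        return None
    if med == 0 and power[peak] == 0:
        return None
    return float(freqs[peak])


def analyze_series(
    series: DiameterSeries,
    windows: AnalysisWindows | None = None,
    estimate_oscillation: bool = True,
) -> WettabilityIndexes:
    """Compute both wettability indexes (and the oscillation estimate)."""
    windows = windows or AnalysisWindows()
    mean_val, n_mean = _window_mean(series, *windows.mean_window, name="mean-diameter")
    res_vals = series.in_window(*windows.residual_window)
    if res_vals.size == 0:
        lo, hi = windows.residual_window
        raise AnalysisError(f"no samples in the residual window [{lo}, {hi}] s")
    res_val = 0.0 if np.all(res_vals == 0.0) else float(res_vals.mean())
    freq = None
    if estimate_oscillation:
        # restrict to the settled late-jet phase (after any two-step spread)
        # and ignore sub-0.05 mm flutter from pixel quantization
        try:
            freq = oscillation_frequency(
                series, window=(0.45, windows.jet_duration_s), min_std_mm=0.05
            )
        except AnalysisError:
            freq = None
    return WettabilityIndexes(
        mean_squeezed_diameter_mm=mean_val,
        residual_diameter_mm=res_val,
        oscillation_freq_hz=freq,
        n_frames_mean_window=n_mean,
        n_frames_residual_window=int(res_vals.size),
    )
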