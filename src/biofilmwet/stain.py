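"""Crystal-violet stain quantification from scanner images of dish bottoms.

The measurement chain converts 8- or 16-bit gamma-compensated scanner counts
into an optical-density-like stain density and reduces it to two per-dish
numbers:

1. every pixel intensity ``I`` is decompensated to the display-linear
   brightness ``I' = -(gamma/ln 10) * ln(I / (2**b - 1))``, which is simply
   ``gamma * log10`` of the reflectance fraction;
2. ``I'`` is mapped to stain density ``d = c1 * I' + c0`` with coefficients
   fitted against neutral-density (ND) filter standards of known OD;
3. the analysis region is the centred disc of half the dish-bottom radius;
4. the dish is summarised by the mean density over that region and by the
   percentage of region pixels whose density exceeds a threshold placed
   midway between the initial-state and incubated-state group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, FitError, GeometryError, InputError, ParameterError

#: Rec. 601 luma weights used when collapsing RGB scans to grayscale.
_REC601 = np.array([0.299, 0.587, 0.114])


@dataclass
class GrayImage:
    """A single-channel intensity grid with its bit depth and optional scale.

    Parameters
    ----------
    intensity
        2-D array of counts in ``[0, 2**bit_depth - 1]``.
    bit_depth
        Bits per sample of the source image (8 or 16 in practice).
    scale_mm_per_px
        Physical pixel pitch, when known.
    """

    intensity: np.ndarray
    bit_depth: int = 8
    scale_mm_per_px: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity)
        if arr.ndim == 3 and arr.shape[2] in (3, 4):
            arr = arr[..., :3].astype(float) @ _REC601
        if arr.ndim != 2 or arr.size == 0:
            raise InputError("intensity must be a non-empty 2-D grid")
        self.intensity = np.asarray(arr, dtype=float)
        full_scale = 2**self.bit_depth - 1
        if self.intensity.min() < 0 or self.intensity.max() > full_scale:
            raise InputError(
                f"intensity outside [0, {full_scale}] for bit depth {self.bit_depth}"
            )

    @property
    def full_scale(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass
class ODMap:
    """Decompensated brightness and (optionally) calibrated density over an ROI."""

    i_prime: np.ndarray
    roi_mask: np.ndarray
    gamma: float
    density: np.ndarray | None = None


@dataclass
class CalibrationFit:
    """Linear map from decompensated brightness to stain density, d = c1*I' + c0."""

    c0: float
    c1: float
    r_squared: float
    n_standards: int


@dataclass
class StainResult:
    """Per-dish summary: mean density and percent stained area over the ROI."""

    mean_density: float
    threshold: float | None = None
    area_ratio_pct: float | None = None
    dish_id: str = ""
    condition: str = ""
    day: str = ""


def decompensate(image: GrayImage, gamma: float = 1.8) -> ODMap:
    """Invert the scanner's display-gamma encoding.

    Computes ``I' = -(gamma / ln 10) * ln(I / (2**b - 1))`` per pixel.
    Saturated-black pixels (I < 1) carry no gradation and are clipped to one
    count so the logarithm stays finite.
    """
    if not np.isfinite(gamma) or gamma <= 0:
        raise ParameterError(f"gamma must be positive, got {gamma}")
    counts = np.clip(image.intensity, 1.0, image.full_scale)
    i_prime = -(gamma / np.log(10.0)) * np.log(counts / image.full_scale)
    roi = np.ones(image.shape, dtype=bool)
    return ODMap(i_prime=i_prime, roi_mask=roi, gamma=float(gamma))


def fit_calibration(
    i_prime_readings: np.ndarray, od_standards: np.ndarray
) -> CalibrationFit:
    """Ordinary least-squares line through (I', OD) pairs of the ND standards."""
    x = np.asarray(i_prime_readings, dtype=float).ravel()
    y = np.asarray(od_standards, dtype=float).ravel()
    if x.size != y.size:
        raise FitError("readings and standards must have equal length")
    if x.size < 2:
        raise FitError("at least two calibration standards are required")
    if np.ptp(x) == 0:
        raise FitError("all I' readings identical; slope is undefined")
    c1, c0 = np.polyfit(x, y, 1)
    resid = y - (c1 * x + c0)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return CalibrationFit(
        c0=float(c0), c1=float(c1), r_squared=float(np.clip(r2, 0.0, 1.0)),
        n_standards=int(x.size),
    )


def extract_roi(
    shape: tuple[int, int] | GrayImage,
    dish_center: tuple[float, float],
    dish_bottom_radius_px: float,
) -> np.ndarray:
    """Boolean disc mask of half the dish-bottom radius about the dish centre.

    The analysis area is deliberately restricted to the central part of the
    dish bottom, which avoids the meniscus shadow at the dish wall.
    Pixel membership is by pixel-centre distance.
    """
    if isinstance(shape, GrayImage):
        shape = shape.shape
    nrow, ncol = shape
    if dish_bottom_radius_px <= 0:
        raise GeometryError("dish radius must be positive")
    r = dish_bottom_radius_px / 2.0
    cr, cc = dish_center
    if cr - r < -0.5 or cc - r < -0.5 or cr + r > nrow - 0.5 or cc + r > ncol - 0.5:
        raise GeometryError(
            f"ROI disc (centre {dish_center}, radius {r:.1f} px) exceeds frame {shape}"
        )
    rows, cols = np.ogrid[:nrow, :ncol]
    mask = (rows - cr) ** 2 + (cols - cc) ** 2 <= r**2
    if not mask.any():
        raise GeometryError("ROI mask is empty")
    return mask


def detect_dish(
    image: GrayImage, radius_band_px: tuple[int, int]
) -> tuple[tuple[float, float], float]:
    """Locate the dish bottom by circular-edge voting (Hough transform).

    Returns ``((row, col), radius_px)`` of the strongest circle with radius in
    the configured band. A manually configured geometry always takes
    precedence over this detector in the pipeline.
    """
    from skimage.feature import canny
    from skimage.transform import hough_circle, hough_circle_peaks

    lo, hi = radius_band_px
    if not (0 < lo < hi):
        raise ParameterError("radius band must satisfy 0 < lo < hi")
    edges = canny(image.intensity / image.full_scale, sigma=2.0)
    radii = np.arange(lo, hi + 1, max(1, (hi - lo) // 50))
    accum = hough_circle(edges, radii)
    _, cc, cr, rad = hough_circle_peaks(accum, radii, total_num_peaks=1)
    if len(rad) == 0:
        raise GeometryError("no circular dish edge found in the radius band")
    return (float(cr[0]), float(cc[0])), float(rad[0])


def stain_density(od: ODMap, fit: CalibrationFit) -> StainResult:
    """Apply the calibration line over the ROI and take the pixel mean.

    Populates ``od.density`` in place for the subsequent area-ratio step.
    """
    if not od.roi_mask.any():
        raise AnalysisError("ROI is empty; no pixels to average")
    od.density = fit.c1 * od.i_prime + fit.c0
    mean_d = float(od.density[od.roi_mask].mean())
    return StainResult(mean_density=mean_d)


def compute_threshold(
    initial_mean_densities: list[float], incubated_mean_densities: list[float]
) -> float:
    """Midpoint between the initial-state and incubated-state group means.

    The threshold separating "stained" from "unstained" pixels is placed at
    the average of the two dish-group averages, so it adapts to the staining
    batch rather than being a fixed OD.
    """
    a = np.asarray(initial_mean_densities, dtype=float)
    b = np.asarray(incubated_mean_densities, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both dish groups must be non-empty")
    return float((a.mean() + b.mean()) / 2.0)


def area_ratio(od: ODMap, threshold: float) -> float:
    """Percent of ROI pixels whose density strictly exceeds the threshold."""
    if od.density is None:
        raise AnalysisError("density not populated; run stain_density first")
    roi = od.roi_mask
    if not roi.any():
        raise AnalysisError("ROI is empty")
    n = int(roi.sum())
    stained = int(np.count_nonzero(od.density[roi] > threshold))
    return 100.0 * stained / n
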