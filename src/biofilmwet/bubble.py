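"""Captive-bubble contact angle by circular-arc fitting.

A captive bubble pressed against a submerged, downward-facing surface is
imaged from the side; the contact angle between the surface and the bubble
silhouette quantifies surface wettability. Bubbles of a few microlitres are
small enough that gravitational distortion is negligible, so the silhouette
is modelled as a circular arc: a least-squares circle is fitted to the
boundary away from the baseline, and the angle follows from where the circle
meets the baseline.

Convention: the reported angle is measured *through the bubble* at the
contact line (a hemisphere reads 90 deg; centre offset h into the bubble
phase reads 90 + asin(h/r) deg). Under this convention a smaller angle means
a more hydrophobic surface; :func:`water_side_angle` converts to the
complementary water-side reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import filters, measure

from .errors import DetectionError, FitError, GeometryError
from .stain import GrayImage


@dataclass
class BubbleProfile:
    """Ordered boundary coordinates of the bubble, plus the baseline row."""

    contour: np.ndarray  # (N, 2) array of (row, col) points
    baseline_row: float
    scale_mm_per_px: float | None = None

    def __post_init__(self) -> None:
        self.contour = np.asarray(self.contour, dtype=float)
        if self.contour.ndim != 2 or self.contour.shape[0] < 10:
            raise DetectionError("profile needs at least 10 contour points")


@dataclass
class AngleResult:
    angle_deg: float
    fit_residual: float  # RMS contour-to-circle distance in pixels
    center: tuple[float, float] = (0.0, 0.0)
    radius_px: float = 0.0


def detect_bubble_profile(
    image: GrayImage, baseline_row: int, min_contrast: float = 10.0
) -> BubbleProfile:
    """Extract the boundary of the largest thresholded blob touching the
    baseline.

    The bubble may be darker or brighter than the background; the minority
    intensity class after Otsu thresholding is taken as foreground. Blank
    images (contrast below ``min_contrast`` counts) raise a detection error.
    """
    arr = image.intensity
    if float(arr.max() - arr.min()) < min_contrast:
        raise DetectionError("image has no detectable bubble (flat intensity)")
    t = filters.threshold_otsu(arr)
    dark = arr < t
    fg = dark if dark.sum() <= dark.size / 2 else ~dark
    labels = measure.label(fg)
    touch_band = labels[max(0, baseline_row - 2) : baseline_row + 3, :]
    candidates = np.unique(touch_band[touch_band > 0])
    if candidates.size == 0:
        raise DetectionError("no thresholded component touches the baseline")
    sizes = {lab: int((labels == lab).sum()) for lab in candidates}
    keep = max(sizes, key=sizes.get)
    mask = labels == keep
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise DetectionError("component has no traceable boundary")
    contour = max(contours, key=len)
    return BubbleProfile(
        contour=contour, baseline_row=float(baseline_row),
        scale_mm_per_px=image.scale_mm_per_px,
    )


def _fit_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kåsa) least-squares circle fit; returns (row, col, radius)."""
    r, c = points[:, 0], points[:, 1]
    A = np.column_stack([r, c, np.ones_like(r)])
    b = r**2 + c**2
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise FitError("circle fit failed") from exc
    cr, cc = sol[0] / 2.0, sol[1] / 2.0
    rad2 = sol[2] + cr**2 + cc**2
    if rad2 <= 0:
        raise FitError("degenerate circle fit (non-positive radius)")
    return cr, cc, math.sqrt(rad2)


def contact_angle_circle_fit(
    profile: BubbleProfile, baseline_band_px: float = 5.0
) -> AngleResult:
    """Fit a circle to the silhouette and read off the contact angle.

    Contour points within ``baseline_band_px`` of the baseline are excluded
    (the contact line is optically distorted there). With the fitted centre
    offset ``h`` from the baseline into the bubble phase, the angle through
    the bubble is ``90 + asin(h/r)`` degrees.
    """
    pts = profile.contour
    away = np.abs(pts[:, 0] - profile.baseline_row) > baseline_band_px
    kept = pts[away]
    if kept.shape[0] < 5:
        raise FitError("too few contour points away from the baseline")
    cr, cc, rad = _fit_circle(kept)
    # the bubble phase is the side of the baseline holding the contour bulk
    side = np.sign(np.median(kept[:, 0]) - profile.baseline_row) or 1.0
    h = (cr - profile.baseline_row) * side
    if abs(h) >= rad:
        raise GeometryError("fitted circle does not intersect the baseline")
    angle = 90.0 + math.degrees(math.asin(h / rad))
    dist = np.hypot(kept[:, 0] - cr, kept[:, 1] - cc)
    residual = float(np.sqrt(np.mean((dist - rad) ** 2)))
    return AngleResult(
        angle_deg=float(angle), fit_residual=residual,
        center=(float(cr), float(cc)), radius_px=float(rad),
    )


def measure_contact_angle(image: GrayImage, baseline_row: int, **fit_kwargs) -> AngleResult:
    """Convenience wrapper: detect the profile, then fit the angle."""
    profile = detect_bubble_profile(image, baseline_row)
    return contact_angle_circle_fit(profile, **fit_kwargs)


def water_side_angle(bubble_side_angle_deg: float) -> float:
    """Convert the bubble-side angle to the water-side convention."""
    return 180.0 - bubble_side_angle_deg
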