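"""Reading and writing the on-disk formats: PNG/TIFF images, YAML manifests,
CSV tables.

A squeeze experiment on disk is a directory of zero-padded PNG frames next to
a ``manifest.yaml`` (frame rate, scale, jet timestamps, bit depth) and an
optional ``truth.csv`` with the generator's ground-truth trajectory.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigError
from .squeeze import DiameterSeries
from .stain import GrayImage

MANIFEST_NAME = "manifest.yaml"
TRUTH_NAME = "truth.csv"

#: CSV float formatting used for all numeric outputs.
FLOAT_FMT = "%.6g"


def _to_dtype(image: GrayImage) -> np.ndarray:
    dtype = np.uint8 if image.bit_depth <= 8 else np.uint16
    return np.clip(np.rint(image.intensity), 0, image.full_scale).astype(dtype)


def write_gray_image(path: str | Path, image: GrayImage) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, _to_dtype(image))
    return path


def read_gray_image(
    path: str | Path, bit_depth: int | None = None, scale_mm_per_px: float | None = None
) -> GrayImage:
    arr = iio.imread(path)
    if bit_depth is None:
        bit_depth = 16 if arr.dtype == np.uint16 else 8
    return GrayImage(arr, bit_depth=bit_depth, scale_mm_per_px=scale_mm_per_px)


def write_video(
    out_dir: str | Path,
    frames: list[GrayImage],
    manifest: dict,
    truth: DiameterSeries | None = None,
) -> Path:
    """Write numbered frames, the manifest, and optionally the ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for k, frame in enumerate(frames):
        iio.imwrite(out_dir / f"frame_{k:05d}.png", _to_dtype(frame))
    with open(out_dir / MANIFEST_NAME, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    if truth is not None:
        df = pd.DataFrame({"time_s": truth.time_s, "diameter_mm": truth.diameter_mm})
        df.to_csv(out_dir / TRUTH_NAME, index=False, float_format=FLOAT_FMT)
    return out_dir


def read_video(exp_dir: str | Path) -> tuple[list[GrayImage], dict]:
    """Read a frame directory and its manifest back into memory."""
    exp_dir = Path(exp_dir)
    manifest_path = exp_dir / MANIFEST_NAME
    if not manifest_path.exists():
        raise ConfigError(f"no {MANIFEST_NAME} in {exp_dir}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    frame_paths = sorted(exp_dir.glob("frame_*.png"))
    if not frame_paths:
        raise ConfigError(f"no frames found in {exp_dir}")
    bit_depth = int(manifest.get("bit_depth", 8))
    scale = manifest.get("scale_mm_per_px")
    frames = [read_gray_image(p, bit_depth=bit_depth, scale_mm_per_px=scale) for p in frame_paths]
    return frames, manifest


def manifest_from_spec(spec) -> dict:
    """Build the sidecar manifest for a squeeze trajectory spec."""
    return {
        "frame_rate_hz": float(spec.frame_rate_hz),
        "scale_mm_per_px": float(spec.scale_mm_per_px),
        "jet_on_s": float(spec.jet_on_s),
        "jet_off_s": float(spec.jet_off_s),
        "bit_depth": int(spec.bit_depth),
        "regime": str(spec.regime),
        "seed": int(spec.seed),
    }


def write_stain_phantom(
    out_dir: str | Path, name: str, image: GrayImage, true_od: np.ndarray
) -> Path:
    """Write a phantom scan (PNG) plus its float-TIFF OD ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_dir / f"{name}.png", _to_dtype(image))
    tifffile.imwrite(out_dir / f"{name}_true_od.tif", true_od.astype(np.float32))
    return out_dir


def read_calibration_table(path: str | Path) -> pd.DataFrame:
    """Read the ND-standard table (columns standard_id, od, mean_i_prime)."""
    df = pd.read_csv(path)
    missing = {"od", "mean_i_prime"} - set(df.columns)
    if missing:
        raise ConfigError(f"calibration table missing columns {sorted(missing)}")
    return df


def write_table(path: str | Path, df: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")
    return path
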