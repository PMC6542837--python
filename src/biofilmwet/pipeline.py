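"""End-to-end runs tying the modules together: simulate, stain, squeeze,
bubble, compare.

Each ``run_*`` function takes a plain configuration dictionary (typically
loaded from YAML by the CLI) and returns the result table it also writes to
disk, so the same entry points serve scripted and shell use.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .bubble import measure_contact_angle
from .errors import AnalysisError, ConfigError
from .phantoms import (
    BubblePhantomSpec,
    STUDY_CONDITIONS,
    make_bubble_image,
    make_squeeze_video,
    study_condition_spec,
)
from .squeeze import AnalysisWindows, analyze_series, diameter_series
from .stain import (
    area_ratio,
    compute_threshold,
    decompensate,
    detect_dish,
    extract_roi,
    fit_calibration,
    stain_density,
)

#: Replicate counts of the four study conditions.
STUDY_REPLICATES = {"PS_initial": 3, "PS_14d": 9, "VGP_initial": 3, "VGP_14d": 6}

#: Dish-to-dish relative variability of the plateau diameter used when
#: simulating replicate experiments.
REPLICATE_JITTER = 0.02


def _replicate_seed(base_seed: int, condition: str, index: int) -> int:
    label = zlib.crc32(condition.encode())  # process-independent, unlike hash()
    return int((base_seed * 9973 + label % 997 * 131 + index) % (2**31 - 1))


def default_demo_config(seed: int = 0, n_replicates: dict | None = None) -> dict:
    """Demo simulation config covering the four study conditions."""
    reps = n_replicates or STUDY_REPLICATES
    return {
        "seed": seed,
        "conditions": [
            {"name": name, "n_replicates": reps.get(name, 3)} for name in STUDY_CONDITIONS
        ],
    }


def simulate_condition_suite(
    config: dict, noise_sd: float = 3.0
) -> dict[str, list[tuple[list, object]]]:
    """Generate squeeze videos for every condition/replicate, in memory.

    Returns ``{condition: [(frames, truth_series), ...]}``. Replicates share
    the condition's trajectory template but jitter the plateau (and any
    nonzero residual) by ~2% to emulate dish-to-dish variation.
    """
    base_seed = int(config.get("seed", 0))
    out: dict[str, list] = {}
    for cond in config["conditions"]:
        name = cond["name"]
        overrides = dict(cond.get("overrides", {}))
        videos = []
        for i in range(int(cond.get("n_replicates", 1))):
            seed = _replicate_seed(base_seed, name, i)
            rng = np.random.default_rng(seed)
            rep_overrides = dict(overrides)
            template = study_condition_spec(name, seed=seed, **overrides)
            factor = 1.0 + REPLICATE_JITTER * rng.standard_normal()
            rep_overrides["plateau_diameter_mm"] = template.plateau_diameter_mm * factor
            if template.residual_diameter_mm > 0:
                rep_overrides["residual_diameter_mm"] = (
                    template.residual_diameter_mm * factor
                )
            rep_overrides.setdefault("noise_sd", noise_sd)
            spec = study_condition_spec(name, seed=seed, **rep_overrides)
            videos.append(make_squeeze_video(spec))
        out[name] = videos
    return out


def run_simulate(config: dict, out_dir: str | Path) -> Path:
    """Write a squeeze-fixture tree: one directory per condition replicate."""
    out_dir = Path(out_dir)
    base_seed = int(config.get("seed", 0))
    for cond in config.get("conditions", []):
        name = cond["name"]
        overrides = dict(cond.get("overrides", {}))
        for i in range(int(cond.get("n_replicates", 1))):
            seed = _replicate_seed(base_seed, name, i)
            spec = study_condition_spec(name, seed=seed, **overrides)
            frames, truth = make_squeeze_video(spec)
            exp_dir = out_dir / name / f"rep_{i:02d}"
            manifest = bio.manifest_from_spec(spec)
            manifest["condition"] = name
            bio.write_video(exp_dir, frames, manifest, truth)
    return out_dir


def run_squeeze(
    input_dir: str | Path, out_dir: str | Path, windows: AnalysisWindows | None = None
) -> pd.DataFrame:
    """Analyze every experiment directory under ``input_dir``.

    Writes one time-series CSV per experiment plus a single ``indexes.csv``;
    returns the indexes table. Experiments that fail analysis are recorded
    and re-raised as a summary error after the loop.
    """
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifests = sorted(input_dir.rglob(bio.MANIFEST_NAME))
    if not manifests:
        raise ConfigError(f"no experiments (manifest files) found under {input_dir}")
    rows, failures = [], []
    for mpath in manifests:
        exp_dir = mpath.parent
        exp_id = str(exp_dir.relative_to(input_dir))
        try:
            frames, manifest = bio.read_video(exp_dir)
            series = diameter_series(frames, manifest)
            idx = analyze_series(series, windows)
        except (ConfigError, AnalysisError) as exc:
            failures.append((exp_id, str(exc)))
            continue
        bio.write_table(
            out_dir / f"{exp_id.replace('/', '_')}_series.csv",
            pd.DataFrame({"time_s": series.time_s, "diameter_mm": series.diameter_mm}),
        )
        rows.append(
            {
                "experiment_id": exp_id,
                "condition": manifest.get("condition", ""),
                "mean_squeezed_diameter_mm": idx.mean_squeezed_diameter_mm,
                "residual_diameter_mm": idx.residual_diameter_mm,
                "oscillation_freq_hz": idx.oscillation_freq_hz,
            }
        )
    table = pd.DataFrame(rows)
    bio.write_table(out_dir / "indexes.csv", table)
    if failures:
        summary = "; ".join(f"{eid}: {msg}" for eid, msg in failures)
        raise AnalysisError(f"{len(failures)} experiment(s) failed: {summary}")
    return table


def run_stain(config: dict, out_dir: str | Path) -> pd.DataFrame:
    """Stain-quantification pipeline over a batch of dish images.

    Config keys: ``gamma``, ``bit_depth``, ``calibration_csv``, ``dishes``
    (list of dicts with path, dish_id, condition, state in {initial,
    incubated}, day label, and dish geometry ``center``/``radius_px`` or an
    ``auto_radius_band``). The stained-area threshold is pooled per
    condition (dish type) from the initial vs incubated group means.
    """
    out_dir = Path(out_dir)
    gamma = float(config.get("gamma", 1.8))
    bit_depth = int(config.get("bit_depth", 8))
    cal_path = config.get("calibration_csv")
    if cal_path is None or not Path(cal_path).exists():
        raise ConfigError("calibration_csv is missing or does not exist")
    cal = bio.read_calibration_table(cal_path)
    fit = fit_calibration(cal["mean_i_prime"].to_numpy(), cal["od"].to_numpy())
    dishes = config.get("dishes", [])
    if not dishes:
        raise ConfigError("no dishes listed in the configuration")

    records = []
    for dish in dishes:
        image = bio.read_gray_image(dish["path"], bit_depth=bit_depth)
        if "center" in dish and "radius_px" in dish:
            center, radius = tuple(dish["center"]), float(dish["radius_px"])
        elif "auto_radius_band" in dish:
            center, radius = detect_dish(image, tuple(dish["auto_radius_band"]))
        else:
            raise ConfigError(f"dish {dish.get('dish_id')} lacks geometry")
        od = decompensate(image, gamma)
        od.roi_mask = extract_roi(image, center, radius)
        result = stain_density(od, fit)
        records.append(
            {
                "dish_id": str(dish.get("dish_id", dish["path"])),
                "condition": str(dish.get("condition", "")),
                "day": str(dish.get("day", "")),
                "state": str(dish.get("state", "")),
                "mean_density": result.mean_density,
                "_od": od,
            }
        )

    df = pd.DataFrame(records)
    df["threshold"] = np.nan
    df["area_ratio_pct"] = np.nan
    for condition, group in df.groupby("condition"):
        initial = group.loc[group["state"] == "initial", "mean_density"]
        incubated = group.loc[group["state"] == "incubated", "mean_density"]
        if initial.empty or incubated.empty:
            raise ConfigError(
                f"condition {condition!r} needs both initial and incubated dishes"
            )
        thr = compute_threshold(initial.tolist(), incubated.tolist())
        for idx in group.index:
            df.loc[idx, "threshold"] = thr
            df.loc[idx, "area_ratio_pct"] = area_ratio(df.loc[idx, "_od"], thr)
    out = df.drop(columns=["_od", "state"]).copy()
    bio.write_table(Path(out_dir) / "stain_results.csv", out)
    return out


def run_bubble(config: dict, out_dir: str | Path) -> pd.DataFrame:
    """Measure the captive-bubble contact angle for each configured still."""
    images = config.get("images", [])
    if not images:
        raise ConfigError("no bubble images listed")
    rows = []
    for item in images:
        image = bio.read_gray_image(item["path"])
        res = measure_contact_angle(image, int(item["baseline_row"]))
        rows.append(
            {
                "image_id": str(item.get("image_id", item["path"])),
                "angle_deg": res.angle_deg,
                "fit_residual": res.fit_residual,
            }
        )
    table = pd.DataFrame(rows)
    bio.write_table(Path(out_dir) / "bubble_angles.csv", table)
    return table


def run_compare(values_csv: str | Path, pairings: list[tuple[str, str]], out_dir: str | Path) -> pd.DataFrame:
    """Gated t-test for each requested pair of groups in a tidy CSV."""
    from .stats import gated_t_test

    df = pd.read_csv(values_csv)
    if not {"group", "value"} <= set(df.columns):
        raise ConfigError("values CSV must have columns 'group' and 'value'")
    rows = []
    for g1, g2 in pairings:
        x = df.loc[df["group"] == g1, "value"].to_numpy()
        y = df.loc[df["group"] == g2, "value"].to_numpy()
        if x.size < 2 or y.size < 2:
            raise ConfigError(f"groups {g1!r}/{g2!r} need at least two values each")
        res = gated_t_test(x, y)
        rows.append(
            {
                "group_1": g1,
                "group_2": g2,
                "test_used": res.test_used,
                "f_statistic": res.f_statistic,
                "f_p_value": res.f_p_value,
                "t_statistic": res.t_statistic,
                "t_p_value": res.t_p_value,
                "n1": res.n1,
                "n2": res.n2,
                "significance": res.significance_tier,
            }
        )
    table = pd.DataFrame(rows)
    bio.write_table(Path(out_dir) / "comparisons.csv", table)
    return table


def simulate_bubble_batch(
    angles_deg: dict[str, float], seed: int = 0, noise_sd: float = 3.0
) -> pd.DataFrame:
    """Render one bubble still per labelled angle and re-measure it."""
    rows = []
    for i, (label, angle) in enumerate(sorted(angles_deg.items())):
        spec = BubblePhantomSpec(
            contact_angle_deg=angle, noise_sd=noise_sd, seed=seed * 977 + i
        )
        image, truth = make_bubble_image(spec)
        res = measure_contact_angle(image, spec.baseline_row)
        rows.append(
            {"label": label, "true_angle_deg": truth, "measured_angle_deg": res.angle_deg}
        )
    return pd.DataFrame(rows)
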