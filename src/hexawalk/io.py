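"""File formats: long-format trial CSV, ground-truth JSON, config YAML.

All interchange is plain text. A trial CSV has the header
``time_s,frame,marker_id,x_mm,y_mm`` (extra columns are preserved through
read/write round trips) preceded by ``# key: value`` comment lines holding
the trial metadata. Frames are 0-based, times in seconds from trial start.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import MARKER_LABELS, WalkerConfig, build_walker_config
from .walker import GroundTruth, Trial

__all__ = ["read_trial", "write_trial", "read_config", "write_config",
           "write_ground_truth", "write_image_stack", "read_image_stack",
           "write_gantry", "read_gantry", "TrialFormatError"]

REQUIRED_COLUMNS = ("time_s", "frame", "marker_id", "x_mm", "y_mm")


class TrialFormatError(ValueError):
    pass


def write_trial(trial: Trial, path) -> None:
    """Write a trial as long-format CSV with metadata comment lines."""
    path = Path(path)
    rows = []
    for label, xy in trial.markers.items():
        rows.append(pd.DataFrame({
            "time_s": trial.times_s,
            "frame": np.arange(trial.n_frames),
            "marker_id": label,
            "x_mm": xy[:, 0], "y_mm": xy[:, 1]}))
    df = pd.concat(rows, ignore_index=True)
    df = df.sort_values(["frame", "marker_id"], kind="mergesort",
                        ignore_index=True)
    if trial.extra is not None:
        extra = trial.extra.sort_values(["frame", "marker_id"],
                                        kind="mergesort", ignore_index=True)
        for col in extra.columns:
            if col not in df.columns:
                df[col] = extra[col].values
    with open(path, "w") as fh:
        fh.write(f"# animal_id: {trial.animal_id}\n")
        fh.write(f"# cohort: {trial.cohort}\n")
        fh.write(f"# frame_rate_hz: {trial.frame_rate_hz!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")  # exact round trip


def read_trial(path) -> Trial:
    """Read a long-format trial CSV; validates markers and monotonic time."""
    path = Path(path)
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TrialFormatError(f"missing required column {col!r}")
    bad = ~df["marker_id"].isin(MARKER_LABELS)
    if bad.any():
        row = int(np.flatnonzero(bad.values)[0])
        raise TrialFormatError(
            f"unknown marker_id {df['marker_id'].iloc[row]!r} at data row "
            f"{row}")
    frames = np.sort(df["frame"].unique())
    times = (df.drop_duplicates("frame").sort_values("frame")["time_s"]
             .to_numpy(float))
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        row = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
        raise TrialFormatError(f"non-monotonic time at frame {frames[row]}")
    markers = {}
    for label, sub in df.groupby("marker_id", sort=False):
        sub = sub.sort_values("frame")
        if len(sub) != len(frames):
            raise TrialFormatError(
                f"marker {label!r}: {len(sub)} rows for {len(frames)} frames")
        markers[label] = sub[["x_mm", "y_mm"]].to_numpy(float)
    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    extra = (df[["frame", "marker_id", *extra_cols]].copy()
             if extra_cols else None)
    return Trial(animal_id=meta.get("animal_id", "unknown"),
                 cohort=meta.get("cohort", "unknown"),
                 frame_rate_hz=float(meta.get("frame_rate_hz", "nan")),
                 times_s=times, markers=markers, extra=extra)


def write_config(config: WalkerConfig, path) -> None:
    """Serialise a walker configuration to YAML."""
    def plain(obj):
        if dataclasses.is_dataclass(obj):
            return {k: plain(v)
                    for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        return obj
    doc = {"legs": {k: {f: getattr(v, f) for f in
                        ("aep_deg", "pep_deg", "period_s", "stance_fraction",
                         "period_jitter_sd_s", "angle_noise_sd_deg")}
                    for k, v in config.legs.items()},
           "edges": [plain(e) for e in config.edges],
           "lesion": {"site": config.lesion.site},
           "body": plain(config.body),
           "vx_mm_s": config.vx_mm_s, "vy_mm_s": config.vy_mm_s,
           "yaw_deg_s": config.yaw_deg_s,
           "frame_rate_hz": config.frame_rate_hz, "seed": config.seed}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_config(path) -> WalkerConfig:
    path = Path(path)
    text = path.read_text()
    raw = (json.loads(text) if path.suffix.lower() == ".json"
           else yaml.safe_load(text))
    return build_walker_config(raw)


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(truth.to_json())


def write_image_stack(stack: np.ndarray, directory) -> list[Path]:
    """Write a stack as numbered lossless 8-bit grayscale PNGs."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, frame in enumerate(stack):
        p = directory / f"frame_{k:06d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def read_image_stack(directory) -> np.ndarray:
    import imageio.v3 as iio

    files = sorted(Path(directory).glob("frame_*.png"))
    if not files:
        raise FileNotFoundError(f"no frame_*.png files in {directory}")
    return np.stack([iio.imread(p) for p in files])


def write_gantry(gantry: np.ndarray, path) -> None:
    pd.DataFrame({"frame": np.arange(len(gantry)),
                  "cam_x_mm": gantry[:, 0],
                  "cam_y_mm": gantry[:, 1]}).to_csv(path, index=False,
                                                    float_format="%.9g")


def read_gantry(path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("frame", "cam_x_mm", "cam_y_mm"):
        if col not in df.columns:
            raise TrialFormatError(f"gantry file missing column {col!r}")
    df = df.sort_values("frame")
    return df[["cam_x_mm", "cam_y_mm"]].to_numpy(float)
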