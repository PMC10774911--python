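"""Readers and writers for frames, centers, tracks, and configuration."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detections import DetectionSet
from .tracking import Track, tracks_to_table

CENTER_COLUMNS = ["frame", "depth_um", "lateral_um", "intensity"]


def write_frames_tiff(path: str | Path, frames: np.ndarray) -> None:
    """Multi-page float32 TIFF, one page per time step."""
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))


def read_frames_tiff(path: str | Path) -> np.ndarray:
    frames = tifffile.imread(path)
    return frames[None] if frames.ndim == 2 else frames


def write_centers_csv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_centers_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def detections_from_table(table: pd.DataFrame, n_frames: int | None = None) -> list[DetectionSet]:
    """Per-frame detection sets from a tidy centers table."""
    n = int(table["frame"].max()) + 1 if n_frames is None else n_frames
    weight_col = "weight" if "weight" in table else "intensity"
    out = []
    for t in range(n):
        sub = table[table["frame"] == t]
        out.append(
            DetectionSet(
                sub[["depth_um", "lateral_um"]].to_numpy(),
                sub[weight_col].to_numpy() if weight_col in sub else np.ones(len(sub)),
                frame=t,
            )
        )
    return out


def write_tracks_csv(path: str | Path, tracks: list[Track]) -> None:
    tracks_to_table(tracks).to_csv(path, index=False)


def write_yaml(path: str | Path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce))


def _coerce(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
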