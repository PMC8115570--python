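"""Readers and writers for the package's on-disk formats.

Gaze dialect: tab-separated text with header
``subject_id  timestamp_ms  gaze_x_px  gaze_y_px  validity`` (one row per
sample, validity in {0,1}). Manifests are YAML. Frame stacks are directories
of zero-padded PNG files plus an optional JSON index.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .synthetic import SceneManifest, Segment

GAZE_COLUMNS = ["subject_id", "timestamp_ms", "gaze_x_px", "gaze_y_px", "validity"]


def write_gaze_tsv(path, df: pd.DataFrame) -> Path:
    path = Path(path)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gaze frame missing columns: {missing}")
    df[GAZE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.3f")
    return path


def read_gaze_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gaze file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: not a gaze TSV (missing {missing})")
    return df


def write_manifest(path, manifest: SceneManifest) -> Path:
    path = Path(path)
    doc = {
        "screen_size": list(manifest.screen_size),
        "fps": float(manifest.fps),
        "segments": [
            {"start": s.start, "end": s.end, "biological_side": s.biological_side}
            for s in manifest.segments
        ],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_manifest(path) -> SceneManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    doc = yaml.safe_load(path.read_text())
    segs = tuple(Segment(s["start"], s["end"], s["biological_side"]) for s in doc["segments"])
    return SceneManifest(segs, tuple(doc["screen_size"]), doc["fps"])


def write_frames(dirpath, frames: np.ndarray, index: dict | None = None) -> Path:
    """Write a (T, H, W[, 3]) array as PNG files ``frame_00000.png`` ..."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    arr = frames
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 1) if arr.dtype.kind == "f" else arr
        arr = (arr * 255).astype(np.uint8) if frames.dtype.kind == "f" else arr.astype(np.uint8)
    for t in range(arr.shape[0]):
        iio.imwrite(dirpath / f"frame_{t:05d}.png", arr[t])
    if index is not None:
        (dirpath / "index.json").write_text(json.dumps(index, indent=1))
    return dirpath


def read_frames(dirpath) -> np.ndarray:
    dirpath = Path(dirpath)
    files = sorted(dirpath.glob("frame_*.png"))
    if not files:
        raise FileNotFoundError(f"no frame_*.png files in {dirpath}")
    return np.stack([iio.imread(f) for f in files])


def read_frame_index(dirpath) -> dict:
    p = Path(dirpath) / "index.json"
    if not p.exists():
        raise FileNotFoundError(f"no index.json in {dirpath}")
    return json.loads(p.read_text())
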