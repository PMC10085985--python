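"""Reading and writing the on-disk formats: frame directories, tables, reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import FrameSequence

__all__ = [
    "read_video_dir",
    "write_frame_table",
    "read_frame_table",
    "write_report",
    "write_standardized_frames",
]


def read_video_dir(path: str | Path) -> FrameSequence:
    """Load a frame directory written by :func:`tearfilm.simulate.write_video_dir`.

    The directory holds numbered image files plus ``manifest.csv`` with
    columns ``filename`` and ``timestamp_s``.
    """
    import imageio.v3 as iio

    path = Path(path)
    manifest = pd.read_csv(path / "manifest.csv")
    frames = []
    for name in manifest["filename"]:
        img = np.asarray(iio.imread(path / name))
        if img.dtype == np.uint8:
            img = img.astype(np.float32) / 255.0
        frames.append(img)
    ts = manifest["timestamp_s"].to_numpy(dtype=float)
    fps = 1.0 / float(np.median(np.diff(ts))) if len(ts) > 1 else 30.0
    return FrameSequence(frames=frames, timestamps_s=ts, fps=fps, source_id=path.name)


def write_frame_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_frame_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, keep_default_na=False, na_values=[""])
    if "reason" in table.columns:
        table["reason"] = table["reason"].fillna("")
    return table


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, default=float))
    return path


def write_standardized_frames(records, path: str | Path) -> Path:
    """Write the standardized 384x384 crops of quality-passing records as PNGs."""
    import imageio.v3 as iio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, r in enumerate(records):
        if r.quality.passed and r.image is not None:
            iio.imwrite(
                path / f"std_{i:05d}.png", (np.asarray(r.image) * 255).astype(np.uint8)
            )
    return path
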