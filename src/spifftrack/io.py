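"""On-disk formats: 16-bit multi-page TIFF movies and CSV tables.

Ground truth and localizations travel as plain CSV; the physical metadata
(pixel size, frame interval) that CSV cannot carry lives in a JSON sidecar
next to the truth table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthdata import GroundTruth
from .tracking import Localization, TrackedSet

__all__ = [
    "write_frames_tiff",
    "read_frames_tiff",
    "write_truth",
    "read_truth",
    "write_localizations",
    "read_localizations",
]


def write_frames_tiff(frames, path: str | Path) -> None:
    """Write a movie as multi-page 16-bit grayscale TIFF.

    Intensities are kept as nonnegative floats in memory and quantized to
    uint16 only here.
    """
    stack = np.asarray(list(frames) if not isinstance(frames, np.ndarray) else frames)
    data = np.clip(np.rint(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), data, photometric="minisblack")


def read_frames_tiff(path: str | Path) -> np.ndarray:
    """Read a movie as a float array of shape (n_frames, ny, nx)."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return data.astype(float)


def _sidecar(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write ground truth as CSV (frame, particle_id, x_px, y_px) plus a
    JSON sidecar with pixel_nm and the frame interval."""
    n_frames, n_particles = truth.n_frames, truth.n_particles
    frames = np.repeat(np.arange(n_frames), n_particles)
    pids = np.tile(np.arange(n_particles), n_frames)
    flat = truth.positions.reshape(-1, 2)
    pd.DataFrame(
        {"frame": frames, "particle_id": pids, "x_px": flat[:, 0], "y_px": flat[:, 1]}
    ).to_csv(path, index=False)
    _sidecar(path).write_text(
        json.dumps({"pixel_nm": truth.pixel_nm, "dt_s": truth.dt_s})
    )


def read_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    n_frames = int(df["frame"].max()) + 1
    n_particles = int(df["particle_id"].max()) + 1
    pos = np.full((n_frames, n_particles, 2), np.nan)
    pos[df["frame"], df["particle_id"], 0] = df["x_px"]
    pos[df["frame"], df["particle_id"], 1] = df["y_px"]
    return GroundTruth(pos, dt_s=float(meta["dt_s"]), pixel_nm=float(meta["pixel_nm"]))


def write_localizations(tracked: TrackedSet, path: str | Path) -> None:
    """Write localizations as CSV: frame, particle_id (position within the
    frame, not an identity), x_px, y_px, quality, radius_used."""
    rows = []
    for fi, frame in enumerate(tracked.frames):
        for pid, loc in enumerate(frame):
            rows.append(
                (fi, pid, loc.x_px, loc.y_px, loc.quality, loc.radius_used, loc.fallback)
            )
    pd.DataFrame(
        rows,
        columns=[
            "frame", "particle_id", "x_px", "y_px", "quality", "radius_used", "fallback",
        ],
    ).to_csv(path, index=False)


def read_localizations(path: str | Path) -> TrackedSet:
    df = pd.read_csv(path)
    n_frames = int(df["frame"].max()) + 1 if len(df) else 0
    frames: list[list[Localization]] = [[] for _ in range(n_frames)]
    for row in df.itertuples(index=False):
        frames[int(row.frame)].append(
            Localization(
                frame_index=int(row.frame),
                x_px=float(row.x_px),
                y_px=float(row.y_px),
                quality=float(row.quality),
                radius_used=int(row.radius_used),
                fallback=bool(row.fallback),
            )
        )
    return TrackedSet(frames)
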