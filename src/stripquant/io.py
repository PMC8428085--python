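"""Frame-stack containers, burst averaging and TIFF round-trip.

A capture session is a sequence of bursts: every 20 s (default) the
camera grabs several frames of the same static scene in quick
succession.  Averaging the frames of one burst suppresses Poisson shot
noise by 1/sqrt(n) while leaving the mean signal untouched, so all
downstream analysis runs on the per-burst averaged image I(t).

Stacks are stored as individual 16-bit unsigned TIFF files (holding the
12-bit ADU range losslessly) plus a CSV manifest with columns
``frame_path``, ``burst``, ``timestamp_s`` and ``resolution_px_per_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import tifffile

ADC_MAX = 4095  # 12-bit analog-to-digital converter ceiling

__all__ = ["ADC_MAX", "FrameStack", "AveragedFrame", "average_burst",
           "average_stack", "save_stack", "load_stack"]


@dataclass
class FrameStack:
    """Raw sensor view: timestamped frames grouped into bursts."""

    frames: np.ndarray              # (n, h, w) uint16, ADU in [0, ADC_MAX]
    timestamps: np.ndarray          # (n,) seconds from sample dispense
    burst_index: np.ndarray         # (n,) int
    resolution_px_per_mm: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.burst_index = np.asarray(self.burst_index, dtype=np.int64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        n = self.frames.shape[0]
        if self.timestamps.shape != (n,) or self.burst_index.shape != (n,):
            raise ValueError("timestamps/burst_index length mismatch")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be non-decreasing")
        for b in np.unique(self.burst_index):
            ts = self.timestamps[self.burst_index == b]
            if np.ptp(ts) != 0:
                raise ValueError(f"burst {b} has varying timestamps")
        if self.resolution_px_per_mm <= 0:
            raise ValueError("resolution_px_per_mm must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_bursts(self) -> int:
        return int(np.unique(self.burst_index).size)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def bursts(self) -> Iterator[tuple[float, np.ndarray]]:
        """Yield (timestamp_s, frames) per burst in time order."""
        for b in np.unique(self.burst_index):
            sel = self.burst_index == b
            yield float(self.timestamps[sel][0]), self.frames[sel]


@dataclass(frozen=True)
class AveragedFrame:
    """Shot-noise-suppressed image I(t): pixelwise burst mean."""

    pixels: np.ndarray              # (h, w) float64
    t: float


def average_burst(frames: np.ndarray | list[np.ndarray],
                  t: float = 0.0) -> AveragedFrame:
    """Pixelwise arithmetic mean of one burst's frames.

    Values stay real (no re-quantization) to avoid bias in the summed
    line intensities downstream.
    """
    arr = np.asarray(frames, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot average an empty burst")
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("frames must share a single 2D shape")
    return AveragedFrame(pixels=arr.mean(axis=0), t=t)


def average_stack(stack: FrameStack) -> list[AveragedFrame]:
    """One averaged frame per burst, in time order."""
    return [average_burst(frames, t=t) for t, frames in stack.bursts()]


def save_stack(stack: FrameStack, out_dir: str | Path) -> Path:
    """Write frames as 16-bit TIFFs plus a CSV manifest; returns it."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(stack.n_frames):
        name = f"frame_{i:04d}.tif"
        tifffile.imwrite(out_dir / name,
                         stack.frames[i].astype(np.uint16))
        rows.append({"frame_path": name,
                     "burst": int(stack.burst_index[i]),
                     "timestamp_s": float(stack.timestamps[i]),
                     "resolution_px_per_mm": stack.resolution_px_per_mm})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False, float_format="%.6f")
    return manifest


def load_stack(manifest: str | Path) -> FrameStack:
    """Load a stack from a manifest CSV written by :func:`save_stack`."""
    manifest = Path(manifest)
    if manifest.is_dir():
        manifest = manifest / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"manifest not found: {manifest}")
    table = pd.read_csv(manifest)
    frames = []
    for rel in table["frame_path"]:
        path = manifest.parent / rel
        if not path.exists():
            raise FileNotFoundError(f"missing frame file: {path}")
        frames.append(tifffile.imread(path))
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")
    return FrameStack(frames=np.stack(frames),
                      timestamps=table["timestamp_s"].to_numpy(),
                      burst_index=table["burst"].to_numpy(),
                      resolution_px_per_mm=float(
                          table["resolution_px_per_mm"].iloc[0]))
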