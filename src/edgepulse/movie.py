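"""Lightweight containers for calibrated time-lapse movies and ratio movies.

A :class:`TimeLapseMovie` holds one ``(T, H, W)`` float array per named channel
plus the physical calibration (μm per pixel, seconds per frame) that every
downstream quantity (velocities in μm/min, depths in μm, lags in s) depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of an acquisition.

    Parameters
    ----------
    um_per_px : float
        Lateral pixel size in micrometers.
    frame_interval_s : float
        Time between consecutive frames in seconds.
    """

    um_per_px: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        if self.um_per_px <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration values must be positive")

    @property
    def px_per_um(self) -> float:
        return 1.0 / self.um_per_px


@dataclass
class TimeLapseMovie:
    """Multi-channel time-lapse stack with physical calibration.

    ``channels`` maps channel name (e.g. ``"FRET"``, ``"CFP"``) to a
    ``(T, H, W)`` float array. All channels must share one shape.
    """

    channels: dict[str, np.ndarray]
    calibration: Calibration

    def __post_init__(self) -> None:
        shapes = {c: a.shape for c, a in self.channels.items()}
        if not shapes:
            raise ValueError("movie needs at least one channel")
        first = next(iter(shapes.values()))
        if len(first) != 3:
            raise ValueError("channel arrays must be (T, H, W)")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]

    def copy(self) -> "TimeLapseMovie":
        return TimeLapseMovie(
            {c: a.copy() for c, a in self.channels.items()}, self.calibration
        )

    def write_tiffs(self, outdir: str | Path, prefix: str = "") -> dict[str, Path]:
        """Write one multi-page TIFF per channel; returns channel -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for name, arr in self.channels.items():
            p = outdir / f"{prefix}{name}.tif"
            tifffile.imwrite(p, arr.astype(np.float32))
            paths[name] = p
        return paths

    @classmethod
    def from_tiffs(
        cls, paths: dict[str, str | Path], calibration: Calibration
    ) -> "TimeLapseMovie":
        channels = {
            name: np.asarray(tifffile.imread(p), dtype=np.float64)
            for name, p in paths.items()
        }
        return cls(channels, calibration)


@dataclass
class RatioMovie:
    """Per-pixel ratio movie (e.g. FRET/CFP) with per-frame validity masks.

    ``values`` is ``(T, H, W)``; entries are meaningful only where ``valid``
    (same shape, boolean) is True. Invalid pixels are stored as NaN.
    """

    values: np.ndarray
    valid: np.ndarray
    calibration: Calibration
    empty_frames: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must share a shape")
        if self.values.ndim != 3:
            raise ValueError("ratio movie must be (T, H, W)")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def frame_means(self) -> np.ndarray:
        """Mean ratio over valid pixels, per frame (NaN for empty frames)."""
        out = np.full(self.n_frames, np.nan)
        for t in range(self.n_frames):
            m = self.valid[t]
            if m.any():
                out[t] = float(np.nanmean(self.values[t][m]))
        return out

    def copy(self) -> "RatioMovie":
        return RatioMovie(
            self.values.copy(), self.valid.copy(), self.calibration,
            list(self.empty_frames),
        )
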