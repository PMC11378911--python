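"""Cell segmentation from reporter intensity and nearest-neighbor tracking.

Segmentation thresholds the (background-subtracted) FRET-channel intensity
histogram with Otsu's criterion on log intensities, refines the binary mask by
Gaussian smoothing + re-thresholding at 0.5, removes sub-pixel edge debris by
morphological opening with a 1-px disk, and drops components below a minimum
area. Tracking links per-frame masks by nearest-centroid consecutive pairing
with a distance cap; downstream edge analysis consumes exactly one track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk, opening


def segment_frame(
    frame: np.ndarray,
    min_area_px: int = 500,
    smooth_sigma: float = 2.0,
    threshold: float | None = None,
) -> list[np.ndarray]:
    """Segment one background-subtracted intensity frame into cell masks.

    A fixed ``threshold`` (intensity units) overrides the histogram-based
    choice. Returns one boolean mask per retained connected component (may be
    empty if nothing exceeds ``min_area_px``).
    """
    frame = np.asarray(frame, dtype=float)
    logf = np.log1p(np.maximum(frame, 0.0))
    if threshold is not None:
        thr = np.log1p(threshold)
    else:
        if np.ptp(logf) == 0:
            return []
        thr = threshold_otsu(logf)
    mask = logf > thr
    if not mask.any():
        return []
    # smooth the binary mask and re-threshold to round the edge
    mask = gaussian(mask.astype(float), sigma=smooth_sigma) > 0.5
    mask = opening(mask, disk(1))
    lab = label(mask, connectivity=2)
    out: list[np.ndarray] = []
    for region in regionprops(lab):
        if region.area >= min_area_px:
            out.append(lab == region.label)
    return out


@dataclass
class CellTrack:
    """One cell's per-frame masks linked across a contiguous frame range."""

    track_id: int
    start_frame: int
    masks: list[np.ndarray] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)

    @property
    def end_frame(self) -> int:
        return self.start_frame + len(self.masks) - 1

    @property
    def n_frames(self) -> int:
        return len(self.masks)

    def mask_stack(self) -> np.ndarray:
        return np.stack(self.masks)

    def to_frame_table(self) -> pd.DataFrame:
        rows = [
            {
                "frame": self.start_frame + i,
                "id": self.track_id,
                "centroid_y": c[0],
                "centroid_x": c[1],
                "area": int(m.sum()),
            }
            for i, (m, c) in enumerate(zip(self.masks, self.centroids))
        ]
        return pd.DataFrame(rows)


def _centroid(mask: np.ndarray) -> tuple[float, float]:
    com = ndimage.center_of_mass(mask)
    return float(com[0]), float(com[1])


def track_cells(
    frame_masks: list[list[np.ndarray]],
    max_distance_px: float = 50.0,
    min_track_frames: int = 5,
) -> list[CellTrack]:
    """Link per-frame masks into tracks by nearest-centroid pairing.

    Each mask in frame t+1 is paired to the nearest live track endpoint from
    frame t if within ``max_distance_px``; pairing is greedy in increasing
    distance, with equidistant ties broken toward the lowest track id.
    Unpaired masks start new tracks; tracks shorter than ``min_track_frames``
    are dropped. No gap closing: a track that misses a frame is terminated.
    """
    if len(frame_masks) < 2:
        raise ValueError("tracking needs >= 2 frames")
    tracks: list[CellTrack] = []
    live: list[CellTrack] = []
    next_id = 0
    for t, masks in enumerate(frame_masks):
        cents = [_centroid(m) for m in masks]
        assigned = [False] * len(masks)
        if live:
            pairs = []
            for mi, c in enumerate(cents):
                for tr in live:
                    d = float(np.hypot(
                        c[0] - tr.centroids[-1][0], c[1] - tr.centroids[-1][1]
                    ))
                    if d <= max_distance_px:
                        pairs.append((d, tr.track_id, mi, tr))
            pairs.sort(key=lambda p: (p[0], p[1]))
            used_tracks: set[int] = set()
            for d, tid, mi, tr in pairs:
                if assigned[mi] or tid in used_tracks:
                    continue
                tr.masks.append(masks[mi])
                tr.centroids.append(cents[mi])
                assigned[mi] = True
                used_tracks.add(tid)
            live = [tr for tr in live if tr.track_id in used_tracks]
        else:
            live = []
        for mi, m in enumerate(masks):
            if assigned[mi]:
                continue
            tr = CellTrack(track_id=next_id, start_frame=t)
            next_id += 1
            tr.masks.append(m)
            tr.centroids.append(cents[mi])
            tracks.append(tr)
            live.append(tr)
        live.sort(key=lambda tr: tr.track_id)
    return [tr for tr in tracks if tr.n_frames >= min_track_frames]


def segment_movie(
    stack: np.ndarray,
    min_area_px: int = 500,
    smooth_sigma: float = 2.0,
    threshold: float | None = None,
) -> list[list[np.ndarray]]:
    """Apply :func:`segment_frame` to every frame of a (T, H, W) stack."""
    return [
        segment_frame(f, min_area_px=min_area_px, smooth_sigma=smooth_sigma,
                      threshold=threshold)
        for f in np.asarray(stack)
    ]


def tracks_to_csv(tracks: list[CellTrack], path) -> None:
    if tracks:
        pd.concat([t.to_frame_table() for t in tracks]).to_csv(path, index=False)
    else:
        pd.DataFrame(
            columns=["frame", "id", "centroid_y", "centroid_x", "area"]
        ).to_csv(path, index=False)
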