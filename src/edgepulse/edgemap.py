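"""Edge windowing, velocity mapping, and windowed activity sampling.

The segmented cell edge is traced as a closed contour, resampled to 900
equal-arc-length boundary points from a deterministic angular origin (the
boundary point nearest the ray at angle 0 from the mask centroid), and binned
in groups of five into 180 averaged coordinate windows. Edge velocity per raw
window is the dot product of the frame-to-frame boundary displacement with the
outward unit normal, converted to μm/min; reporter activity per window is the
mean ratio over the window's depth-band pixels (cumulative band from the edge,
assigned by distance transform + nearest boundary point).

Frame-to-frame window correspondence is by normalized arc length anchored at
each frame's centroid-relative angular origin — deterministic and stable for
compact cells. Velocity column t describes the t → t+1 displacement; the last
column of a velocity map is NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import json
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.measure import find_contours

from .movie import Calibration, RatioMovie

N_RAW_WINDOWS = 900
BIN_FACTOR = 5
N_WINDOWS = N_RAW_WINDOWS // BIN_FACTOR  # 180

#: Window depths (μm) used throughout: cumulative bands from the cell edge.
DEFAULT_DEPTHS_UM = (0.98, 2.0, 3.3, 4.9, 6.5, 8.1)


@dataclass
class FrameWindows:
    """Windowing of one frame's mask: boundary points, normals, depth pixels."""

    points: np.ndarray        # (900, 2) float, (row, col) px
    normals: np.ndarray       # (900, 2) float, outward unit normals (row, col)
    centroid: tuple[float, float]
    perimeter_px: float
    # depth μm -> (pixel_rows, pixel_cols, window_id in 0..179)
    depth_pixels: dict[float, tuple[np.ndarray, np.ndarray, np.ndarray]]

    @property
    def window_centers(self) -> np.ndarray:
        """(180, 2) centers of the binned windows."""
        return self.points.reshape(N_WINDOWS, BIN_FACTOR, 2).mean(axis=1)

    @property
    def arc_lengths_px(self) -> np.ndarray:
        """(900,) arc length of each raw window segment."""
        diffs = np.diff(
            np.vstack([self.points, self.points[:1]]), axis=0
        )
        return np.hypot(diffs[:, 0], diffs[:, 1])


@dataclass
class EdgeWindowGrid:
    """Per-frame windowings for one cell track."""

    frames: list[FrameWindows]
    calibration: Calibration
    depths_um: tuple[float, ...]

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class SpatiotemporalMap:
    """180 × T matrix of a per-window quantity over time."""

    values: np.ndarray        # (180, T)
    kind: str                 # "velocity" | "activity"
    calibration: Calibration
    depth_um: float | None = None

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values).to_csv(path, index=False)

    def write_sidecar(self, path) -> None:
        Path(path).write_text(json.dumps({
            "kind": self.kind,
            "depth_um": self.depth_um,
            "um_per_px": self.calibration.um_per_px,
            "frame_interval_s": self.calibration.frame_interval_s,
        }, indent=2))


def _trace_closed_contour(mask: np.ndarray, smooth_px: float = 6.0) -> np.ndarray:
    """Longest closed 0.5-level contour of a binary mask, (N, 2) (row, col).

    The contour is smoothed with a periodic Gaussian along arc length
    (σ = ``smooth_px`` pixels) to suppress the rasterization staircase, which
    would otherwise inflate the perimeter by several percent and corrupt the
    normals.
    """
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no contour")
    contour = max(contours, key=lambda c: c.shape[0])
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    if smooth_px > 0 and contour.shape[0] > 8:
        spacing = float(np.mean(np.hypot(
            *np.diff(np.vstack([contour, contour[:1]]), axis=0).T
        )))
        sigma_pts = max(smooth_px / max(spacing, 1e-6), 1e-6)
        contour = np.column_stack([
            ndimage.gaussian_filter1d(contour[:, 0], sigma_pts, mode="wrap"),
            ndimage.gaussian_filter1d(contour[:, 1], sigma_pts, mode="wrap"),
        ])
    return np.vstack([contour, contour[:1]])


def _resample_equal_arc(
    contour: np.ndarray, centroid: tuple[float, float], n: int
) -> np.ndarray:
    """Resample a closed contour to n equal-arc points from the angle-0 origin.

    The origin is the contour vertex whose angle around the centroid (atan2 of
    (col - c_col, row - c_row) measured in image coordinates) is closest to 0,
    ties broken toward the lowest vertex index.
    """
    pts = contour[:-1]  # drop duplicate closing vertex
    ang = np.arctan2(pts[:, 0] - centroid[0], pts[:, 1] - centroid[1])
    start = int(np.argmin(np.abs(ang)))
    pts = np.roll(pts, -start, axis=0)
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.arange(n) * total / n
    rows = np.interp(targets, s, closed[:, 0])
    cols = np.interp(targets, s, closed[:, 1])
    return np.column_stack([rows, cols])


def _outward_normals(points: np.ndarray, centroid, stencil: int = 12) -> np.ndarray:
    # wide central-difference stencil: adjacent resampled points are sub-pixel
    # apart, so a +-1 stencil would amplify residual rasterization noise
    nxt = np.roll(points, -stencil, axis=0)
    prv = np.roll(points, stencil, axis=0)
    tangent = nxt - prv
    norm = np.hypot(tangent[:, 0], tangent[:, 1])
    norm[norm == 0] = 1.0
    tangent = tangent / norm[:, None]
    normal = np.column_stack([tangent[:, 1], -tangent[:, 0]])
    radial = points - np.asarray(centroid)[None, :]
    flip = np.sum(normal * radial, axis=1) < 0
    normal[flip] *= -1.0
    return normal


def make_windows(
    mask: np.ndarray,
    calibration: Calibration,
    depths_um: tuple[float, ...] = DEFAULT_DEPTHS_UM,
) -> FrameWindows:
    """Window one frame's mask: 900 raw boundary points + depth-band pixels.

    The mask must be a single connected component not touching the image
    border; holes are filled before tracing. Interior pixels within each
    cumulative depth band (Euclidean distance to the edge ≤ depth) are
    assigned to the nearest of the 900 boundary points and thence to one of
    the 180 binned windows.
    """
    mask = np.asarray(mask, dtype=bool)
    if (mask[0, :].any() or mask[-1, :].any()
            or mask[:, 0].any() or mask[:, -1].any()):
        raise ValueError("mask touches the image border")
    filled = ndimage.binary_fill_holes(mask)
    n_comp = ndimage.label(filled)[1]
    if n_comp != 1:
        raise ValueError(f"mask must have exactly one component, got {n_comp}")
    centroid = ndimage.center_of_mass(filled)
    contour = _trace_closed_contour(filled)
    points = _resample_equal_arc(contour, centroid, N_RAW_WINDOWS)
    normals = _outward_normals(points, centroid)
    perimeter = float(
        np.hypot(*np.diff(np.vstack([points, points[:1]]), axis=0).T).sum()
    )

    dist_px = ndimage.distance_transform_edt(filled)
    tree = cKDTree(points)
    depth_pixels: dict[float, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    max_depth_px = max(depths_um) / calibration.um_per_px
    rows, cols = np.nonzero(filled & (dist_px <= max_depth_px))
    if rows.size:
        _, nearest_raw = tree.query(np.column_stack([rows, cols]))
        window_id = (nearest_raw // BIN_FACTOR).astype(np.int64)
        d = dist_px[rows, cols]
        for depth in depths_um:
            sel = d <= depth / calibration.um_per_px
            depth_pixels[float(depth)] = (rows[sel], cols[sel], window_id[sel])
    else:
        for depth in depths_um:
            depth_pixels[float(depth)] = (
                np.zeros(0, int), np.zeros(0, int), np.zeros(0, int)
            )
    return FrameWindows(
        points=points,
        normals=normals,
        centroid=(float(centroid[0]), float(centroid[1])),
        perimeter_px=perimeter,
        depth_pixels=depth_pixels,
    )


def make_grid(
    masks: np.ndarray | list[np.ndarray],
    calibration: Calibration,
    depths_um: tuple[float, ...] = DEFAULT_DEPTHS_UM,
) -> EdgeWindowGrid:
    """Window every frame of a mask stack."""
    frames = [make_windows(m, calibration, depths_um) for m in masks]
    return EdgeWindowGrid(frames=frames, calibration=calibration,
                          depths_um=tuple(float(d) for d in depths_um))


def edge_velocity_map(grid: EdgeWindowGrid) -> SpatiotemporalMap:
    """Edge velocity map in μm/min from consecutive frame windowings.

    Per raw window, displacement = matched boundary point at t+1 minus the
    point at t (arc-length correspondence); velocity = displacement · outward
    normal at t, scaled to μm/min; 900 values mean-binned to 180. Column t is
    the t → t+1 velocity; the final column is NaN.
    """
    if grid.n_frames < 2:
        raise ValueError("velocity map needs >= 2 frames")
    cal = grid.calibration
    scale = cal.um_per_px / cal.frame_interval_s * 60.0
    T = grid.n_frames
    vmap = np.full((N_WINDOWS, T), np.nan)
    for t in range(T - 1):
        a, b = grid.frames[t], grid.frames[t + 1]
        disp = b.points - a.points
        v_raw = np.sum(disp * a.normals, axis=1) * scale
        vmap[:, t] = v_raw.reshape(N_WINDOWS, BIN_FACTOR).mean(axis=1)
    return SpatiotemporalMap(values=vmap, kind="velocity", calibration=cal)


def activity_map(
    grid: EdgeWindowGrid, ratio: RatioMovie, depth_um: float
) -> SpatiotemporalMap:
    """Windowed mean reporter activity at one depth, (180, T).

    Windows whose depth band contains no valid ratio pixel are NaN.
    """
    depth = float(depth_um)
    if depth not in grid.depths_um:
        raise ValueError(
            f"depth {depth} μm not in grid depths {grid.depths_um}"
        )
    if ratio.n_frames != grid.n_frames:
        raise ValueError("ratio movie and grid differ in frame count")
    T = grid.n_frames
    amap = np.full((N_WINDOWS, T), np.nan)
    for t in range(T):
        rows, cols, wid = grid.frames[t].depth_pixels[depth]
        if rows.size == 0:
            continue
        vals = ratio.values[t][rows, cols]
        ok = ratio.valid[t][rows, cols] & np.isfinite(vals)
        if not ok.any():
            continue
        sums = np.bincount(wid[ok], weights=vals[ok], minlength=N_WINDOWS)
        counts = np.bincount(wid[ok], minlength=N_WINDOWS)
        present = counts > 0
        amap[present, t] = sums[present] / counts[present]
    return SpatiotemporalMap(values=amap, kind="activity", calibration=ratio.calibration,
                             depth_um=depth)


def smooth_map(
    stmap: SpatiotemporalMap, kernel: tuple[int, int] = (3, 3)
) -> SpatiotemporalMap:
    """NaN-aware moving-average smoothing, circular along the window axis.

    Missing values are ignored and the average renormalized by the number of
    present neighbors; a missing value surrounded by data is thereby imputed.
    """
    kw, kt = kernel
    if kw % 2 == 0 or kt % 2 == 0:
        raise ValueError("kernel sizes must be odd")
    vals = stmap.values
    filled = np.where(np.isfinite(vals), vals, 0.0)
    present = np.isfinite(vals).astype(float)
    # circular on the window axis, truncated (renormalized) at the time edges
    num = _circular_window_convolve(filled, kw, kt)
    den = _circular_window_convolve(present, kw, kt)
    out = np.full_like(vals, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return SpatiotemporalMap(values=out, kind=stmap.kind,
                             calibration=stmap.calibration,
                             depth_um=stmap.depth_um)


def _circular_window_convolve(arr: np.ndarray, kw: int, kt: int) -> np.ndarray:
    """Box-sum with circular wrap on axis 0 and zero padding on axis 1."""
    pw, pt = kw // 2, kt // 2
    wrapped = np.concatenate([arr[-pw:], arr, arr[:pw]], axis=0) if pw else arr
    if pt:
        wrapped = np.pad(wrapped, ((0, 0), (pt, pt)), mode="constant")
    k = np.ones((kw, kt))
    full = ndimage.convolve(wrapped, k, mode="constant", cval=0.0)
    if pw:
        full = full[pw:-pw]
    if pt:
        full = full[:, pt:-pt]
    return full


def render_heatmap(stmap: SpatiotemporalMap, path, cmap: str | None = None) -> None:
    """Write a heatmap PNG (blue-yellow divergent for velocity maps)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if cmap is None:
        cmap = "cividis" if stmap.kind == "velocity" else "viridis"
    fig, ax = plt.subplots(figsize=(8, 4))
    vals = stmap.values
    if stmap.kind == "velocity":
        vmax = np.nanmax(np.abs(vals)) or 1.0
        im = ax.imshow(vals, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    else:
        im = ax.imshow(vals, aspect="auto", cmap=cmap)
    ax.set_xlabel("frame")
    ax.set_ylabel("window")
    fig.colorbar(im, ax=ax, label=f"{stmap.kind}")
    fig.savefig(path, dpi=120)
    plt.close(fig)
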