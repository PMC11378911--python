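"""Raw stacks → background-subtracted, registered, bleach-corrected ratios.

The ratiometric chain mirrors standard FRET-biosensor practice: a blank-well
background model is subtracted, the acceptor channel is registered onto the
donor by phase correlation of temporal means (chromatic/camera offsets are
static), both channels are noise-filtered with the same disk-mean kernel
before the per-pixel division, and the ratio movie is divided by a bleaching
curve derived from control cells whose true ratio is assumed constant.
Percentile clipping (default 1st/99th over all valid pixels of the movie)
tames outlier ratios in localization-based reporters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.morphology import disk
from skimage.registration import phase_cross_correlation

from .movie import RatioMovie, TimeLapseMovie


def _disk_mean_kernel(radius: int) -> np.ndarray:
    k = disk(radius).astype(float)
    return k / k.sum()


def disk_mean_filter(image: np.ndarray, radius: int) -> np.ndarray:
    """Circular (disk) averaging filter, nearest-edge padding."""
    if radius <= 0:
        return image.astype(float, copy=True)
    return ndimage.convolve(
        image.astype(float), _disk_mean_kernel(radius), mode="nearest"
    )


@dataclass
class BackgroundModel:
    """Per-channel smoothed blank-well background images."""

    images: dict[str, np.ndarray]
    n_source_frames: dict[str, int]

    def for_channel(self, channel: str) -> np.ndarray:
        return self.images[channel]


def build_background_model(
    blank_stacks: dict[str, list[np.ndarray]], filter_radius: int = 5
) -> BackgroundModel:
    """Average blank-well frames per channel, then disk-mean smooth.

    ``blank_stacks`` maps channel name to a list of (T, H, W) or (H, W)
    arrays from wells without cells.
    """
    images: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for channel, stacks in blank_stacks.items():
        if not stacks:
            raise ValueError(f"no blank stacks for channel {channel!r}")
        frames = []
        for s in stacks:
            s = np.asarray(s, dtype=float)
            frames.extend(s if s.ndim == 3 else [s])
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"blank frames for {channel!r} differ in shape")
        mean = np.mean(frames, axis=0)
        images[channel] = disk_mean_filter(mean, filter_radius)
        counts[channel] = len(frames)
    return BackgroundModel(images=images, n_source_frames=counts)


def subtract_background(
    movie: TimeLapseMovie,
    model: BackgroundModel,
    neighborhood_radius: int = 5,
) -> TimeLapseMovie:
    """Subtract the local-median-summarized background; floor at zero.

    Per pixel, the subtracted value is the median of the averaged background
    image within a disk neighborhood (robust local background), applied
    identically to every frame.
    """
    out: dict[str, np.ndarray] = {}
    footprint = disk(neighborhood_radius).astype(bool)
    for channel, arr in movie.channels.items():
        bg = model.for_channel(channel)
        if bg.shape != movie.frame_shape:
            raise ValueError(
                f"background shape {bg.shape} != frame shape {movie.frame_shape}"
            )
        bg_med = ndimage.median_filter(bg, footprint=footprint, mode="nearest")
        out[channel] = np.maximum(arr - bg_med[None, :, :], 0.0)
    return TimeLapseMovie(out, movie.calibration)


def register_channels(
    movie: TimeLapseMovie,
    reference: str = "CFP",
    max_shift_px: float = 10.0,
    upsample_factor: int = 20,
) -> tuple[TimeLapseMovie, dict[str, tuple[float, float]]]:
    """Align non-reference channels by one global subpixel translation.

    The shift is estimated by phase correlation between temporal-mean images
    (the inter-channel offset is a static chromatic/camera offset). Estimated
    shifts beyond ``max_shift_px`` trigger a warning and the identity
    transform. Returns the registered movie and the applied shift per channel.
    """
    if len(movie.channels) < 2:
        raise ValueError("registration needs >= 2 channels")
    ref_mean = movie[reference].mean(axis=0)
    out: dict[str, np.ndarray] = {reference: movie[reference].copy()}
    shifts: dict[str, tuple[float, float]] = {reference: (0.0, 0.0)}
    for channel, arr in movie.channels.items():
        if channel == reference:
            continue
        # classic (non-whitened) correlation: microscopy channels are smooth,
        # and phase whitening is dominated by noise on such images
        shift, _, _ = phase_cross_correlation(
            ref_mean, arr.mean(axis=0), upsample_factor=upsample_factor,
            normalization=None,
        )
        if np.hypot(*shift) > max_shift_px:
            warnings.warn(
                f"estimated shift {tuple(shift)} for {channel!r} exceeds "
                f"{max_shift_px} px; applying identity",
                stacklevel=2,
            )
            shift = np.zeros(2)
        if np.allclose(shift, 0.0):
            out[channel] = arr.copy()
        else:
            out[channel] = np.stack(
                [ndimage.shift(f, shift, order=1, mode="nearest") for f in arr]
            )
        shifts[channel] = (float(shift[0]), float(shift[1]))
    return TimeLapseMovie(out, movie.calibration), shifts


def compute_ratio(
    movie: TimeLapseMovie,
    num_channel: str,
    den_channel: str,
    masks: np.ndarray,
    smooth_radius: int = 2,
    den_floor: float = 1e-3,
) -> RatioMovie:
    """Per-pixel ratio of disk-smoothed channels inside per-frame masks.

    Pixels where the smoothed denominator falls below ``den_floor`` are
    invalid; frames with an empty mask are flagged in ``empty_frames``.
    """
    num = movie[num_channel]
    den = movie[den_channel]
    masks = np.asarray(masks, dtype=bool)
    if masks.shape != num.shape:
        raise ValueError("masks must match movie shape")
    T = movie.n_frames
    values = np.full(num.shape, np.nan)
    valid = np.zeros(num.shape, dtype=bool)
    empty: list[int] = []
    for t in range(T):
        if not masks[t].any():
            empty.append(t)
            continue
        n_s = disk_mean_filter(num[t], smooth_radius)
        d_s = disk_mean_filter(den[t], smooth_radius)
        ok = masks[t] & (d_s > den_floor)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = n_s / d_s
        values[t][ok] = r[ok]
        valid[t] = ok
    return RatioMovie(values, valid, movie.calibration, empty)


@dataclass
class BleachCurve:
    """Per-frame multiplicative bleaching correction curve, c(0) = 1."""

    c: np.ndarray
    kind: str                      # "empirical" | "exponential"
    frame_interval_s: float
    tau_s: float | None = None     # exponential kind only
    rate_per_s: float | None = None

    def __post_init__(self) -> None:
        if not np.isclose(self.c[0], 1.0):
            raise ValueError("bleach curve must be normalized to c(0) = 1")
        if np.any(self.c <= 0):
            raise ValueError("bleach curve must be strictly positive")

    def to_csv(self, path) -> None:
        pd.DataFrame({"frame": np.arange(self.c.size), "c": self.c}).to_csv(
            path, index=False
        )


def fit_bleach_curve(
    control_ratios: list[RatioMovie],
    kind: str = "empirical",
    smooth_frames: int = 5,
) -> BleachCurve:
    """Bleaching curve from control movies assumed to have constant truth.

    The per-frame mean ratio is averaged across control movies and normalized
    to frame 0. ``kind="empirical"`` applies a moving average (default 5
    frames); ``kind="exponential"`` fits c(t) = exp(−t/τ) and reports τ.
    """
    if not control_ratios:
        raise ValueError("need at least one control ratio movie")
    T = control_ratios[0].n_frames
    if T < 5:
        raise ValueError("bleach curve needs >= 5 frames")
    if any(r.n_frames != T for r in control_ratios):
        raise ValueError("control movies differ in length")
    dt = control_ratios[0].calibration.frame_interval_s
    curve = np.nanmean([r.frame_means() for r in control_ratios], axis=0)
    if np.any(~np.isfinite(curve)):
        raise ValueError("bleach curve undefined on some frames (empty masks)")
    curve = curve / curve[0]
    if kind == "empirical":
        sm = ndimage.uniform_filter1d(curve, size=smooth_frames, mode="nearest")
        sm = sm / sm[0]
        return BleachCurve(c=sm, kind=kind, frame_interval_s=dt)
    if kind == "exponential":
        t = np.arange(T) * dt

        def model(tt, rate):
            return np.exp(-rate * tt)

        r0 = max(-np.polyfit(t, np.log(np.maximum(curve, 1e-12)), 1)[0], 1e-12)
        popt, _ = optimize.curve_fit(model, t, curve, p0=[r0])
        rate = float(popt[0])
        return BleachCurve(
            c=model(t, rate), kind=kind, frame_interval_s=dt,
            tau_s=1.0 / rate if rate != 0 else np.inf, rate_per_s=rate,
        )
    raise ValueError(f"unknown bleach curve kind {kind!r}")


def bleach_correct(ratio: RatioMovie, curve: BleachCurve) -> RatioMovie:
    """Divide the ratio movie by the bleaching curve, frame-wise.

    Not idempotent: applying the same curve twice divides by c(t)² — callers
    must correct exactly once.
    """
    if curve.c.size < ratio.n_frames:
        raise ValueError("bleach curve does not cover all frames")
    out = ratio.copy()
    out.values = out.values / curve.c[: ratio.n_frames, None, None]
    return out


def clip_percentiles(
    ratio: RatioMovie, p_lo: float = 1.0, p_hi: float = 99.0
) -> RatioMovie:
    """Clip valid ratio values to whole-movie percentiles.

    Percentiles are computed over all valid pixels of the whole movie (linear
    interpolation between order statistics), so per-frame temporal dynamics
    are preserved.
    """
    vals = ratio.values[ratio.valid]
    if vals.size < 100:
        raise ValueError("percentile clipping needs >= 100 valid pixels")
    lo, hi = np.percentile(vals, [p_lo, p_hi])
    out = ratio.copy()
    out.values[out.valid] = np.clip(out.values[out.valid], lo, hi)
    return out
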