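"""Synthetic time-lapse generator with exportable ground truth.

Emulates the statistical structure of a randomly motile adherent cell imaged
with a ratiometric (FRET/CFP) activity reporter: a compact cell whose boundary
undergoes minute-scale, spatially localized protrusion and retraction events,
an edge-proximal "Rho-like" activity field that rises where and when the edge
retracts (with a configurable temporal lag), a deeper, delayed "NM2-like"
field, per-channel exponential photobleaching, additive background, and
additive Gaussian noise.

Model
-----
The cell boundary is star-shaped around a fixed center,

    r(θ, t) = R0 + Σ_i A_i · exp(-Δθ_i² / 2σ_i²) · S((t - t_i) / D_i),

where ``S`` is the integrated raised cosine, ``S(u) = u - sin(2πu)/(2π)`` on
[0, 1] (0 below, 1 above). Each event is therefore a Gaussian bump in angle
whose radial displacement rises monotonically from 0 to A_i over duration D_i
with a raised-cosine *velocity* pulse — one planted bump produces exactly one
signed edge-motion event, with closed-form normal velocity

    v(θ, t) = Σ_i A_i / D_i · exp(-Δθ_i²/2σ_i²) · (1 - cos(2π u_i)),  0<u_i<1.

Peak speed at the bump center is 2|A_i|/D_i (120·|A_i|/D_i in μm/min).

Activity coupling is phenomenological, not mechanistic:

    a(θ, t) = baseline + gain · max(0, -v(θ, t - lag)),

i.e. activity follows local retraction speed after a fixed lag, and the
NM2-like field is the same quantity further delayed and low-pass filtered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .movie import Calibration, TimeLapseMovie

TWO_PI = 2.0 * np.pi


def _as_array(value, n: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.full(n, float(arr[0]))
    if arr.size != n:
        raise ValueError(f"{name}: expected scalar or length {n}, got {arr.size}")
    return arr


@dataclass
class BoundaryParams:
    """Parameters of the deforming star-shaped boundary.

    Amplitudes are signed radial displacements in μm (positive = protrusion).
    ``event_angular_width`` is the Gaussian σ of the bump in radians.
    ``event_times`` / ``event_angles`` may be None, in which case events are
    spread over the movie and around the perimeter deterministically from the
    seed, with alternating protrusion/retraction signs.
    """

    base_radius: float = 60.0
    n_events: int = 10
    event_amplitude: float | tuple | list | np.ndarray | None = None
    event_duration: float | tuple | list | np.ndarray = 200.0
    event_angular_width: float | tuple | list | np.ndarray = 0.19
    event_times: tuple | list | np.ndarray | None = None
    event_angles: tuple | list | np.ndarray | None = None
    wave_speed: float = 0.0
    frame_interval: float = 25.0
    n_frames: int = 150
    seed: int = 0

    # resolved per-event arrays (filled in __post_init__)
    amplitudes: np.ndarray = field(init=False, repr=False)
    durations: np.ndarray = field(init=False, repr=False)
    widths: np.ndarray = field(init=False, repr=False)
    times: np.ndarray = field(init=False, repr=False)
    angles: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        n = int(self.n_events)
        if n < 0:
            raise ValueError("n_events must be >= 0")
        rng = np.random.default_rng([int(self.seed), 0x0E17])

        if self.event_amplitude is None:
            # alternate protrusion / retraction at the default event scale
            amp = np.where(np.arange(n) % 2 == 0, 13.5, -13.5)
        else:
            amp = _as_array(self.event_amplitude, n, "event_amplitude")
        self.amplitudes = amp
        self.durations = _as_array(self.event_duration, n, "event_duration")
        self.widths = _as_array(self.event_angular_width, n, "event_angular_width")
        if np.any(self.durations <= 0) or np.any(self.widths <= 0):
            raise ValueError("event durations and widths must be positive")

        duration_s = (self.n_frames - 1) * self.frame_interval
        if self.event_times is None:
            if n > 0:
                # stagger event onsets across the usable time span
                margin = self.durations.max() if n else 0.0
                usable = max(duration_s - margin - self.frame_interval, 1.0)
                base = np.linspace(
                    self.frame_interval, self.frame_interval + usable, n,
                    endpoint=False,
                )
                jitter = rng.uniform(0, usable / max(n, 1) * 0.3, size=n)
                self.times = base + jitter
            else:
                self.times = np.zeros(0)
        else:
            self.times = _as_array(self.event_times, n, "event_times")
        if self.event_angles is None:
            offset = rng.uniform(0, TWO_PI)
            self.angles = (np.linspace(0, TWO_PI, n, endpoint=False) + offset) % TWO_PI
        else:
            self.angles = _as_array(self.event_angles, n, "event_angles") % TWO_PI

        if n > 0 and self.base_radius <= np.abs(self.amplitudes).max():
            raise ValueError("base_radius must exceed max |event_amplitude|")

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) * self.frame_interval

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class CouplingParams:
    """Phenomenological coupling of reporter fields to edge motion."""

    activity_gain: float = 0.05      # ratio units per (μm/min) of retraction
    activity_lag: float = 50.0       # s; activity follows velocity
    activity_baseline: float = 1.0   # ratio units
    activity_depth_um: float = 2.0   # edge band in which activity is painted
    nm2_delay: float = 150.0         # s, extra delay of the NM2-like field
    nm2_depth_band: tuple[float, float] = (5.0, 8.0)  # μm from the edge
    noise_sd: float = 10.0           # intensity units, additive Gaussian
    bleach_tau_num: float = 3000.0   # s, FRET channel
    bleach_tau_den: float = 6000.0   # s, CFP channel
    background_level: float = 100.0  # intensity units

    def __post_init__(self) -> None:
        if self.activity_lag < 0:
            raise ValueError("activity_lag must be >= 0")
        if self.bleach_tau_num <= 0 or self.bleach_tau_den <= 0:
            raise ValueError("bleach taus must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class TrueEvent:
    """One planted edge-motion event as it appears on a 180×T velocity map."""

    kind: str                 # "protrusion" | "retraction"
    t_start: int              # first suprathreshold frame (velocity columns)
    t_end: int                # last suprathreshold frame, inclusive
    w_start: int              # window range (may wrap; w_start..w_end mod 180)
    w_end: int
    mean_velocity: float      # μm/min over the suprathreshold region
    peak_speed: float         # μm/min, finite-difference max at the bump center
    n_pixels: int             # suprathreshold map pixels


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that the analysis must recover."""

    true_events: list[TrueEvent] = field(default_factory=list)
    true_lag_s: float | None = None
    true_transition_frames: list[tuple[int, int]] = field(default_factory=list)
    true_bleach_taus: tuple[float, float] | None = None
    true_exponential_rate_k: float | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_events": [vars(e) for e in self.true_events],
            "true_lag_s": self.true_lag_s,
            "true_transition_frames": [list(t) for t in self.true_transition_frames],
            "true_bleach_taus": list(self.true_bleach_taus)
            if self.true_bleach_taus else None,
            "true_exponential_rate_k": self.true_exponential_rate_k,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _wrap_angle(dtheta: np.ndarray) -> np.ndarray:
    return (dtheta + np.pi) % TWO_PI - np.pi


@dataclass
class BoundarySeries:
    """Sampled boundary r(θ, t) plus closed-form radius/velocity evaluation."""

    params: BoundaryParams
    theta: np.ndarray          # dense angular grid, (n_theta,)
    radii: np.ndarray          # (n_frames, n_theta), μm
    ground_truth: SyntheticGroundTruth

    def radius_at(self, theta, t) -> np.ndarray:
        """Closed-form r(θ, t); θ in radians, t in seconds (broadcastable)."""
        p = self.params
        theta = np.asarray(theta, dtype=float)
        t = np.asarray(t, dtype=float)
        r = np.full(np.broadcast_shapes(theta.shape, t.shape), p.base_radius)
        for a, d, s, t0, th0 in zip(
            p.amplitudes, p.durations, p.widths, p.times, p.angles
        ):
            u = np.clip((t - t0) / d, 0.0, 1.0)
            step = u - np.sin(TWO_PI * u) / TWO_PI
            dth = _wrap_angle(theta - th0 - p.wave_speed * np.maximum(t - t0, 0.0))
            r = r + a * np.exp(-(dth**2) / (2 * s**2)) * step
        return r

    def velocity_at(self, theta, t) -> np.ndarray:
        """Closed-form instantaneous radial velocity in μm/min."""
        p = self.params
        theta = np.asarray(theta, dtype=float)
        t = np.asarray(t, dtype=float)
        v = np.zeros(np.broadcast_shapes(theta.shape, t.shape))
        for a, d, s, t0, th0 in zip(
            p.amplitudes, p.durations, p.widths, p.times, p.angles
        ):
            u = (t - t0) / d
            active = (u > 0) & (u < 1)
            rate = np.where(active, (1.0 - np.cos(TWO_PI * np.clip(u, 0, 1))) / d, 0.0)
            dth = _wrap_angle(theta - th0 - p.wave_speed * np.maximum(t - t0, 0.0))
            g = np.exp(-(dth**2) / (2 * s**2))
            v = v + a * g * rate
            if p.wave_speed != 0.0:
                u_c = np.clip(u, 0.0, 1.0)
                step = u_c - np.sin(TWO_PI * u_c) / TWO_PI
                dg = g * (dth / s**2) * p.wave_speed
                v = v + np.where(u > 0, a * dg * step, 0.0)
        return 60.0 * v

    def true_velocity_map(self, n_windows: int = 180) -> np.ndarray:
        """Forward-difference velocity on the window grid, μm/min.

        Column ``t`` holds the t → t+1 radial displacement rate, matching the
        convention of the measured edge-velocity maps; the last column is NaN.
        """
        p = self.params
        centers = (np.arange(n_windows) + 0.5) * TWO_PI / n_windows
        times = p.frame_times
        r = self.radius_at(centers[:, None], times[None, :])
        vmap = np.full((n_windows, p.n_frames), np.nan)
        vmap[:, :-1] = np.diff(r, axis=1) / p.frame_interval * 60.0
        return vmap

    @property
    def max_radius(self) -> float:
        return float(self.radii.max())


def _peak_center_speed(params: BoundaryParams, i: int, n_sub: int = 400) -> float:
    """Finite-difference peak |dr/dt| (μm/min) at event i's (moving) center."""
    t0, d = params.times[i], params.durations[i]
    tt = np.linspace(t0, t0 + d, n_sub)
    th = params.angles[i] + params.wave_speed * (tt - t0)
    # evaluate the single event's radius contribution directly
    u = np.clip((tt - t0) / d, 0, 1)
    step = u - np.sin(TWO_PI * u) / TWO_PI
    r = params.amplitudes[i] * step  # bump center: Gaussian factor = 1
    del th
    return float(np.max(np.abs(np.diff(r) / np.diff(tt))) * 60.0)


def _circular_range(windows: np.ndarray, n: int) -> tuple[int, int]:
    """Smallest circular [start, end] (mod n) covering the given windows."""
    present = np.zeros(n, dtype=bool)
    present[windows] = True
    if present.all():
        return 0, n - 1
    absent = np.nonzero(~present)[0]
    ext = np.concatenate([absent, absent + n])
    runs = np.split(ext, np.nonzero(np.diff(ext) > 1)[0] + 1)
    longest = max(runs, key=len)
    return int((longest[-1] + 1) % n), int((longest[0] - 1) % n)


def _true_events_from_map(
    boundary: "BoundarySeries", v_thresh: float, n_windows: int
) -> list[TrueEvent]:
    p = boundary.params
    vmap = boundary.true_velocity_map(n_windows)
    centers = (np.arange(n_windows) + 0.5) * TWO_PI / n_windows
    events: list[TrueEvent] = []
    for i in range(p.n_events):
        sign = 1.0 if p.amplitudes[i] > 0 else -1.0
        dth = np.abs(_wrap_angle(centers - p.angles[i]))
        wsel = dth <= 5.0 * p.widths[i]
        f0 = max(int(np.floor(p.times[i] / p.frame_interval)) - 1, 0)
        f1 = min(
            int(np.ceil((p.times[i] + p.durations[i]) / p.frame_interval)) + 1,
            p.n_frames - 2,
        )
        sub = vmap[np.ix_(wsel, np.arange(f0, f1 + 1))]
        supra = sign * sub > v_thresh
        if not supra.any():
            continue
        wi, ti = np.nonzero(supra)
        wids = np.nonzero(wsel)[0][np.unique(wi)]
        frames = np.arange(f0, f1 + 1)[np.unique(ti)]
        w_start, w_end = _circular_range(wids, n_windows)
        events.append(
            TrueEvent(
                kind="protrusion" if sign > 0 else "retraction",
                t_start=int(frames.min()),
                t_end=int(frames.max()),
                w_start=w_start,
                w_end=w_end,
                mean_velocity=float(sub[supra].mean()),
                peak_speed=_peak_center_speed(p, i),
                n_pixels=int(supra.sum()),
            )
        )
    return events


def simulate_boundary_series(
    params: BoundaryParams,
    n_theta: int = 1800,
    truth_v_thresh: float = 3.84,
    n_windows: int = 180,
) -> BoundarySeries:
    """Simulate the deforming boundary and derive its ground truth.

    Returns a :class:`BoundarySeries` whose ``ground_truth.true_events`` are
    the planted events as they appear on an analytic ``n_windows × T``
    velocity map thresholded at ``truth_v_thresh`` (μm/min) — the quantity the
    downstream event detector is expected to recover.
    """
    theta = np.linspace(0, TWO_PI, n_theta, endpoint=False)
    bs = BoundarySeries(
        params=params,
        theta=theta,
        radii=np.zeros((params.n_frames, n_theta)),
        ground_truth=SyntheticGroundTruth(),
    )
    bs.radii = bs.radius_at(theta[None, :], params.frame_times[:, None])
    if np.any(bs.radii <= 0):
        raise ValueError("parameters produce a non-positive radius; reduce "
                         "retraction amplitudes or increase base_radius")
    bs.ground_truth.true_events = _true_events_from_map(
        bs, truth_v_thresh, n_windows
    )
    bs.ground_truth.true_transition_frames = _true_transitions(bs, n_windows)
    return bs


def _true_transitions(bs: BoundarySeries, n_windows: int) -> list[tuple[int, int]]:
    """Zero crossings (+ → −) of the continuous center velocity.

    For every protrusion event immediately followed (at the same angle) by a
    retraction, returns ``(window_index, frame_index)`` of the true
    protrusion→retraction transition, on a fine time grid.
    """
    p = bs.params
    out: list[tuple[int, int]] = []
    for i in range(p.n_events):
        if p.amplitudes[i] <= 0 or p.wave_speed != 0.0:
            continue
        th = p.angles[i]
        # does a retraction start at this angle right at/after this event?
        partners = [
            j for j in range(p.n_events)
            if p.amplitudes[j] < 0
            and abs(_wrap_angle(np.array([p.angles[j] - th]))[0]) < p.widths[i]
            and 0 <= p.times[j] - (p.times[i] + p.durations[i]) <= 2 * p.frame_interval
        ]
        if not partners:
            continue
        tt = np.linspace(0, p.duration_s, 8 * p.n_frames)
        v = bs.velocity_at(np.array(th), tt)
        peak = int(np.argmax(v))
        below = np.nonzero(v[peak:] < 0)[0]
        if below.size == 0:
            continue
        t_cross = tt[peak + below[0]]
        w = int(th / TWO_PI * n_windows) % n_windows
        out.append((w, int(round(t_cross / p.frame_interval))))
    return out


def transition_pair_params(
    n_pairs: int = 5,
    amplitude: float = 10.0,
    protrusion_duration: float = 600.0,
    retraction_duration: float = 250.0,
    base_radius: float = 60.0,
    frame_interval: float = 25.0,
    seed: int = 0,
) -> BoundaryParams:
    """Boundary parameters planting protrusion→retraction pairs.

    Each pair is a slow protrusion (long enough to satisfy the >20-frame
    positive-velocity eligibility rule at 25 s/frame) immediately followed by
    a retraction at the same angle, producing a clean velocity zero crossing.
    """
    cycle = protrusion_duration + retraction_duration
    n_frames = int(np.ceil((cycle + 4 * frame_interval) / frame_interval)) + 2
    angles = np.linspace(0, TWO_PI, n_pairs, endpoint=False) + np.pi / n_pairs
    amps, durs, times, angs = [], [], [], []
    for k in range(n_pairs):
        amps += [amplitude, -amplitude]
        durs += [protrusion_duration, retraction_duration]
        times += [frame_interval, frame_interval + protrusion_duration]
        angs += [angles[k], angles[k]]
    return BoundaryParams(
        base_radius=base_radius,
        n_events=2 * n_pairs,
        event_amplitude=amps,
        event_duration=durs,
        event_times=times,
        event_angles=angs,
        frame_interval=frame_interval,
        n_frames=n_frames,
        seed=seed,
    )


@dataclass
class ActivityFields:
    """Edge-band activity a(θ, t) and deep-band NM2-like density m(θ, t)."""

    theta: np.ndarray      # (n_theta,)
    a: np.ndarray          # (n_frames, n_theta), ratio units
    m: np.ndarray          # (n_frames, n_theta)
    coupling: CouplingParams

    def activity_at(self, theta, frame: int) -> np.ndarray:
        return np.interp(theta, self.theta, self.a[frame], period=TWO_PI)

    def nm2_at(self, theta, frame: int) -> np.ndarray:
        return np.interp(theta, self.theta, self.m[frame], period=TWO_PI)


def simulate_activity_coupling(
    boundary: BoundarySeries, coupling: CouplingParams
) -> ActivityFields:
    """Couple reporter fields to the boundary's true normal velocity.

    ``a(θ, t) = baseline + gain · max(0, −v(θ, t − lag))`` with v evaluated on
    the closed-form boundary (v ≡ 0 before the movie starts); the NM2-like
    field is the same expression delayed by ``nm2_delay`` and low-pass
    filtered with a 3-frame moving average in time.
    """
    p = boundary.params
    if coupling.activity_lag > p.duration_s or coupling.nm2_delay > p.duration_s:
        raise ValueError("lag/delay exceeds movie duration")
    theta = boundary.theta
    times = p.frame_times

    def rectified(ts: np.ndarray) -> np.ndarray:
        v = boundary.velocity_at(theta[None, :], ts[:, None])
        v[ts <= 0, :] = 0.0
        return np.maximum(0.0, -v)

    a = coupling.activity_baseline + coupling.activity_gain * rectified(
        times - coupling.activity_lag
    )
    m_raw = coupling.activity_baseline + coupling.activity_gain * rectified(
        times - coupling.activity_lag - coupling.nm2_delay
    )
    m = ndimage.uniform_filter1d(m_raw, size=3, axis=0, mode="nearest")
    boundary.ground_truth.true_lag_s = coupling.activity_lag
    return ActivityFields(theta=theta, a=a, m=m, coupling=coupling)


@dataclass
class RenderOptics:
    """Rasterization geometry of the virtual microscope."""

    pixel_size_um: float = 0.33
    image_shape: tuple[int, int] | None = None  # None → sized to fit the cell
    margin_um: float = 4.0
    cfp_level: float = 1000.0   # uniform reporter density inside the cell
    n_blank_frames: int = 5
    include_nm2: bool = False


@dataclass
class RenderedMovie:
    movie: TimeLapseMovie
    blank: TimeLapseMovie
    masks: np.ndarray          # (T, H, W) bool, ground-truth cell masks
    center_px: tuple[float, float]


def render_timelapse(
    boundary: BoundarySeries,
    fields: ActivityFields,
    coupling: CouplingParams,
    optics: RenderOptics | None = None,
) -> RenderedMovie:
    """Rasterize the simulation into FRET/CFP stacks plus a blank stack.

    The CFP channel is a uniform reporter density inside the cell; the FRET
    channel is CFP × local activity (the activity field painted within
    ``activity_depth_um`` of the edge, baseline deeper), so the true per-pixel
    FRET/CFP inside the cell equals the activity field. Both channels then
    bleach exponentially with their own τ, gain a constant background, and
    additive Gaussian noise. The rasterized ground-truth mask per frame uses
    the star-shaped inside test ρ ≤ r(θ) (exact for this boundary family).
    """
    optics = optics or RenderOptics()
    p = boundary.params
    px = optics.pixel_size_um
    if optics.image_shape is None:
        half_px = int(np.ceil((boundary.max_radius + optics.margin_um) / px))
        shape = (2 * half_px + 1, 2 * half_px + 1)
    else:
        shape = tuple(optics.image_shape)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dx = (xx - cx) * px
    dy = (yy - cy) * px
    rho = np.hypot(dx, dy)
    phi = np.mod(np.arctan2(dy, dx), TWO_PI)

    rng = np.random.default_rng([int(p.seed), 0xF1E1])
    T = p.n_frames
    fret = np.zeros((T,) + shape, dtype=np.float64)
    cfp = np.zeros_like(fret)
    nm2 = np.zeros_like(fret) if optics.include_nm2 else None
    masks = np.zeros((T,) + shape, dtype=bool)
    depth_px = coupling.activity_depth_um / px
    band_lo, band_hi = (d / px for d in coupling.nm2_depth_band)

    for t in range(T):
        r_t = np.interp(phi, boundary.theta, boundary.radii[t], period=TWO_PI)
        inside = rho <= r_t
        if (
            inside[0, :].any() or inside[-1, :].any()
            or inside[:, 0].any() or inside[:, -1].any()
        ):
            raise ValueError("cell touches the image border; enlarge the image")
        masks[t] = inside
        dist = ndimage.distance_transform_edt(inside)
        act = np.full(shape, coupling.activity_baseline)
        edge_band = inside & (dist <= depth_px)
        act[edge_band] = fields.activity_at(phi[edge_band], t)
        cfp_t = optics.cfp_level * inside
        fret_t = cfp_t * act
        tsec = t * p.frame_interval
        fret[t] = fret_t * np.exp(-tsec / coupling.bleach_tau_num)
        cfp[t] = cfp_t * np.exp(-tsec / coupling.bleach_tau_den)
        if nm2 is not None:
            dens = np.full(shape, coupling.activity_baseline)
            deep = inside & (dist > band_lo) & (dist <= band_hi)
            dens[deep] = fields.nm2_at(phi[deep], t)
            nm2[t] = optics.cfp_level * dens * np.exp(
                -tsec / coupling.bleach_tau_den
            )

    channels = {"FRET": fret, "CFP": cfp}
    if nm2 is not None:
        channels["NM2"] = nm2
    for name in channels:
        channels[name] = (
            channels[name]
            + coupling.background_level
            + rng.normal(0.0, coupling.noise_sd, size=(T,) + shape)
            if coupling.noise_sd > 0
            else channels[name] + coupling.background_level
        )
    cal = Calibration(um_per_px=px, frame_interval_s=p.frame_interval)
    blank_rng = np.random.default_rng([int(p.seed), 0xB1A2])
    blank_channels = {}
    for name in channels:
        b = np.full((optics.n_blank_frames,) + shape, coupling.background_level)
        if coupling.noise_sd > 0:
            b = b + blank_rng.normal(0.0, coupling.noise_sd, size=b.shape)
        blank_channels[name] = b
    boundary.ground_truth.true_bleach_taus = (
        coupling.bleach_tau_num, coupling.bleach_tau_den
    )
    return RenderedMovie(
        movie=TimeLapseMovie(channels, cal),
        blank=TimeLapseMovie(blank_channels, cal),
        masks=masks,
        center_px=(cy, cx),
    )


def simulate_movie(
    params: BoundaryParams | None = None,
    coupling: CouplingParams | None = None,
    optics: RenderOptics | None = None,
) -> tuple[RenderedMovie, BoundarySeries, ActivityFields]:
    """Convenience wrapper: boundary → coupling → rendering with defaults."""
    params = params or BoundaryParams()
    coupling = coupling or CouplingParams()
    boundary = simulate_boundary_series(params)
    fields = simulate_activity_coupling(boundary, coupling)
    rendered = render_timelapse(boundary, fields, coupling, optics)
    return rendered, boundary, fields


def write_simulation(
    outdir: str | Path, rendered: RenderedMovie, boundary: BoundarySeries
) -> dict[str, Path]:
    """Write channel TIFFs, blank TIFFs, masks and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = rendered.movie.write_tiffs(outdir)
    for name, arr in rendered.blank.channels.items():
        p = outdir / f"blank_{name}.tif"
        tifffile.imwrite(p, arr.astype(np.float32))
        paths[f"blank_{name}"] = p
    mask_path = outdir / "true_masks.tif"
    tifffile.imwrite(mask_path, rendered.masks.astype(np.uint8))
    paths["true_masks"] = mask_path
    gt_path = outdir / "ground_truth.json"
    boundary.ground_truth.to_json(gt_path)
    paths["ground_truth"] = gt_path
    return paths
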