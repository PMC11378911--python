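"""Protrusion/retraction events, transitions, buildup traces, excitability.

Events are connected suprathreshold regions of the (smoothed) edge-velocity
map: protrusions where v > v_thresh (default 3.84 μm/min), retractions where
v < −v_thresh, 8-connected with circular wrap along the window axis (the cell
edge is a ring), kept if they cover at least ``min_area`` map pixels (default
25). Protrusion→retraction transitions are found on a 15-window ROI-mean
velocity trace by the rule: first frame x with negative acceleration, positive
velocity at x−1 and negative velocity at x; of x−1 and x, the frame with the
smaller |velocity| is the transition point (ties toward x−1), and only
transitions preceded by more than 20 frames of positive ROI-mean velocity are
eligible. Aligned 41-frame (±20) velocity and activity traces pool across
events, and the excitability diagnostic regresses dA/dt on A during the
buildup window (default frames −14…+3 ≈ −6 min…+1 min at 25 s/frame): a
positive slope indicates self-amplifying (excitable) activation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .edgemap import SpatiotemporalMap

DEFAULT_V_THRESH = 3.84   # μm/min
DEFAULT_MIN_AREA = 25     # map pixels
ROI_WINDOWS = 15          # 15 of 180 windows = 8.33% of the perimeter
TRACE_HALF = 20           # ±20 frames → 41-frame traces


@dataclass
class Event:
    """One connected suprathreshold region of a velocity map."""

    kind: str                     # "protrusion" | "retraction"
    pixels: tuple[np.ndarray, np.ndarray]   # (window_idx, frame_idx)
    t_start: int
    t_end: int
    w_start: int                  # window range start (may wrap mod 180)
    w_end: int
    area: int
    mean_velocity: float          # μm/min
    duration_min: float
    span_pct: float               # distinct windows / 180 × 100
    mean_activity: float | None = None
    relative_activity: float | None = None

    def as_row(self) -> dict:
        return {
            "type": self.kind,
            "t_start": self.t_start,
            "t_end": self.t_end,
            "w_start": self.w_start,
            "w_end": self.w_end,
            "area": self.area,
            "mean_v": self.mean_velocity,
            "duration_min": self.duration_min,
            "span_pct": self.span_pct,
            "mean_activity": self.mean_activity,
            "rel_activity": self.relative_activity,
        }


@dataclass
class EventSet:
    events: list[Event] = field(default_factory=list)
    v_thresh: float = DEFAULT_V_THRESH
    min_area: int = DEFAULT_MIN_AREA

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def protrusions(self) -> list[Event]:
        return [e for e in self.events if e.kind == "protrusion"]

    @property
    def retractions(self) -> list[Event]:
        return [e for e in self.events if e.kind == "retraction"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.as_row() for e in self.events])


def _label_circular(binary: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected labeling with circular wrap along axis 0 (windows)."""
    structure = np.ones((3, 3), dtype=bool)
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return labels, 0
    # merge components that touch across the window seam (rows -1 and 0)
    parent = list(range(n + 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    top, bottom = labels[0], labels[-1]
    T = binary.shape[1]
    for t in range(T):
        if top[t] == 0:
            continue
        for dt in (-1, 0, 1):
            tt = t + dt
            if 0 <= tt < T and bottom[tt] != 0:
                union(int(top[t]), int(bottom[tt]))
    out = labels.copy()
    remap: dict[int, int] = {}
    next_label = 0
    for lab in range(1, n + 1):
        root = find(lab)
        if root not in remap:
            next_label += 1
            remap[root] = next_label
    for lab in range(1, n + 1):
        out[labels == lab] = remap[find(lab)]
    return out, next_label


def _window_range(windows: np.ndarray, n_windows: int) -> tuple[int, int]:
    """Circular [start, end] covering the occupied windows with the smallest arc."""
    present = np.zeros(n_windows, dtype=bool)
    present[windows] = True
    if present.all():
        return 0, n_windows - 1
    # longest run of absent windows defines the gap; range is its complement
    absent = np.nonzero(~present)[0]
    ext = np.concatenate([absent, absent + n_windows])
    runs = np.split(ext, np.nonzero(np.diff(ext) > 1)[0] + 1)
    longest = max(runs, key=len)
    start = (longest[-1] + 1) % n_windows
    end = (longest[0] - 1) % n_windows
    return int(start), int(end)


def detect_events(
    velocity: SpatiotemporalMap,
    v_thresh: float = DEFAULT_V_THRESH,
    min_area: int = DEFAULT_MIN_AREA,
    measure_map: SpatiotemporalMap | None = None,
) -> EventSet:
    """Detect protrusion and retraction events on a velocity map (μm/min).

    Thresholding and connectivity run on ``velocity`` (typically the smoothed
    map, so stochastic noise does not fragment events); per-event mean
    velocities are taken from ``measure_map`` when given (typically the
    unsmoothed map, so the amplitude statistic is not biased low by the
    denoising filter).
    """
    vals = velocity.values
    stat_vals = measure_map.values if measure_map is not None else vals
    if stat_vals.shape != vals.shape:
        raise ValueError("measure_map must match the velocity map shape")
    dt_min = velocity.calibration.frame_interval_s / 60.0
    events: list[Event] = []
    for kind, sign in (("protrusion", 1.0), ("retraction", -1.0)):
        binary = np.isfinite(vals) & (sign * vals > v_thresh)
        labels, n = _label_circular(binary)
        for lab in range(1, n + 1):
            wi, ti = np.nonzero(labels == lab)
            if wi.size < min_area:
                continue
            w_start, w_end = _window_range(wi, vals.shape[0])
            n_windows_distinct = np.unique(wi).size
            n_frames_distinct = np.unique(ti).size
            events.append(Event(
                kind=kind,
                pixels=(wi, ti),
                t_start=int(ti.min()),
                t_end=int(ti.max()),
                w_start=w_start,
                w_end=w_end,
                area=int(wi.size),
                mean_velocity=float(np.nanmean(stat_vals[wi, ti])),
                duration_min=n_frames_distinct * dt_min,
                span_pct=n_windows_distinct / vals.shape[0] * 100.0,
            ))
    events.sort(key=lambda e: (e.t_start, e.w_start, e.kind))
    return EventSet(events=events, v_thresh=v_thresh, min_area=min_area)


def relative_event_activity(
    event: Event,
    activity: SpatiotemporalMap,
    velocity: SpatiotemporalMap,
    v_thresh: float = DEFAULT_V_THRESH,
) -> tuple[float, float]:
    """Event activity normalized to nonmoving-edge activity in the same span.

    Returns ``(score, percent_difference)`` where score = mean activity over
    the event's pixels divided by the mean activity over pixels with
    |v| ≤ v_thresh within the event's time range. Raises if the time span
    contains no nonmoving pixels with valid activity.
    """
    if activity.values.shape != velocity.values.shape:
        raise ValueError("activity and velocity maps must share a shape")
    wi, ti = event.pixels
    ev_vals = activity.values[wi, ti]
    ev_vals = ev_vals[np.isfinite(ev_vals)]
    span = slice(event.t_start, event.t_end + 1)
    v_span = velocity.values[:, span]
    a_span = activity.values[:, span]
    nonmoving = np.isfinite(v_span) & (np.abs(v_span) <= v_thresh)
    ref_vals = a_span[nonmoving]
    ref_vals = ref_vals[np.isfinite(ref_vals)]
    if ev_vals.size == 0 or ref_vals.size == 0 or ref_vals.mean() == 0:
        raise ValueError("relative activity undefined: no nonmoving reference "
                         "pixels (or no valid event pixels) in the event span")
    score = float(ev_vals.mean() / ref_vals.mean())
    return score, (score - 1.0) * 100.0


def annotate_activity(
    events: EventSet,
    activity: SpatiotemporalMap,
    velocity: SpatiotemporalMap,
) -> EventSet:
    """Fill mean and relative activity on every event (in place)."""
    for e in events:
        wi, ti = e.pixels
        vals = activity.values[wi, ti]
        vals = vals[np.isfinite(vals)]
        e.mean_activity = float(vals.mean()) if vals.size else None
        try:
            e.relative_activity = relative_event_activity(
                e, activity, velocity, events.v_thresh
            )[0]
        except ValueError:
            e.relative_activity = None
    return events


def find_transition(
    trace: np.ndarray, min_positive_run: int = 21
) -> int | None:
    """Protrusion→retraction transition frame on an ROI-mean velocity trace.

    x is the first frame with (i) negative acceleration (backward second
    difference v[x] − 2v[x−1] + v[x−2] < 0), (ii) v[x−1] > 0, (iii) v[x] < 0,
    preceded by at least ``min_positive_run`` frames of positive velocity.
    Returns the frame among {x−1, x} with the smaller |v| (ties toward x−1),
    or None.
    """
    v = np.asarray(trace, dtype=float)
    for x in range(2, v.size):
        if not (np.isfinite(v[x - 2]) and np.isfinite(v[x - 1])
                and np.isfinite(v[x])):
            continue
        if not (v[x - 1] > 0 and v[x] < 0):
            continue
        accel = v[x] - 2 * v[x - 1] + v[x - 2]
        if not accel < 0:
            continue
        run = 0
        for k in range(x - 1, -1, -1):
            if np.isfinite(v[k]) and v[k] > 0:
                run += 1
            else:
                break
        if run < min_positive_run:
            continue
        return x - 1 if abs(v[x - 1]) <= abs(v[x]) else x
    return None


@dataclass
class TransitionEvent:
    """One transition with 41-frame aligned traces (anchor at index 20)."""

    window_center: int
    transition_frame: int
    velocity_trace: np.ndarray     # (41,), μm/min, NaN outside the movie
    activity_trace: np.ndarray     # (41,), ratio units
    valid: np.ndarray              # (41,) bool

    @property
    def anchor_index(self) -> int:
        return TRACE_HALF


def _roi_mean(values: np.ndarray, center: int, roi_windows: int) -> np.ndarray:
    half = roi_windows // 2
    rows = (np.arange(center - half, center + half + 1)) % values.shape[0]
    with np.errstate(invalid="ignore"):
        return np.nanmean(values[rows], axis=0)


def roi_velocity_trace(
    velocity: SpatiotemporalMap, center_window: int,
    roi_windows: int = ROI_WINDOWS,
) -> np.ndarray:
    """Mean velocity over a circular ROI of ``roi_windows`` windows."""
    return _roi_mean(velocity.values, center_window, roi_windows)


def align_buildup(
    velocity: SpatiotemporalMap,
    activity: SpatiotemporalMap,
    centers: list[int] | None = None,
    roi_windows: int = ROI_WINDOWS,
    min_positive_run: int = 21,
) -> list[TransitionEvent]:
    """Find transitions and extract aligned ±20-frame buildup traces.

    ROI centers default to the retraction-onset windows of detected events:
    every window is scanned unless ``centers`` is given. For each ROI whose
    mean velocity trace contains a qualifying transition, 41-frame velocity
    and activity traces centered on the transition are extracted (circular
    ROI averaging over windows; frames outside the movie are invalid).
    """
    if velocity.values.shape != activity.values.shape:
        raise ValueError("maps must share a shape")
    if centers is None:
        centers = list(range(velocity.n_windows))
    T = velocity.n_frames
    out: list[TransitionEvent] = []
    seen: set[tuple[int, int]] = set()
    for c in centers:
        vtrace = _roi_mean(velocity.values, c, roi_windows)
        x = find_transition(vtrace, min_positive_run)
        if x is None:
            continue
        key = (c, x)
        if key in seen:
            continue
        seen.add(key)
        atrace_full = _roi_mean(activity.values, c, roi_windows)
        vel41 = np.full(2 * TRACE_HALF + 1, np.nan)
        act41 = np.full(2 * TRACE_HALF + 1, np.nan)
        valid = np.zeros(2 * TRACE_HALF + 1, dtype=bool)
        for i, f in enumerate(range(x - TRACE_HALF, x + TRACE_HALF + 1)):
            if 0 <= f < T:
                vel41[i] = vtrace[f]
                act41[i] = atrace_full[f]
                valid[i] = np.isfinite(vel41[i]) or np.isfinite(act41[i])
        out.append(TransitionEvent(
            window_center=int(c), transition_frame=int(x),
            velocity_trace=vel41, activity_trace=act41, valid=valid,
        ))
    return out


def pool_traces(transitions: list[TransitionEvent]) -> dict[str, np.ndarray]:
    """Pool aligned traces across transitions (NaN-aware mean and count)."""
    if not transitions:
        raise ValueError("no transitions to pool")
    vel = np.vstack([t.velocity_trace for t in transitions])
    act = np.vstack([t.activity_trace for t in transitions])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return {
            "velocity_mean": np.nanmean(vel, axis=0),
            "activity_mean": np.nanmean(act, axis=0),
            "n_velocity": np.isfinite(vel).sum(axis=0),
            "n_activity": np.isfinite(act).sum(axis=0),
            "time_offset_frames": np.arange(-TRACE_HALF, TRACE_HALF + 1),
        }


@dataclass
class ExcitabilityFit:
    """OLS fit of dA/dt (per min) against A over the buildup window."""

    slope_per_min: float
    intercept: float
    r_value: float
    n_pairs: int
    activity: np.ndarray
    rate: np.ndarray


def excitability_fit(
    pooled_activity: np.ndarray,
    frame_interval_s: float,
    anchor_index: int = TRACE_HALF,
    window_frames: tuple[int, int] = (-14, 3),
) -> ExcitabilityFit:
    """Rate-of-change analysis of the pooled activity buildup trace.

    Pairs A_t with (A_{t+1} − A_t)/Δt (Δt in minutes) over frames
    ``anchor + window_frames[0] … anchor + window_frames[1]`` (default 18
    points ≈ −6 min to +1 min at 25 s/frame) and fits an ordinary
    least-squares line. A positive slope is the excitability signature.
    """
    a = np.asarray(pooled_activity, dtype=float)
    dt_min = frame_interval_s / 60.0
    lo = anchor_index + window_frames[0]
    hi = anchor_index + window_frames[1]
    idx = [t for t in range(max(lo, 0), min(hi, a.size - 2) + 1)
           if np.isfinite(a[t]) and np.isfinite(a[t + 1])]
    if len(idx) < 3:
        raise ValueError("excitability fit needs >= 3 valid (A, dA/dt) pairs")
    A = a[idx]
    rate = (a[np.asarray(idx) + 1] - A) / dt_min
    if np.allclose(A, A[0]):
        return ExcitabilityFit(0.0, float(rate.mean()), 0.0, len(idx), A, rate)
    fit = stats.linregress(A, rate)
    return ExcitabilityFit(
        slope_per_min=float(fit.slope),
        intercept=float(fit.intercept),
        r_value=float(fit.rvalue),
        n_pairs=len(idx),
        activity=A,
        rate=rate,
    )
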