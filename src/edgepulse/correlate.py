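"""Per-window cross-correlation of edge velocity and activity; response curves.

Per window, the velocity series is recentered in time (the map stores t → t+1
displacements, so the value at frame x is the mean of the x−1 → x and
x → x+1 columns), both series are z-scored, and the normalized cross-
correlation is computed over symmetric lags with division by the overlap
count at each lag (unbiased, so edge lags are not attenuated). The 180
per-window curves average to one per-cell curve; per-cell curves average to a
per-condition curve with a 95% confidence band. Sign convention: negative lag
means activity follows velocity.

``normalize_response`` implements the two-stage normalization of perturbation
time courses: (i) divide by the series' own pre-addition mean, (ii) divide
pointwise by the mean stage-(i)-normalized control series, so shared drifts
cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .edgemap import SpatiotemporalMap

DEFAULT_MAX_LAG = 24  # frames; 10 min at 25 s/frame


@dataclass
class CorrelationCurve:
    """Cross-correlation vs lag, with provenance level and sample size."""

    lags_frames: np.ndarray
    lags_s: np.ndarray
    r: np.ndarray
    level: str                      # "per-window" | "per-cell" | "per-condition"
    n: int                          # series (windows or cells) averaged
    se: np.ndarray | None = None    # per-condition only

    @property
    def lag_at_min_s(self) -> float:
        return float(self.lags_s[int(np.nanargmin(self.r))])

    @property
    def lag_at_max_s(self) -> float:
        return float(self.lags_s[int(np.nanargmax(self.r))])

    def to_frame(self) -> pd.DataFrame:
        d = {"lag_frames": self.lags_frames, "lag_s": self.lags_s, "r": self.r}
        if self.se is not None:
            d["se"] = self.se
        return pd.DataFrame(d)


def _zscore(x: np.ndarray) -> np.ndarray | None:
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        return None
    return (x - x.mean()) / sd


def _xcorr_unbiased(zv: np.ndarray, za: np.ndarray, max_lag: int) -> np.ndarray:
    """r(l) = Σ_t zv(t)·za(t−l) / (N−|l|) for l in −max_lag…max_lag.

    With za = zv this gives exactly 1 at lag 0. Positive l means the activity
    series shifted later aligns with velocity, i.e. activity *precedes*
    velocity; a negative minimum means activity follows velocity.
    """
    n = zv.size
    out = np.full(2 * max_lag + 1, np.nan)
    for i, lag in enumerate(range(-max_lag, max_lag + 1)):
        if lag >= 0:
            a, b = zv[lag:], za[: n - lag]
        else:
            a, b = zv[: n + lag], za[-lag:]
        if a.size > 0:
            out[i] = float(np.dot(a, b) / a.size)
    return out


def recenter_velocity(values: np.ndarray) -> np.ndarray:
    """Average flanking displacement columns so frame x describes x itself.

    Input column t holds the t → t+1 velocity; output column x (1 ≤ x ≤ T−2)
    is the mean of columns x−1 and x; the first and last columns are NaN.
    """
    out = np.full_like(values, np.nan)
    out[:, 1:-1] = 0.5 * (values[:, :-2] + values[:, 1:-1])
    return out


def crosscorrelate_maps(
    velocity: SpatiotemporalMap,
    activity: SpatiotemporalMap,
    max_lag: int = DEFAULT_MAX_LAG,
) -> CorrelationCurve:
    """Per-cell cross-correlation curve between velocity and activity maps.

    Windows with zero variance or missing data are skipped and excluded from
    the per-cell average.
    """
    if velocity.values.shape != activity.values.shape:
        raise ValueError("maps must share a shape")
    T = velocity.n_frames
    if T < 2 * max_lag + 5:
        raise ValueError(
            f"need >= {2 * max_lag + 5} frames for max_lag={max_lag}"
        )
    v_re = recenter_velocity(velocity.values)
    frames = slice(1, T - 1)  # recentered velocity is defined here
    curves = []
    for w in range(velocity.n_windows):
        v = v_re[w, frames]
        a = activity.values[w, frames]
        ok = np.isfinite(v) & np.isfinite(a)
        if not ok.all():
            # require contiguous complete series for a clean lag structure
            if ok.sum() < 2 * max_lag + 5:
                continue
            # trim to the longest finite prefix/suffix-free span
            idx = np.nonzero(ok)[0]
            v, a = v[idx[0]: idx[-1] + 1], a[idx[0]: idx[-1] + 1]
            if not (np.isfinite(v).all() and np.isfinite(a).all()):
                continue
        zv, za = _zscore(v), _zscore(a)
        if zv is None or za is None:
            continue
        curves.append(_xcorr_unbiased(zv, za, max_lag))
    if not curves:
        raise ValueError("no windows with usable series")
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.nanmean(np.vstack(curves), axis=0)
    return CorrelationCurve(
        lags_frames=lags,
        lags_s=lags * velocity.calibration.frame_interval_s,
        r=r,
        level="per-cell",
        n=len(curves),
    )


def aggregate_condition(curves: list[CorrelationCurve]) -> CorrelationCurve:
    """Pointwise mean of per-cell curves with a 95% confidence band."""
    if not curves:
        raise ValueError("need at least one curve")
    lags = curves[0].lags_frames
    for c in curves[1:]:
        if not np.array_equal(c.lags_frames, lags):
            raise ValueError("curves have mismatched lag grids")
    stack = np.vstack([c.r for c in curves])
    mean = stack.mean(axis=0)
    n = len(curves)
    se = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(
        lags.size, np.nan
    )
    return CorrelationCurve(
        lags_frames=lags,
        lags_s=curves[0].lags_s,
        r=mean,
        level="per-condition",
        n=n,
        se=1.96 * se,
    )


@dataclass
class ResponseCurve:
    """Normalized perturbation-response time course (baseline = 1)."""

    time_min: np.ndarray
    value: np.ndarray
    addition_frame: int
    stages: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_min": self.time_min, "value": self.value})


def normalize_response(
    series: np.ndarray,
    addition_frame: int,
    control_series: list[np.ndarray],
    frame_interval_s: float = 60.0,
) -> ResponseCurve:
    """Two-stage normalization of a mean-activity time course.

    Stage (i): divide the series by its own mean over frames before
    ``addition_frame``. Stage (ii): divide pointwise by the mean of the
    stage-(i)-normalized control series, cancelling shared drifts.
    """
    series = np.asarray(series, dtype=float)
    if addition_frame <= 1:
        raise ValueError("addition frame must be > 1")
    if not control_series:
        raise ValueError("need at least one control series")
    pre = series[:addition_frame].mean()
    if pre == 0 or not np.isfinite(pre):
        raise ValueError("pre-addition mean is zero or undefined")
    stage1 = series / pre
    controls = []
    for c in control_series:
        c = np.asarray(c, dtype=float)
        if c.size != series.size:
            raise ValueError("control series length mismatch")
        cpre = c[:addition_frame].mean()
        if cpre == 0 or not np.isfinite(cpre):
            raise ValueError("control pre-addition mean is zero or undefined")
        controls.append(c / cpre)
    ctrl_mean = np.mean(controls, axis=0)
    value = stage1 / ctrl_mean
    t_min = (np.arange(series.size) - addition_frame) * frame_interval_s / 60.0
    return ResponseCurve(
        time_min=t_min, value=value, addition_frame=addition_frame,
        stages=("own-baseline", "control-mean"),
    )
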