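"""Shared fixtures: expensive end-to-end runs are session-scoped and reused."""

from __future__ import annotations

import numpy as np
import pytest

from edgepulse import edgemap, events, preprocess
from edgepulse.movie import Calibration
from edgepulse.pipeline import RunConfig, run_pipeline
from edgepulse.synthetic import (
    CouplingParams,
    render_timelapse,
    simulate_activity_coupling,
    simulate_boundary_series,
    transition_pair_params,
)


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default synthetic movie (10 planted events)."""
    return run_pipeline(RunConfig(seed=0))


@pytest.fixture(scope="session")
def dense_run():
    """Full pipeline on a densely cycling movie (40 events/h) for lag work."""
    return run_pipeline(RunConfig(seed=0, n_events=40, run_events=False))


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noise-free rendered movie + boundary + fields (bleaching on)."""
    from edgepulse.synthetic import BoundaryParams

    params = BoundaryParams(n_frames=60, seed=3)
    coupling = CouplingParams(noise_sd=0.0)
    boundary = simulate_boundary_series(params)
    fields = simulate_activity_coupling(boundary, coupling)
    rendered = render_timelapse(boundary, fields, coupling)
    return rendered, boundary, fields, coupling


@pytest.fixture(scope="session")
def transition_analysis():
    """Maps + ground truth for a movie of protrusion→retraction pairs."""
    params = transition_pair_params(n_pairs=10, seed=1)
    coupling = CouplingParams()
    boundary = simulate_boundary_series(params)
    fields = simulate_activity_coupling(boundary, coupling)
    rendered = render_timelapse(boundary, fields, coupling)
    model = preprocess.build_background_model(
        {c: [rendered.blank[c]] for c in rendered.movie.channels}
    )
    sub = preprocess.subtract_background(rendered.movie, model)
    ratio = preprocess.compute_ratio(sub, "FRET", "CFP", rendered.masks)
    grid = edgemap.make_grid(rendered.masks, rendered.movie.calibration, (2.0,))
    vel = edgemap.smooth_map(edgemap.edge_velocity_map(grid))
    act = edgemap.smooth_map(edgemap.activity_map(grid, ratio, 2.0))
    return vel, act, boundary.ground_truth


@pytest.fixture()
def calibration():
    return Calibration(um_per_px=0.33, frame_interval_s=25.0)


def circle_mask(shape: tuple[int, int], center, radius_px: float) -> np.ndarray:
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2


def brute_force_events(
    vals: np.ndarray, v_thresh: float, min_area: int
) -> list[tuple[str, frozenset]]:
    """Independent flood-fill event oracle: 8-connectivity, circular rows.

    Returns (kind, frozenset of (window, frame)) for every suprathreshold
    component of size >= min_area, enumerated by BFS.
    """
    n_w, n_t = vals.shape
    out = []
    for kind, sign in (("protrusion", 1.0), ("retraction", -1.0)):
        supra = np.isfinite(vals) & (sign * vals > v_thresh)
        seen = np.zeros_like(supra, dtype=bool)
        for w0 in range(n_w):
            for t0 in range(n_t):
                if not supra[w0, t0] or seen[w0, t0]:
                    continue
                comp = []
                stack = [(w0, t0)]
                seen[w0, t0] = True
                while stack:
                    w, t = stack.pop()
                    comp.append((w, t))
                    for dw in (-1, 0, 1):
                        for dt in (-1, 0, 1):
                            if dw == dt == 0:
                                continue
                            w2 = (w + dw) % n_w  # circular window axis
                            t2 = t + dt
                            if not (0 <= t2 < n_t):
                                continue
                            if supra[w2, t2] and not seen[w2, t2]:
                                seen[w2, t2] = True
                                stack.append((w2, t2))
                if len(comp) >= min_area:
                    out.append((kind, frozenset(comp)))
    return out


def detected_event_pixel_sets(evset) -> list[tuple[str, frozenset]]:
    return [
        (e.kind, frozenset(zip(e.pixels[0].tolist(), e.pixels[1].tolist())))
        for e in evset
    ]


def make_velocity_map(vals: np.ndarray, calibration=None) -> "edgemap.SpatiotemporalMap":
    cal = calibration or Calibration(0.33, 25.0)
    return edgemap.SpatiotemporalMap(
        values=np.asarray(vals, dtype=float), kind="velocity", calibration=cal
    )


def make_activity_map(vals: np.ndarray, calibration=None) -> "edgemap.SpatiotemporalMap":
    cal = calibration or Calibration(0.33, 25.0)
    return edgemap.SpatiotemporalMap(
        values=np.asarray(vals, dtype=float), kind="activity", calibration=cal,
        depth_um=2.0,
    )
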