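"""Protrusion→retraction transitions, aligned buildup traces, rate-of-change.

A movie of slow protrusions each followed by a retraction provides clean
velocity zero crossings. Transitions are detected on 15-window ROI-mean
velocity traces, ±20-frame traces are pooled, and the excitability diagnostic
regresses dA/dt on A: a positive slope on an exponentially rising trace is
the signature of self-amplifying activation.
"""

import numpy as np

from edgepulse import edgemap, events, preprocess
from edgepulse.synthetic import (
    CouplingParams, render_timelapse, simulate_activity_coupling,
    simulate_boundary_series, transition_pair_params,
)

params = transition_pair_params(n_pairs=10, seed=1)
coupling = CouplingParams()
boundary = simulate_boundary_series(params)
fields = simulate_activity_coupling(boundary, coupling)
rendered = render_timelapse(boundary, fields, coupling)

model = preprocess.build_background_model(
    {c: [rendered.blank[c]] for c in rendered.movie.channels})
sub = preprocess.subtract_background(rendered.movie, model)
ratio = preprocess.compute_ratio(sub, "FRET", "CFP", rendered.masks)
grid = edgemap.make_grid(rendered.masks, rendered.movie.calibration, (2.0,))
vel = edgemap.smooth_map(edgemap.edge_velocity_map(grid))
act = edgemap.smooth_map(edgemap.activity_map(grid, ratio, 2.0))

found = events.align_buildup(vel, act)
truth = boundary.ground_truth.true_transition_frames
print(f"{len(found)} ROI transitions detected; "
      f"true zero crossings at frames {sorted({f for _, f in truth})}")
errs = [min(abs(tr.transition_frame - f) for _, f in truth) for tr in found]
print(f"max |detected - true| = {max(errs)} frame(s)")

pooled = events.pool_traces(found)
mid = pooled["velocity_mean"][18:23]
print(f"pooled velocity around the anchor (frames -2..+2): "
      f"{np.round(mid, 2)} um/min  (sign change at the anchor)")

# rate-of-change analysis on a closed-form exponential buildup
k = 0.3  # per min
t = np.arange(41) * 25.0 / 60.0
fit = events.excitability_fit(1.2 * np.exp(k * t), 25.0)
print(f"\nexponential trace (k = {k}/min): fitted dA/dt-vs-A slope = "
      f"{fit.slope_per_min:.4f}/min (discrete closed form "
      f"{(np.exp(k * 25 / 60) - 1) / (25 / 60):.4f}/min), r = {fit.r_value:.3f}")
print("A positive slope means activity accelerates with its own level — "
      "the excitable-system signature.")
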