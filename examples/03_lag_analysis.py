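"""Cross-correlate edge velocity with edge-band activity, per window.

A densely cycling movie (40 events/h, the scale seen in motile endothelial
cells) is analyzed end to end; activity is coupled to retraction speed with a
50-s delay, so the per-cell cross-correlation curve should dip at lag −2
frames (= −50 s at 25 s/frame). Negative lag means activity follows velocity.
"""

import numpy as np

from edgepulse.pipeline import RunConfig, run_pipeline

res = run_pipeline(RunConfig(seed=1, n_events=40, run_events=False))
curve = res.xcorr

print("lag (s)   r")
for lag_s, r in zip(curve.lags_s, curve.r):
    marker = "  <-- min" if r == np.nanmin(curve.r) else ""
    if abs(lag_s) <= 150:
        print(f"{lag_s:+7.0f}  {r:+.3f}{marker}")
i = int(np.nanargmin(curve.r))
print(f"\nminimum r = {curve.r[i]:+.3f} at {curve.lags_s[i]:+.0f} s "
      f"(averaged over {curve.n} windows)")
print("The negative dip at -50 s recovers the generator's coupling delay: "
      "peak activity follows peak (retraction) edge velocity by two frames.")
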