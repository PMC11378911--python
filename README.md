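# edgepulse

Quantitative analysis of cell-edge dynamics and pulsatile GTPase signaling
from ratiometric time-lapse microscopy.

Randomly motile adherent cells (e.g. endothelial cells) cycle through local
protrusions and retractions on a minute scale, and FRET biosensors report the
Rho-family GTPase activity that drives them. `edgepulse` turns two-channel
(FRET/CFP) movies of single cells into the standard quantitative readouts of
this field:

- **Ratiometric preprocessing** — blank-well background subtraction, channel
  registration, noise-filtered per-pixel FRET/CFP ratios, photobleaching
  correction from control cells, percentile clipping for localization ratios.
- **Segmentation & tracking** — histogram-based cell masks, nearest-neighbor
  linking.
- **Edge windowing** — the cell outline is resampled to 900 equal-arc
  boundary points, binned into 180 coordinate windows with depth-resolved
  interior pixel bands; per-window edge velocity v (μm/min, displacement
  projected on the outward normal) and reporter activity form 180 × T
  spatiotemporal maps.
- **Event analysis** — protrusions (v > 3.84 μm/min) and retractions
  (v < −3.84 μm/min) as ≥25-pixel connected regions of the velocity map, with
  per-event speed/duration/span statistics and activity normalized to
  nonmoving edge regions.
- **Transition-aligned buildup** — protrusion→retraction transition detection
  on 15-window ROIs, pooled 41-frame (±20) velocity/activity traces, and the
  excitability diagnostic: the slope of dA/dt versus A during buildup
  (positive slope ⇒ self-amplifying, excitable activation).
- **Cross-correlation** — per-window velocity × activity correlation curves
  averaged per cell and per condition; a negative peak at negative lag means
  activity follows edge retraction.
- **Morphometry** — eccentricity/solidity/area shape records, nucleus-based
  object filtering, perinuclear quantification, hotspot ratios, adhesion-area
  change.
- **Synthetic benchmark** — a generator of deforming-cell movies with exact
  ground truth (event list, coupling lag, bleach constants) used to validate
  every stage end to end.

The analysis model in brief: a 180 × T velocity map V and activity map A are
built from one tracked cell; events are connected components of
{V > θ} / {V < −θ}; the per-window cross-correlation
r(ℓ) = ⟨z(V_w)(t)·z(A_w)(t − ℓ)⟩ is averaged over windows; buildup traces pool
A around velocity zero crossings; and excitability is the OLS slope of
(A_{t+1} − A_t)/Δt on A_t over t ∈ [−6 min, +1 min] around the transition.

## Worked example

```python
from edgepulse.pipeline import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=1), outdir="out")
print(result.event_set.to_frame()[["type", "t_start", "mean_v", "span_pct",
                                   "rel_activity"]].round(3))
```

prints (abridged):

```
      type  t_start  mean_v  span_pct  rel_activity
protrusion        5   5.717     7.778         1.000
retraction       17  -5.625     6.111         1.104
protrusion       33   5.745     7.222         1.000
retraction       45  -5.663     5.556         1.111
...
```

Ten planted events come back as ten detections: protrusions move at
~+5.7 μm/min and retractions at ~−5.7 μm/min across ~6–8% of the perimeter,
and the relative activity column shows the generator's coupling — reporter
activity elevated ~11% in retractions and flat in protrusions, mirroring the
behavior of Rho sensors in motile cells. The cross-correlation curve of the
same run dips below zero at lag −50 s (`result.xcorr.lag_at_min_s`),
recovering the generator's 50-s activity lag: peak activity follows peak edge
velocity by two frames.

The `examples/` directory has one short script per capability (simulation,
event detection, lag analysis, buildup/excitability, bleach correction, shape
metrics); each prints the numbers it computes and one line on what they mean.

A thin CLI wraps the pipeline for shell use:

```bash
edgepulse demo --outdir out --seed 1          # full synthetic round trip
edgepulse simulate --outdir sim --seed 1      # movie + ground truth only
edgepulse run --fret F.tif --cfp C.tif --blank-fret BF.tif \
              --blank-cfp BC.tif --outdir out # user-supplied stacks
```

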