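# Methods

`edgepulse` quantifies pulsatile signaling at the edge of single adherent
cells from two-channel ratiometric (FRET/CFP) time-lapse movies. This note
describes the models and procedures each module implements, the parameters
that matter, the numerical choices, and what the synthetic benchmark does and
does not establish about real data.

## The measurement model

A biosensor movie is a multi-channel stack with physical calibration (default
0.33 μm/px, 25 s/frame). The analysis chain is:

1. **Background**: blank-well stacks are averaged per channel and smoothed
   with a disk-mean filter (radius 5 px). Each data frame has the per-pixel
   *local median* of this background image (disk neighborhood, radius 5 px)
   subtracted, floored at zero. The local-median summarization makes the
   subtraction robust to residual hot pixels in the background model.
2. **Registration**: the FRET channel is aligned to CFP by one global
   subpixel translation, estimated by cross-correlation of the two channels'
   temporal-mean images (`skimage` phase correlation with classic, i.e.
   non-whitened, normalization — spectral whitening is noise-dominated on
   smooth cell images). The inter-channel offset is chromatic/camera in
   origin and therefore static; estimates beyond a cap (default 10 px) fall
   back to the identity with a warning.
3. **Ratio**: both channels are smoothed with the same disk-mean kernel
   (radius 2 px) and divided per pixel inside the per-frame cell mask.
   Pixels whose smoothed denominator falls below a floor are invalid.
4. **Bleaching**: assuming control (untreated) cells have constant true
   ratio, the per-frame mean ratio across control movies, normalized to
   frame 0, is the correction curve c(t). The default is an empirically
   smoothed curve (5-frame moving average, "exponential-like" but not forced
   to be exponential); a single-exponential fit is available and reports the
   decay constant. Correction divides the ratio movie by c(t). For two
   channels bleaching as exp(−t/τ_num) and exp(−t/τ_den), the ratio decays at
   the differential rate 1/τ_num − 1/τ_den, which the exponential fit
   recovers.
5. **Percentile clipping** (localization-ratio reporters such as
   ezrin/volume-marker): ratio values outside the 1st–99th percentile of all
   valid pixels of the whole movie are clipped to those limits. The
   percentile scope is the whole movie, not per frame, so temporal dynamics
   are preserved; percentiles use linear interpolation between order
   statistics.

## Segmentation and tracking

Cell masks come from Otsu's threshold on the log-intensity histogram of the
(background-subtracted) FRET channel, refined by Gaussian smoothing of the
binary mask (σ = 2 px, re-threshold at 0.5), morphological opening with a
1-px disk (removes sub-pixel debris trails), and a minimum object area
(default 500 px). Tracking is nearest-centroid consecutive pairing with a
distance cap (default 50 px/frame), greedy in distance with ties broken
toward the lowest track id; there is no gap closing or mitosis handling.
Downstream edge analysis consumes exactly one track spanning the movie.

## Edge windowing and spatiotemporal maps

The cell edge of each frame is traced as the 0.5-level contour of the
(hole-filled) mask, smoothed with a periodic Gaussian along arc length
(σ = 6 px), and resampled to **900 equal-arc boundary points** starting at a
deterministic origin — the contour point whose angle around the mask centroid
is closest to 0. Without contour smoothing the rasterization staircase
inflates the perimeter by ~4% and corrupts normals by tens of degrees; with
it, a rasterized circle reproduces its analytic perimeter to <0.3% and radial
normals to <1°. Outward unit normals come from central differences over a
±12-point stencil (adjacent resampled points are sub-pixel apart).

Frame-to-frame window correspondence is by normalized arc length anchored at
each frame's centroid-relative origin: window *i* of frame t corresponds to
window *i* of frame t+1. Per raw window, velocity is the dot product of the
displacement between corresponding points with the frame-t outward normal,
scaled to μm/min. The 900 raw values are mean-binned in groups of five into
**180 averaged windows**. Velocity column t describes the t → t+1 motion; the
last column is undefined. This correspondence is deterministic and accurate
for compact cells whose deformations are perturbative relative to cell size;
it degrades when single events rearrange a large fraction of the perimeter
(see Limitations).

Reporter activity is sampled in cumulative depth bands from the edge
(defaults 0.98, 2.0, 3.3, 4.9, 6.5, 8.1 μm): interior pixels within the
band (by Euclidean distance transform) are assigned to the nearest of the
900 boundary points and averaged per binned window. Window depth 2.0 μm is
the default for edge-proximal activity.

Maps are denoised with a NaN-aware 3×3 moving average that is circular along
the window axis (the edge is a ring), truncated-and-renormalized at the time
edges, and imputes isolated missing values.

## Events, transitions, buildup, excitability

**Events** are connected components of the thresholded, smoothed velocity
map: protrusions where v > 3.84 μm/min, retractions where v < −3.84 μm/min
(8-connectivity with circular wrap along the window axis), kept when they
cover ≥ 25 map pixels. Detection runs on the smoothed map so noise does not
fragment events, but per-event mean velocities are measured on the unsmoothed
map: a 3×3 box filter biases the amplitude of compact events low by ~5–8%,
and reading the statistic from the original data avoids that bias. Per-event
records include area, time range, circular window range, span
(distinct windows / 180 × 100), duration, and mean activity. Relative event
activity divides the event's mean activity by the mean over *nonmoving*
pixels (|v| ≤ threshold) within the same time span; it is reported both as a
ratio and as a percent difference.

**Transitions** (protrusion→retraction) are found on the mean velocity trace
of a 15-window circular ROI (8.33% of the perimeter): the anchor candidate x
is the first frame with negative acceleration (backward second difference
< 0), v[x−1] > 0 and v[x] < 0; of x−1 and x the frame with smaller |v| is the
transition point, ties toward the earlier frame. Only transitions preceded by
more than 20 frames of positive ROI-mean velocity qualify. For each
transition a 41-frame (±20) velocity and activity trace is extracted; frames
outside the movie are invalid and excluded from pooled means. ROI placement
is automated by scanning all 180 window centers (the original analysis placed
ROIs manually on velocity maps); duplicate (center, frame) detections are
dropped, and neighboring centers detecting the same physical event pool as
replicates.

**Excitability** is diagnosed on the pooled activity trace by regressing the
forward-difference rate (A_{t+1} − A_t)/Δt on A_t over the buildup window,
frames −14 … +3 relative to the anchor (18 points ≈ −6 min to +1 min at
25 s/frame; configurable). On A(t) = A₀e^{kt} sampled at Δt the regression is
exactly linear with slope (e^{kΔt} − 1)/Δt (≈ k + k²Δt/2 forward-difference
bias, ~6.5% at k = 0.3/min); on a linear trace the slope is 0 and the
intercept is the constant rate. A positive slope — activity accelerating with
its own level — is the excitable-system signature.

## Cross-correlation and response normalization

Per window, the velocity series is recentered in time (the value at frame x
is the mean of the x−1→x and x→x+1 columns, removing the half-frame offset
inherent to displacement measurements), both series are z-scored, and the
normalized cross-correlation is computed over lags ±24 frames (±10 min) with
division by the overlap count at each lag (the unbiased normalization, so
edge lags are not attenuated; the curve equals 1 at lag 0 for a series with
itself). Windows with zero variance or missing data are skipped. The
per-window curves average to one per-cell curve; per-cell curves average to a
per-condition curve with a 95% band (mean ± 1.96·SE). Sign convention:
negative lag means activity follows velocity.

Perturbation responses (per-field-of-view mean activity over time) are
normalized in two stages: (i) by the series' own pre-addition mean, then
(ii) pointwise by the mean of stage-(i)-normalized control series, so any
drift shared with controls cancels exactly.

## Morphometry

Shape metrics use the standard second-central-moment definitions
(`skimage.measure.regionprops`): eccentricity = interfocal distance / major
axis of the moment ellipse; solidity = area / convex-hull area; axes,
perimeter and area are reported in calibrated units. Object filtering keeps
cells with area > 3000 px containing exactly one nucleus. Nuclei are detected
by Gaussian smoothing + Otsu + watershed on the distance transform.
Perinuclear quantification dilates each nucleus by a 7-px disk and reports
the mean marker intensity per cell, assigning contested pixels to the nearest
nucleus. Hotspot analysis thresholds a marker at 8× over background (median
intensity outside the cell mask) and reports in-hotspot ratio and marker
means normalized to the whole-cell means. Adhesion-area change is
100·(A₁ − A₀)/A₀.

## The synthetic generator

The generator is first-class, tested code; it defines the conditions under
which every end-to-end property is verified.

**Boundary.** The cell is star-shaped around a fixed center:
r(θ, t) = R₀ + Σᵢ Aᵢ·exp(−Δθᵢ²/2σᵢ²)·S((t − tᵢ)/Dᵢ), with S the integrated
raised cosine (S(u) = u − sin(2πu)/2π on [0, 1]). Each event is a Gaussian
bump in angle whose radial displacement rises monotonically with a
raised-cosine *velocity* pulse, so one planted bump is exactly one signed
edge-motion event with closed-form normal velocity and peak speed 120·|A|/D
μm/min. An out-and-back radial bump was rejected because each such bump would
count as both a protrusion and a retraction, breaking one-to-one ground-truth
accounting. Events may travel (``wave_speed``) to emulate propagating waves.

**Defaults** (the benchmark conditions): R₀ = 60 μm, 10 events per 62.5-min
movie alternating protrusion/retraction, |A| = 13.5 μm, D = 200 s, σ = 0.19
rad. These give suprathreshold event mean speeds ≈ ±5.7 μm/min (matching the
~6 μm/min scale of endothelial protrusion/retraction events), spans ≈ 7% of
the perimeter, and ≈ 40 suprathreshold map pixels per event. The large base
radius keeps the ±13.5 μm displacements perturbative: on a much smaller cell
the equal-arc windows compress inside retraction valleys and events shrink
below the 25-px rule. For cross-correlation studies the dense-cycling
condition (40 events/h, the per-hour event count reported for these cells) is
used; it gives the same lag recovery with a deeper negative peak. The
transition benchmark plants slow protrusions (600 s, satisfying the >20-frame
positive-velocity eligibility) each followed by a retraction at the same
angle, and records the true zero crossing of the continuous center velocity
on a fine time grid.

**Coupling.** a(θ, t) = baseline + gain·max(0, −v(θ, t − lag)) with defaults
gain 0.05 per (μm/min), lag 50 s, baseline 1.0 — activity rises where and
when the edge retracts, lagging by two frames. The NM2-like field is the same
quantity delayed by a further 150 s and low-pass filtered (3-frame moving
average), painted in a deeper band (5–8 μm). The coupling is phenomenological:
it reproduces the *statistical* structure (anticorrelation at a lag, delayed
deep-band signal) without any reaction–diffusion mechanism, and it cannot
produce pre-retraction activity buildup — which is why the excitability
benchmark uses closed-form exponential traces rather than the movie path.

**Rendering.** CFP = uniform density (1000 intensity units) inside the mask;
FRET = CFP × activity (activity painted within 2 μm of the edge, baseline
deeper), so true per-pixel FRET/CFP equals the activity field. Channels decay
as exp(−t/τ) (defaults τ_FRET = 3000 s, τ_CFP = 6000 s), gain a constant
background (100) and additive Gaussian noise (σ = 10 ≈ 1% of signal; a
deliberate simplification of Poisson shot noise, sufficient to stress the
smoothing filters). Masks are rasterized by the exact star-shape inside test
ρ ≤ r(θ) with r interpolated on the dense angular grid — equivalent to
point-in-polygon for this boundary family and reproducible to the bit under a
fixed seed. Blank background stacks (background + noise) accompany every
movie.

**What the benchmark does not show.** Real cells have nonuniform reporter
density, Poisson noise, focal drift, blebs, neighbors and mitosis; boundaries
are not star-shaped and events are not angularly Gaussian. Passing the
synthetic suite demonstrates that the *computations* are correct under known
ground truth, not that segmentation or windowing is robust to every real-data
pathology.

## Numerical choices and degenerate inputs

- Velocity column convention: column t = t → t+1 motion; the recentering step
  in cross-correlation removes the half-frame offset.
- Thresholds: 3.84 μm/min event threshold (a 3.86 variant appears in some
  figure legends of the motivating literature; the value is configurable),
  25-px minimum event area (kept if area ≥ 25), 15-window ROI, ±20-frame
  traces, >20-frame eligibility, 1/99 percentile clipping, 7-px nuclear
  dilation, 3000-px object filter, 8× background hotspot threshold.
- Depth 2.0 μm and the 1.95 μm quoted in some figure contexts refer to the
  same 6-px band at 0.33 μm/px; depths are realized in pixels and reported
  in μm.
- Ties: transition |v| ties break toward the earlier frame; tracking
  distance ties break toward the lowest track id; event labels are sorted by
  (t_start, w_start, kind).
- Degenerate inputs raise: empty blank lists, masks touching the image
  border, multi-component masks (holes are filled, split cells are not),
  bleach curves on < 5 frames, percentile clipping on < 100 pixels,
  correlation on movies shorter than 2·max_lag + 5 frames, zero pre-addition
  means.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical configuration + seed reproduces every
  output byte-for-byte.

## Problem sizes

The shipped benchmarks run one 150-frame, ~470²-px movie for event recovery,
one for lag recovery, two 40-frame movies for transitions, and one 60-frame
noise-free control for bleaching — each a single cell, chosen so the full
suite and the reproduction script finish in minutes on one CPU while keeping
every quantity at the calibration of the motivating experiments.

## Known limitations

- One cell per analysis; no gap closing, mitosis, or blebbing
  classification.
- Arc-length window correspondence accumulates drift between the window grid
  and material points when deformations are large relative to cell size;
  velocities remain correct locally but window indices of distant features
  shift by a few windows over an hour of large events.
- The cross-correlation magnitude on sparse-event movies is small (most
  windows are quiet most of the time); the lag location is robust, the depth
  of the dip scales with event density.
- The excitability fit assumes the pooled buildup trace is well sampled over
  the fitting window; it refuses (< 3 pairs) rather than extrapolate.
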