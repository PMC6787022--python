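# Methods

This note documents the models, rules and numerical choices the package
implements, what the synthetic generator does and does not emulate, and the
known limitations.

## Observation model and unit conventions

A recording is a stack of 1024×1024 grayscale frames (configurable) from a
camera with a 13 µm sensor pixel pitch, captured at 4–8 Hz under 20X–64X
magnification. Conversions are exact and fixed:
`time (s) = frames × 1/frequency`, `distance (µm) = pixels ×
(13 µm / magnification)`; e.g. 1000 frames at 8 Hz span 125 s and one pixel
at 20X spans 0.65 µm. Pixel coordinates are 0-based with x = column,
y = row, origin top-left; centroids are fractional.

## Detection and linking

Background: per-pixel temporal median over the whole stack; scale: per-pixel
1.4826 × temporal MAD (robust to the moving minority of dark pixels). A
pixel is foreground in a frame when its residual exceeds `k_sigma` (default
5) times the scale, strictly — an all-constant stack yields no detections.
One repair step is applied to the background model: a pixel whose temporal
median deviates from the frame-wide background level by more than the same
threshold takes the global level instead. Without this, a cell that never
moves is its own background and silently vanishes; with it, stationary and
moving cells are treated alike. Foreground pixels are grouped by
8-connectivity; components below `min_blob_pixels` (default 2, matching
cells that occupy at least 2–3 pixels) are noise; the centroid is the
arithmetic mean of member pixel coordinates.

Linking is greedy nearest-neighbour: per frame, (open track, detection)
pairs within `search_radius` are assigned in order of increasing distance
(ties: lower detection index, then lower track index), so assignment is
invariant to detection ordering up to the documented tie-break. Leftover
detections farther than `new_path_radius` (default: the search radius) from
every open track end start new tracks; nearer leftovers are treated as
spurious. Tracks missing more than `max_missed` (default 2) consecutive
frames are closed. A global-likelihood linker would resolve crossing
trajectories better; within a close encounter this linker guarantees track
count, not identity. The search radius is data-dependent — a sensible
default is (max plausible speed × frame interval) / pixel size.

Filtering keeps trajectories with ≥ 10 samples and, by default, at least one
frame displacement exceeding the species' body length (completely idle cells
carry no motility information). Body-length defaults: 2 µm for small
twitching cells, 3 µm for larger swimmers, both config-overridable.

## Step segmentation

In physical units, a frame displacement below the body length marks a
waiting state; consecutive waiting frames accumulate. A run opens with the
first at-or-above-body-length displacement and extends while each new
displacement direction deviates ≤ 5° (configurable) from the run's **net**
direction so far — the running-mean baseline, not frame-to-frame, so slow
curvature eventually terminates a run, consistent with reading the rule as
~1 px lateral drift per 10 px of travel. A run closes on a waiting frame or
a sharper turn, emitting one step record: net displacement (dx, dy, ε),
run duration, and the wait that preceded the run. We store
`τ = τ_wait + τ_run` and both components, so τ is the full time cost of a
step and the τ's of a trajectory sum to its covered duration — the property
the CTRW clock recursion needs. Trailing wait with no subsequent run becomes
a terminal pure-wait record (ε = 0), excluded from jump statistics.
Segmentation is exactly translation- and rotation-invariant.

## Ensemble statistics

All trajectories are translated to start at the origin. On a common regular
time grid (the finest native frame interval), `mean_disp` is the mean of
|r(t)| over trajectories still recorded and `variance` the mean squared
distance from the ensemble-mean position — i.e. radial, the sum of the two
per-axis variances. Whether the observable should be |mean vector| instead
of mean |vector|, or per-axis rather than radial variance, is ambiguous in
general; both alternatives are trivially computable from the same arrays,
and the chosen pair is what the drift and diffusion estimators consume.
Moments are truncated at the last time with at least 50 unique live
trajectories (default), since the ensemble thins as cells leave the window.
Drift speed V is the free-intercept OLS slope of mean displacement vs time.
Note this conflates advection with diffusive growth of |r|: on drift-free
data it still returns a positive slope, which is a property of the estimator
itself, not a bug in its implementation.

Empirical PDFs are histogram densities (area exactly 1); default binning is
logarithmic, 30 bins per decade, matching the decades-spanning supports.
Lag-1 correlations pair consecutive steps within the same cell only;
terminal ε = 0 records are excluded from jump pairs; fewer than 10 pairs
flags the estimate sparse.

## CTRW models

The Monte-Carlo walk starts every particle at the origin and repeats
`r += (dx, dy)`, `t += τ` until t exceeds the horizon (each particle takes
at least one step; the crossing step is kept). *Coupled*: one master-table
row per step, drawn uniformly with replacement — the empirical joint (ε, τ)
distribution, realised without any parametric copula. *Uncoupled*:
displacement and waiting time from two independently drawn rows. Recorded
(dx, dy) are used as-is by default, preserving any anisotropy; an option
resamples an isotropic direction of the same length. No drift is added to
the CTRW — drift enters only the ADE.

First passage at a control radius L interpolates within steps: a particle
rests through the wait component, then traverses the jump chord at constant
speed over the run component. Because |r| along a straight chord is maximal
at an endpoint, the first event state with |r| ≥ L brackets the true
crossing, found by solving the chord-circle quadratic. With ~100 µm jumps,
instantaneous jumps would let a single event cross every L < 100 µm at its
start time and badly distort early breakthrough — hence finite-speed chords.
Particles not reaching L within the horizon are censored.

Real-path breakthroughs use the identical code path: recorded trajectories
are encoded as histories whose steps are the sample-to-sample segments
(zero wait component — dwell is already embedded in the positions), making
model and observation bit-comparable.

## ADE model

`D(t) = ½ dσ²/dt` by second-order finite differences (optionally after a
centred moving-average smoothing of σ²); negative estimates are floored at
zero and counted; beyond the last observed time D holds its final value.
Because the variance is radial (2-D), this D is twice the per-axis
coefficient — for an isotropic Brownian ensemble with per-axis D₀ the
estimator returns 2·D₀, consistent with how it is consumed. The
breakthrough is the semi-infinite 1-D solution
`C/C0 = ½ erfc((L − V t)/(2√(D t)))` evaluated pointwise with D = D(t),
applied radially with L the control radius. Two approximations are
deliberate and preserved: the 1-D form is used for a radial geometry, and it
is a resident-concentration (fraction beyond L), not a strict first-passage,
solution — a property test verifies exactly that against a simulated
drift-diffusion walk. The first-arrival density is the numerical time
derivative of C/C0, floored at zero (a time-varying D can make it locally
negative) and rescaled so its integral equals the final C/C0; model moments
are density-weighted over the evaluation horizon, which therefore matters
and defaults to 1000 s — well beyond a typical 250 s observation window,
since slow models keep arriving long after recording stops.

## Curve conventions

Breakthrough densities are normalised by the total ensemble size C0, so the
curve's area equals its recovery. Arrival moments are over arrivers only,
population (divide-by-n) convention — censoring means recoveries far below 1
must still yield finite moments. Curves recovering < 2% are flagged
unreliable and dropped from comparison plots.

## Synthetic generator

Each cell alternates waits (position fixed) with straight runs traversed at
constant `run_speed`; positions are sampled on a regular grid (default
0.25 s, i.e. 4 Hz). Defaults emulate the observed statistics: lognormal
jumps with mode 5.5 µm, σ = 0.8 and a hard 100 µm maximum; truncated-Pareto
waits (exponent 1.2, scale 0.25 s, support to 250 s); body length 3 µm;
run speed 12 µm/s so typical runs span several frames; 100 cells × 125 s.
Optional slow drift (µm/s, e.g. the 0.15–0.22 µm/s creep seen in sealed
chambers) is added to sampled positions only, never to the ground-truth step
table. Rendering draws each in-frame cell as a filled disk (≥ 2 px) of
`cell_level` intensity on a `background_level` canvas, converted by the
inverse unit equations, plus i.i.d. Gaussian sensor noise; cells outside the
window are absent, edge-straddling disks are clipped and counted.

Correlated steps use a lag-1 Gaussian copula: an AR(1) latent normal chain
pushed through the marginal inverse CDF. The latent coefficient is
**calibrated** (Gauss–Hermite quadrature + root finding) so the requested
number *is* the Pearson lag-1 correlation of the output — for skewed
marginals the raw copula ρ can miss the Pearson value by > 0.05, and very
heavy-tailed marginals admit only weak anticorrelation (the sampler refuses
unreachable targets rather than silently under-delivering). The injected
wait correlation lives on the waiting-state component; the total step time
additionally carries the run duration, which rides on the jump length.

Two opt-in switches make generated steps *exactly* recoverable by the
segmentation rules, used by the validation experiments: `frame_aligned`
quantises event durations to the sampling grid (otherwise event boundaries
fall between frames and the boundary frames are ambiguous at any sample
size), and `min_turn_deg` redraws run directions within 6° of the previous
run (a < 5° turn is invisible to the ±5° rule, so ~3% of consecutive runs
would merge). Neither changes the jump/wait marginals materially; both
default off.

What the generator does **not** emulate: hydrodynamic or near-surface
effects, chemotaxis, cell shape/orientation, out-of-focus blur, obstacle
geometries, or speed variation within a run. Passing round-trip tests
therefore validates the pipeline's bookkeeping and estimators under the
model's own assumptions — not the biological fidelity of any particular
recording.

## Validation experiment sizes

The self-contained experiments (`motile_ctrw.experiments`, also driven by
`scripts/acceptance.py`) use: a 20-cell 1024×1024×200-frame noiseless render
for tracking recovery (count must match exactly, RMSE < 1 px); ~200–300
cells × 125 s (≥ 10⁴ steps) for distribution/correlation recovery;
2000 CTRW particles vs ~300 independent real trajectories for the
self-consistency loop. Statistical checks at the 5% level use Monte-Carlo
ensembles large enough that their own standard error sits near 2–3%.

## Known limitations

- Greedy linking can swap identities when cells pass within the search
  radius; only counts are guaranteed there.
- Segmentation at finite frame rate biases small jumps (partial boundary
  frames are classified as waits) and induces small spurious lag-1
  correlations; these artifacts are visible in the README example and are
  shared with any frame-based segmentation of continuous motion.
- The drift estimator inherits the |r|-slope definition and so reports a
  positive "drift" on purely diffusive ensembles.
- The ADE and CTRW comparisons inherit the censoring asymmetry discussed in
  the README: model horizons are free, observations are not.
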