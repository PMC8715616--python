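# Methods

## The optical tracer signal

The measurement chain converts a video of a dye-tracer experiment into a
scalar trace and applies a stability criterion to it.

**Frame sampling.**  Frames are taken at ticks t = 0, 1/r, 2/r, … for a
requested sampling rate r (default 1 Hz, against typical 30 fps source
material); for each tick the temporally nearest decoded frame is selected
and the tick time is recorded.  Tick-based selection rather than
"every k-th frame" keeps non-integer fps/r ratios well defined; the two
coincide at integer ratios.  Timestamps are re-based to zero at the first
sampled frame.

**Segmentation.**  The heterogeneity statistic must run over reactor pixels
only — background pixels are constant and would dilute the SD by an
uncontrolled amount that depends on how much background the crop retains.
The default method marks every pixel whose RGB Euclidean distance from a
pre-tracer reference frame exceeds a threshold in at least one frame: the
dye only ever appears inside the reactor, so the union of changed pixels
outlines it.  The raw mask is reduced to its largest 4-connected component
and its holes are filled; no erosion or dilation is applied, so the pixel
count is stable and auditable.  One mask is computed per video and reused
for every frame — per-frame masks would inject SD jitter through mask-size
changes.  A luminance-threshold method (reactor darker than a white
backdrop) and explicit mask images are provided for scenes where no clean
reference frame exists.

The default distance threshold is 30 (of 255·√3 ≈ 442 full scale), suitable
for strongly dyed reactors.  The threshold must sit below the typical
distance of the *dispersed* state, which for weak dilutions can be small:
with the synthetic generator's colors the fully mixed state sits ≈ 24 from
the reference, so pipeline runs on synthetic videos use threshold 10
(≈ 4% of the clear-to-dye color distance, comfortably above the noise).

**Greyscale.**  Color is collapsed to the HSV "value" pseudochannel,
V = max(R, G, B), per pixel.  Max-channel is symmetric in the channels and
cheap, but compresses contrast when dye and liquid share a bright channel
(a blue dye on a white background leaves B high in both); a Rec. 709 luma
mode (0.2126 R + 0.7152 G + 0.0722 B, rounded) is selectable for such
scenes.  Value remains the default.

**Heterogeneity.**  Per frame, the signal is the *population* standard
deviation (÷N) of the masked value-channel intensities.  With thousands of
mask pixels the ÷N vs ÷(N−1) distinction is far below quantization; the
population form matches image-histogram conventions and is stated so
results are bit-reproducible.  Accumulation is double precision on
mean-shifted values (two-pass); tests hold it to 1e-9 relative against an
independent pure-Python oracle.  No illumination-drift correction is
applied between frames — drift enters the trace and is visible rather than
silently removed.

## The mixing-time criterion

Given a trace (optical SD or pH) and the tracer-addition time t_add, the
final stable value F is the mean of the last n_last = 15 samples, and the
mixing time is the duration from t_add until the signal reaches the band
F ± tol·|F| with tol = 0.05.  Two deliberate generalizations:

* **criterion** — `stay` (default) takes the earliest sample after which
  the signal never leaves the band; `first_cross` takes the first in-band
  sample.  "Stability" on an oscillating signal means sustained residence,
  and first-cross would under-report there; on monotone traces the two
  coincide (a tested invariant).
* **band_mode** — `relative_final` is the band above; for a signal that
  decays to (near) zero it degenerates, so `relative_range` sets the band
  to F ± tol·(max − F) with the maximum taken after t_add.  The degenerate
  case raises an explanatory error instead of switching silently; the video
  pipeline defaults to `relative_range`, the pH pipeline to
  `relative_final`.

Times are reported on the trace's sampling grid (no sub-sample
interpolation), so a continuous band crossing maps to the first sample at
or after it — the quantization error is below one sampling interval.
t_mix is non-increasing in tolerance and `first_cross` ≤ `stay` wherever
both converge; both are enforced by brute-force property tests.

Tracer addition is normally logged by the experimenter and passed
explicitly.  When it is not, a detector takes baseline mean μ₀ and SD σ₀
over the first 10 samples and reports the first sample beginning a run of
3 consecutive samples with |v − μ₀| > 5·max(σ₀, 1e-6).  These defaults are
plumbing, not a claim about probe physics; an explicit time always wins.

## The synthetic generator

The generator emulates exactly the features the method depends on, with
closed-form behavior for testing:

* a vertical column region on a constant white background (the background
  never changes, so reference-diff segmentation is exact by construction);
* a dye pulse at a known time t_add occupying the top 10% of column rows
  at concentration c = 1;
* row-wise first-order relaxation toward the conserved column mean c̄:
  c(y,t) = c̄ + (c(y,t_add) − c̄)·exp(−r(y)·(t−t_add)/τ), with r(y)
  interpolating from 1 at the top to `gradient` ∈ (0,1] at the bottom —
  `gradient < 1` reproduces bottom-last mixing and its prolonged tail;
* linear color mapping clear→dye, seeded Gaussian pixel noise inside the
  column (default 0; 8-bit units), rounding to uint8.

Defaults: 120×320 px frames, column 40×288, τ = 8 s, gradient 1,
t_add = 5 s, 60 s at 1 fps, clear (235,235,235) → dye (70,70,200).  The dye
color is patent-blue-like so the value transform retains contrast
(V = 235 − 35c, linear in concentration); it is a fixture choice, not a
claim about a real dye spectrum.  The intensity head-room (235, not 255)
keeps additive noise un-clipped.

What it does *not* emulate: bubbles, refraction, specular highlights,
camera response, illumination drift, or 3-D flow.  Passing the recovery
tests therefore demonstrates that the measurement chain is faithful to the
image-formation model, not that the model is a CFD-grade account of a real
column.

**Ground truth.**  Because the field is laterally uniform, the per-frame
value-channel SD is computable from the row concentrations alone.  The
oracle evaluates the *expected measured* trace: for a noiseless rendering
it reproduces the uint8 rounding of the row intensities exactly — on a
two-level field quantization staircases the SD and genuinely shifts the
band crossing, so an idealized continuous-intensity closed form
(`quantize=False`, t_mix = τ·ln(1/tol) rounded up for gradient 1 under the
range band) is offered separately but is not what a rendered video
produces.  With noise, rounding acts as dither and the noise and
quantization variances (σ² + 1/12) add in quadrature to the spatial signal
variance; the band is anchored at the last-15 mean of this expected trace,
exactly as the analysis anchors it at the measured one.  The oracle scans
its band crossing with an independent brute-force loop, not the analysis
code.  End-to-end, the pipeline recovers the oracle within ±2 sampling
intervals in ≥ 95% of runs over τ ∈ {4, 8, 16} s × noise SD {0, 2} × 20
seeds (in practice: 100%, mostly exact for noiseless runs and within one
interval for noisy ones).

The pH generator is a first-order step response
pH(t) = pH∞ + (pH₀ − pH∞)·exp(−(t−t_add)/τ) sampled every 3 s with seeded
Gaussian readout noise; its band crossing has the closed form
τ·ln((pH∞−pH₀)/(tol·pH∞)) rounded up to the grid.

## Method comparison

Paired mixing times (reference on x, optical on y — slope and intercept
depend on this orientation) are summarized by the Pearson correlation and
an OLS line; R² = ρ² for simple regression is asserted to 1e-12 as an
internal consistency check.  No p-values: the intended use is a handful of
operating conditions, where inference on ρ is not meaningful.  The optical
method systematically reads higher than a probe placed near the injection
point, because the image integrates the whole vessel — including late-mixing
zones such as the column bottom — while the probe sees only its own
location; the comparison table therefore reports per-condition differences
(optical − reference) alongside the correlation.

## Problem sizes and tolerances

Validation suites run on 120×320 px frames (11 520-pixel column masks) at
1 fps for 45–95 s of simulated time, durations scaled as
t_add + 4τ + 25 so the trace holds a ≥ 15-sample settled tail beyond the
slowest crossing.  SD oracle agreement: 1e-9 relative; regression identity:
1e-12 absolute; recovery: ±2 sampling intervals at ≥ 95% of seeds;
noiseless model-vs-pipeline trace agreement: exact to float rounding
(< 0.5 intensity units asserted).  Determinism is part of the contract:
a fixed generator seed yields bit-identical frames, traces and result
files.

## Known limitations

* The ±5%-of-final band is ill-posed for signals with a zero plateau; the
  range-relative band is a documented deviation from the literal recipe,
  chosen over silent failure.
* Max-channel greyscale loses contrast for bright dyes on bright
  backgrounds; choose `luma` there.
* A single static mask assumes a rigid vessel; flexible-bag reactors that
  bulge during aeration would need per-frame registration, which is out of
  scope.
* No illumination-drift correction: a lighting change during the
  experiment inflates the SD floor and can defeat the stay criterion.
* MOV/MP4 decoding requires an imageio video plugin at run time; frame
  directories, TIFF stacks and GIF are always supported.
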