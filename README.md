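# mixclock

Optical mixing-time determination for transparent bioreactors from
dye-tracer videos.

Mixing time — the time a reactor needs to homogenize a tracer pulse to a
prescribed uniformity — is a basic hydrodynamic characteristic of any
bioreactor, and the classical ways to measure it (conductivity or pH probes)
give a single-point reading that can miss poorly mixed regions.  For
transparent vessels such as bubble-column photobioreactors there is a simple
optical alternative: film the vessel while a dye pulse disperses, and watch
the spatial non-uniformity of the image decay.  `mixclock` implements that
method as a tested library and CLI, aimed at bioprocess engineers and
students characterizing bench-scale photobioreactors with nothing more than
a camera.

## Method

For each sampled frame, pixels are cropped to the reactor, the reactor
region is segmented from the background, and color is collapsed to the HSV
*value* pseudochannel, V = max(R, G, B).  The tracer signal is the
pixel-to-pixel heterogeneity

> s(t) = √( (1/N) Σᵢ (Vᵢ(t) − V̄(t))² )

the population standard deviation over the N reactor pixels of frame t.
While the dye is partly distributed, s(t) is large; before addition and
after complete mixing it is minimal.  The mixing time t₉₅ is the time from
tracer addition until the signal reaches — and by default stays within —
±5% of its *final stable value* F, defined as the mean of the last 15
samples.  The same criterion applied to a pH-probe log (NaOH pulse tracer,
3 s readings) gives the classical reference measurement, and a comparison
module computes the Pearson ρ and OLS line between the two methods across
operating conditions.

Because the optical signal decays toward zero, a ±5%·F band can collapse;
for SD traces the band is therefore taken as F ± 5% of the signal range by
default in the video pipeline (`band_mode="relative_range"`), while pH
analysis keeps the literal F ± 5%·F band.

A synthetic video generator with analytically known mixing behavior (a
row-wise first-order relaxation of a dye pulse in a vertical column,
optionally mixing the column bottom last) provides ground truth for
end-to-end validation: the full pipeline recovers the analytic mixing time
to within ±2 sampling intervals across relaxation constants and noise
levels.

## Worked example

Generate a 60 s synthetic bubble-column video (relaxation constant
τ = 8 s, dye added at t = 5 s, pixel noise SD 1) and run the full optical
pipeline on it:

```
$ mixclock --quiet simulate --out frames --truth truth.csv \
      --tau 8 --duration 60 --noise-sd 1.0 --seed 42
{"t_mix_s": 19.0, "t_add_s": 5.0}

$ mixclock --quiet run-video --frames frames --out run --threshold 10 \
      --t-add 5 --no-plot
{"t_add_s": 5.0, "t_mix_s": 18.0, "final_value": 1.0427387588125594,
 "band_low": 0.5545177360619544, "band_high": 1.5309597815631644,
 "tolerance": 0.05, "n_last": 15, "criterion": "stay",
 "band_mode": "relative_range", "converged": true}
```

The generator reports the analytic mixing time of this video (19 s); the
measurement pipeline — segmentation by reference-frame difference, value
channel, pixel SD per frame, ±5%-of-range stability band — recovers 18 s,
one sampling interval away.  The signal plateaus at a final SD of ≈ 1.04
(the pixel-noise floor), and the band `[0.55, 1.53]` is F ± 5% of the
signal range.  `run/` holds every intermediate: the sampled frames, the
reactor mask, the SD trace CSV, the result CSV and a provenance record.

For a pH reference log: `mixclock run-ph --ph-csv probe.csv --out ph_run`.
Paired results from both methods can be correlated with
`mixclock compare --pairs pairs.csv`.

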