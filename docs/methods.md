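# Methods

## Fixation detection (I-DT)

Fixations are identified with the dispersion-threshold algorithm: a window
of consecutive samples is admissible when its dispersion,
`(max x − min x) + (max y − min y)`, stays at or below a pixel threshold.
The detector seeds a window with the samples spanning the minimum duration;
if admissible, the window is greedily extended rightward until the next
sample would break the threshold, the fixation is emitted (centroid = mean
of member samples, duration = t_end − t_start), and scanning restarts after
it; otherwise the window slides by one sample. This greedy left-to-right
rule is verified in the tests against an exhaustive maximal-window
enumeration on streams of up to 200 samples.

Parameters: minimum duration 100 ms and threshold 1° of visual angle, the
conventional I-DT operating point for 100 Hz trackers. The angle is
converted with the chord formula `2·d·tan(θ/2)·pixels_per_cm` (d = 60 cm,
37.8 px/cm for a 96-dpi-class display → 39.6 px); the pixel pitch has no
single canonical value, so it is explicit in the config and the resolved
pixel threshold is logged. Samples flagged invalid or off-screen are
dropped, not clamped, and break detection windows — interpolating across
tracking loss would fabricate fixations. A trial losing more than 20% of
its samples, or yielding no fixation, is excluded (and counted) rather than
scored.

## Heatmap and entropy

Each fixation contributes an isotropic Gaussian kernel (σ = 30 px ≈ 0.5°
of visual angle, the effective resolution of a wearable tracker) evaluated
at pixel centres of the 1280×1024 grid. Kernels are truncated at 5σ —
beyond which the truncation changes the entropy by under 1e−5 bits, an
order of magnitude inside the 1e−4 agreement the tests demand against
untruncated summation — and renormalised over their on-screen support, so
edge-adjacent fixations lose no mass. Fixation weights `d_f` are
duration-proportional and sum to one; the summed mixture is renormalised
once more before the entropy step, which requires a probability
distribution. Entropy uses `0·log 0 := 0` and a 1e−300 floor; the result is
reported in **bits** (base 2). Base 2 is the only base consistent with
per-type mean entropies around 16–16.5 on this grid, since the natural-log
maximum for 1280×1024 cells is ln(1.31e6) ≈ 14.09 while the base-2 maximum
is 20.32.

Heatmaps are built from detected fixations (not raw samples): the mixture
is indexed by fixations, and duration weighting is what makes the heatmap
reflect both the frequency and the persistence of attention. The grid is
kept at full display resolution; downsampling would shift entropies by the
log of the area ratio.

## Statistics

Pearson correlation (two-tailed p from the t transform with n−2 df) and
simple OLS regression of response time on entropy, overall and per task
type; `R²` equals `r²` for every simple fit and is asserted as an internal
consistency check. Descriptives use the n−1 SD. Difficulty ratings are
compared with a classical one-way ANOVA. Gender comparisons use Welch's
unequal-variance t-test — no test was mandated by the design, and Welch is
the safer default — applied to trial-level pools within each type rather
than participant means. p-values are uncorrected, mirroring per-analysis
reporting; α = 0.05 only drives report formatting. scipy.stats provides
the implementations; the tests re-derive r, slopes and F from their
definitions as an independent route.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes: 16
participants (8F/8M), 15 trials each balanced over three task types (240
trials), question ids drawn without replacement from a pool of 8 per type,
per-type heatmap entropy HE ~ N(16.46, 0.92²), N(16.05, 0.50²),
N(16.18, 0.65²) bits, and response time from the per-type linear models

| scope | slope (s/bit) | intercept (s) | R² |
|---|---|---|---|
| type 1 | 5.188 | −78.494 | 0.377 |
| type 2 | 1.496 | −20.697 | 0.178 |
| type 3 | 2.987 | −44.326 | 0.342 |
| overall | 4.28 | −64.76 | 0.354 |

with Gaussian residuals of SD `|slope|·sd(HE)·sqrt((1−R²)/R²)`, which makes
the population R² equal the target. Generating per type and pooling
reproduces the overall row analytically (pooled covariance/variance give
r → 0.595, slope → 4.24), so the overall model functions as a derived
check, not a second generation path. Likert difficulty means default to
2.5/4.0/5.5 (SD 1.0) for types 1–3 — only their ordering and separability
are consequential — rounded and clipped to 1..7. Genders carry no injected
effect, so gender tests estimate the nominal false-positive rate.

**Response-time positivity.** The Type-1 line is negative for HE below
≈ 15.1 bits, so a linear-Gaussian RT model necessarily produces some
non-positive values in the lower entropy tail (real response times are
positive because the real joint distribution is not linear-Gaussian; the
skew mismatch is a known limitation). Clamping at a floor censors ~19% of
Type-1 trials and attenuates the recoverable overall slope by ≈ 0.6 s/bit,
so the generator's default leaves the model intact; an optional
`rt_floor_s` enforces positivity at that documented cost, and ingestion of
real data always requires positive RTs.

**Entropy calibration (full-gaze mode).** Fast mode draws HE values
directly and is the default for statistics-only work. Full mode constructs
a fixation pattern per trial whose *computed* entropy matches the drawn
target: k well-separated equal-duration clusters give entropy ≈
(single-kernel entropy) + log₂ k, so a calibration curve tabulates the
actually computed mean entropy for k = 1..32 (4 placements each,
pool-adjacent-violators smoothed, required strictly increasing, cached).
A target is hit by picking the bracketing k and adding a (k+1)-th cluster
whose relative duration α solves the mixture-entropy interpolation by
bisection. Cluster centres sit on a jittered grid with a 5σ edge margin.
Durations are weight-proportional, scaled so the lightest fixation stays
above 120 ms (detectable at the 100 ms minimum); total fixation time is
4 s unless that scaling demands more. Gaze is sampled at 100 Hz with 2 px
isotropic jitter, clusters joined by two straight-line transition samples
that the detector rejects as saccades. Achieved entropy after the full
detection → KDE → entropy chain lands within ~0.03 bits of target on
average; targets outside the calibrated range (≈ 13.9–18.8 bits) are
clamped with a warning (<1% of Type-1 draws).

All randomness flows from one integer seed; per-trial substreams are
seeded by (seed, participant index, trial index), so datasets are
reproducible and independent of generation order.

## Problem sizes

Replicate studies use 100 datasets per scope (240 trials pooled, 80 per
type), chosen so replicate-mean sampling error is a few thousandths on r;
the full-gaze calibration study uses 80 Type-1 trials at full 1280×1024
grid resolution (mean sampling error of the 80 targets alone is
0.92/√80 ≈ 0.10 bits). The null-rate study uses 1000 replicates.

## Known limitations

- Gaussian residuals make synthetic RT distributions symmetric, unlike the
  right-skewed RTs typical of real tasks; means, slopes and correlations
  are unaffected but tail behaviour is not realistic.
- Participant nesting is ignored (no mixed-effects structure), matching
  the trial-pooled analysis the pipeline reproduces.
- Synthetic gaze contains no smooth pursuit, blinks, drift or
  velocity-profile saccades, so passing round-trip tests demonstrates
  correctness of the pipeline, not robustness to every real-data artefact;
  the invalid-sample and drop-fraction paths are exercised separately.
- Saccade labelling is not implemented; the fixation complement is
  sufficient for heatmap construction.
- AOI-based transition entropies (Shannon/Markov over regions) are out of
  scope by design — the metric exists precisely for interfaces where AOIs
  are unstable.
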