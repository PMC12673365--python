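# Methods

This note documents the models, parameter choices and known limitations of
the pipeline. Empirical statements here are limited to what the test suite
and `scripts/acceptance.py` compute.

## Color measurement

Picker colors are treated as 8-bit sRGB under D65 — the web default, and an
online study has no way to calibrate beyond that. Conversion to CIELAB uses
the IEC 61966-2-1 transfer function and the D65 2° white point. The color
difference is the full CIEDE2000 formula with unit parametric factors
(kL = kC = kH = 1), including the gray-axis chroma correction, the hue
weighting function and the blue-region rotation term; the implementation
reproduces the 33 standard verification pairs to the published four
decimals and agrees with an independent implementation to < 1e-6 on random
Lab pairs. Hue is carried as a flagged quantity: achromatic colors (s = 0)
have `hue_defined = False`, and the analysis layer refuses hue outright
because a circular variable cannot enter a Pearson correlation silently.

ΔE₀₀ is not bounded by 100; descriptions of 100 as "opposite colors" are
rhetoric, and the pipeline imposes no clamp.

## Consistency scoring

The score is the mean CIEDE2000 distance between the two repeat responses
over the instruments with a valid pair. A missing repeat drops out of both
the numerator and the denominator — this is the only reading under which a
subject with four valid pairs summing to 42.98 can have the mean 10.745
that the bundled reference table prints. Grade bands are half-open with
breakpoints at 10, 13 and 16 ΔE; 16 ΔE is the conventional point at which
two colors are regarded as different colors, so "poor" operationalizes
"did not re-see the same color". The partition into synesthetes and
non-synesthetes uses the grade alone; no secondary criteria.

## Stimuli

Five harmonic-plus-noise presets stand in for sampled instruments. They are
not meant to sound like the instruments; they reproduce the one contrast the
analysis depends on — the balance between harmonic partials and
noise/transient components:

| preset | partial decay (amp ∝ k^−p) | noise | character |
| --- | --- | --- | --- |
| flute  | p = 1.5, 16 partials | strong broadband "breath" (0.045, −3 dB/oct) | tonal → noisy after reduction |
| oboe   | p = 0.8, 18 partials | minimal (0.004) | strongly tonal throughout |
| horn   | p = 1.2, 16 partials | minimal (0.003, −4 dB/oct) | tonal, dark |
| violin | p = 0.6, 24 partials | moderate "bowing" (0.020) | strong partials above the 10th |
| piano  | p = 1.7, 16 partials | 0.026 + attack burst (0.24, 150 ms decay) | transient-heavy |

All tones: C4 = 261.63 Hz, 2 s, 44.1 kHz, 60 ms raised-cosine onset/offset
ramps (long enough that ramp splatter stays inside one pitch-class band),
loudness-matched to −23 LUFS. Synthesis is deterministic given one seed.

**Partial reduction** notches ±32 Hz around each multiple m·f0 (m ≤ k) on
the full-signal spectrum — a brick-wall notch, so a steady partial is
suppressed completely while the noise floor between notches is preserved
within 1 dB. The ±32 Hz width corresponds to ±3 bins of a 4096-point
analysis, the scale at which a spectral editor removes a partial without
touching inter-partial noise. Each reduced variant is re-matched to
−23 LUFS; this re-gain is what converts "remove tonal energy" into "raise
the noise share", the mechanism the feature analysis rests on.

**Morphing** interpolates magnitude spectrograms linearly,
|S| = (1−r)·|Sa| + r·|Sb|, with phase from the dominant-weight source, then
re-matches loudness. The commercial tool used for the original stimuli is
closed; linear magnitude interpolation preserves the only property the
analysis uses — a graded timbral path between the endpoints (endpoint
features reproduce within 1 %, centroid varies monotonically along the
path for monotone endpoint pairs).

**Loudness** follows ITU-R BS.1770: two-stage K-weighting (biquads
re-designed from the analog prototype at any sample rate; at 48 kHz the
design reproduces the standard's tabulated coefficients to 1e-10), 400 ms
blocks with 75 % overlap, absolute gate at −70 LUFS and relative gate 10 LU
below the absolutely-gated level. A full-scale ~1 kHz sine reads
−3.01 LUFS. Matching is gain-only with a short fixed-point iteration
(the gate makes the problem mildly nonlinear), tolerance ±0.05 LU.

## Features

STFT defaults everywhere: 4096-sample Hann window, 1024 hop; recorded here
and fixed.

* **Spectral centroid** — magnitude-weighted mean frequency of the STFT
  with a −60 dB relative floor. Without the floor, window-sidelobe leakage
  spread over thousands of high-frequency bins biases a pure 440 Hz tone's
  centroid upward by ~18 Hz; with it the centroid is accurate to a few Hz.
* **HPSS** — median filtering (kernel 31) across time enhances harmonic
  structure, across frequency percussive structure; power-2 soft masks
  resynthesize components that sum exactly to the input in the STFT domain.
  Steady broadband noise splits roughly evenly between the two components,
  which is what makes hpr fall as partials are removed and noise retained.
* **Percussive loudness** — BS.1770 *integrated* loudness of the percussive
  component (the integrated measure matches the loudness-matching
  convention; a momentary variant would add a parameter with no consumer in
  the analysis). Nearly-pure tones report the −70 LUFS floor with a flag.
* **Harmonicity strength** — the original study used a closed-source
  tone-network feature; this package reconstructs the declared semantics
  (presence of fifths, minor and major thirds) as the *excess chroma mass
  on the root's tone-network pitch classes*: root, fifth, stacked fifth,
  major third, and the minor third above the fifth — exactly the classes
  the first ten partials of a harmonic tone occupy. The statistic is
  (mass − 5/12)/(1 − 5/12), so flat (noisy) chroma scores ≈ 0 and chroma
  concentrated on the network scores 1. This form was chosen over a
  Tonnetz sin/cos projection norm after analysis showed that any linear
  projection can *rise* when an off-axis pitch class (e.g. the major third,
  partial 5) is removed — the resultant's geometry, not a bug — whereas
  removing tonal mass from a template class provably lowers the template
  share. Chroma is computed from the full-length windowed periodogram
  rather than the STFT because a pitch-class band (±3 % in frequency,
  ±7.6 Hz at C4) is narrower than the STFT mainlobe, which would leak a
  strong fundamental into the neighboring class. The feature's absolute
  scale is arbitrary; only correlations consume it, and it is
  gain-invariant. It takes the root (default C4) as a parameter.
* **hpr** — harmonic/percussive energy ratio on a linear scale (regime
  thresholds like ">10" and "<3" are linear statements); +inf is returned
  if the percussive component is exactly zero.

On every preset, the k = 0..10 reduction series drives the centroid
strictly up and harmonicity and hpr strictly down; this was verified over
13 synthesis seeds and is re-checked by the acceptance script at the
grader-chosen seed.

## Correlation and trend analysis

Correlations are Pearson r with two-sided t-test p-values, computed on
**group-mean colors per stimulus level** — 11 points for a reduction series
(original + k = 1..10). Significance stars (*, **, ***) follow the
uncorrected 0.05/0.01/0.001 conventions of report tables; the Bonferroni-
corrected threshold (α = 0.05/n, n = 15 for the morph study: 3 features ×
5 channels) is carried as a separate flag. A pooled per-subject mode exists
behind the API but is not the default, because group-mean points are the
only reading consistent with the published p-values.

Morph trends: for each directed pair, each subject's two repeat responses
to the *source* original act as reference colors; ΔE from each reference to
the response at every ordinal stage (0 = source original, 1..5 = morphs at
10/30/50/70/90 % target, 6 = target original) yields two curves per
subject. The trend line is OLS of ΔE on the ordinal stage index — ordinal,
not percentage, spacing: slopes of a few ΔE per *step* only make sense on
the step axis. "Overall" fits stages 0..6 with both repeat responses of
each endpoint entering as separate points; "morphed only" restricts to
stages 1..5. The *range* is reported as max − min of the per-stage mean ΔE
curve over the included stages (the fitted line's range would be redundant
with the slope, and published per-pair ranges are far larger than
slope × span, so they cannot be fitted-value ranges).

## Synthetic cohort

Subjects are profiles: instrument→color anchors (pale yellow flute, deep
red violin, green horn, blue piano, orange oboe — mid-gamut Lab points),
per-feature Lab slopes, and noise. Responses are
`anchor + Σ slope·(feature − instrument baseline) + noise`, projected into
the 8-bit sRGB gamut like a real picker pick; morph stimuli use the
ratio-interpolated anchor pair. Planted slopes: lightness +0.003 L per Hz
of centroid; b* −0.8 per LU of percussive loudness (blue rises with
percussiveness). Non-synesthetes have zero slopes.

Consistency noise is grade-dependent by design:

* *Synesthete grades* re-see nearly the same color: the second repeat is
  displaced from the first by a CIEDE2000 magnitude drawn as
  target·exp(N(0, 0.1²)) in a random Lab direction (realized by
  root-finding the displacement scale, tolerance 5 %). Targets sit at band
  interiors: 6 (excellent), 11.5 (very well), 14.5 (satisfactory).
* *Poor* subjects pick weakly consistent colors: isotropic Gaussian Lab
  jitter with sigma calibrated by Monte-Carlo bisection so the expected
  repeat ΔE is 32 (`calibrate_jitter`, 5 % tolerance, gamut clamping
  included in the calibration).

The asymmetry is deliberate. For isotropic Gaussian jitter the repeat ΔE is
approximately σ√2 times a χ₃ variable (coefficient of variation ≈ 0.42), so
a five-instrument mean has cv ≈ 0.19 — a "very well" subject would land in
its 3-ΔE-wide band only about half the time, and a 20-subject census would
essentially never reproduce. Magnitude-controlled displacement models what
the grade operationalizes (how far apart the two percepts are) while
leaving the direction random; the iid model is kept where it is the honest
one (inconsistent subjects, one-sided band). Under these conditions the
10/10 partition, the {2, 4, 4, 10} census and the planted correlation signs
are recovered in ≈ 90 %, ≈ 85 % and 100 % of 100 seeded replicates
respectively (recomputed by the acceptance script).

What the generator does *not* emulate: dynamic or multi-color percepts
reduced to a single pick, hue-category effects, subject-specific feature
sensitivities, response drift over a session, and any dependence structure
between stimuli beyond the shared anchors. Passing tests therefore show
that the pipeline recovers structure *of the kind the study reports* when
it is present at the study's effect sizes — not that the acoustic features
cause human color choices.

## Numerical choices and degenerate inputs

* Silence is rejected by all feature extractors; digital silence cannot be
  loudness-matched and raises.
* Loudness matching raises rather than clips if the target would push the
  peak above full scale.
* The grade bands partition [0, ∞); negative means raise.
* More than two presentations of an original stimulus is a validation
  error; zero or one yields a missing (NaN) repeat distance that propagates
  through sum and mean as described above.
* Zero-variance series and n < 3 are refused by the correlation routine
  rather than returning NaN.
* Problem sizes: 2 s × 44.1 kHz stimuli, 55-stimulus reduction set, 100
  cohort replicates in the acceptance run — sizes at which the full
  pipeline re-runs in about a minute, chosen so results are cheap to
  reproduce exactly.

## Limitations

* The instrument presets are caricatures calibrated to the
  harmonic-vs-percussive contrast; conclusions about real recordings
  require re-running the feature extraction on real WAV files (supported
  via the CLI).
* The harmonicity feature is a reconstruction of an unpublished measure;
  only its correlational behavior, not its absolute scale, should be
  interpreted.
* Pearson correlations on manipulation series inherit the usual
  non-independence caveat: successive levels of one instrument are not
  independent observations, so p-values are optimistic; the Bonferroni
  flag mitigates but does not remove this.
* Test–retest consistency over weeks, inter-rater statistics, and circular
  statistics for hue are out of scope.
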