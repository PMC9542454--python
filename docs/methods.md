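# Methods

This note documents the models, parameter choices and numerical decisions
behind `faceemg`, and what the test suite does and does not establish.

## Session model

A session is an ordered sequence of 25 video events over a common timeline:
five neutral videos (76 s in total), six negative (93 s), five neutral
(81 s), nine positive (78 s), separated by 10 s rating breaks. Event
intervals are half-open `[start_s, end_s)` in seconds from session start;
each block's printed total duration is split evenly across its videos. The
per-block totals sum to 328 s of video; some study descriptions quote a
338 s total, which is inconsistent with the per-block numbers — this
package follows the per-block durations. A session recording spans the last
event's end plus one final rating break.

## Synthetic cohort generator

`faceemg.synthetic_data` generates cohorts with the statistical structure
the analysis assumes, so every downstream stage can be validated end to end
with no recorded data.

**Signal model.** Each channel is Gaussian white noise band-passed to
20–450 Hz (the informative facial-sEMG band; at reduced sampling rates the
band shrinks with Nyquist), normalized to unit SD, and amplitude-modulated
by a per-sample gain profile: a muscle- and category-specific activation
gain during videos, a resting gain (0.7) during breaks, with 100 ms
raised-cosine transitions to avoid spectral edge ringing. On top of the
myogenic carrier the generator adds:

- 50 Hz powerline interference with harmonics (amplitude of harmonic *k*
  falls off as 1/k; default base amplitude 1.0 × the baseline carrier SD,
  3 harmonics), with per-channel random phase;
- sub-20 Hz artifacts: a 0.3 Hz-band random-walk drift plus Poisson-timed
  (0.2 s⁻¹) 200 ms biphasic blink-like pulses, together scaled to 2 × the
  baseline carrier SD. All artifact content is kept below 20 Hz so the
  muscle-specific high-pass must remove it — a testable contract.

**Effect profile.** The default gains encode the expected physiology:

| muscle            | rest | neutral | negative | positive | arousal coupling |
|-------------------|------|---------|----------|----------|------------------|
| orbicularis (l/r), zygomaticus (l/r) | 0.7 | 1.0 | 1.25 | 1.9 | 0.4 |
| corrugator        | 0.7  | 1.3     | 1.5      | 1.05     | 0.0 |

Arousal coupling multiplies the envelope by `1 + c·(arousal − 5)/4`, so a
unit coupling doubles activation at rating 9 and vanishes at the scale
midpoint; the corrugator's zero coupling makes it the configured arousal
null. The smiling muscles' `negative > neutral` ordering makes their
amplitude V-shaped in valence (negative videos are arousing); the
corrugator's gains fall monotonically from negative to positive content.
The corrugator values were additionally chosen so that its expected
amplitude is nearly identical in the low-arousal and high-arousal rating
bins given the category composition of those bins, matching the arousal
null at the condition-mean level.

**Ratings.** Valence and arousal are drawn per video from a normal
distribution with the per-category means/SDs of the study's manipulation
check — neutral (4.65 ± 1.11 valence, 3.41 ± 1.65 arousal), negative
(3.18 ± 1.70, 6.67 ± 1.40), positive (6.60 ± 1.26, 5.88 ± 1.48) — rounded
and clipped to 1–9. This discretized truncated normal is the simplest model
matching the printed summary statistics; tests compare simulated marginals
against its exact discretized means, not against the nominal parameters.

**Determinism.** A cohort is a pure function of its configuration:
per-subject seeds derive from the cohort seed via a `SeedSequence`, and
within a subject the rating draws precede the signal draws in a single RNG
stream, so ratings can be regenerated without synthesizing signals.

**What the generator does not emulate.** Electrode-contact variation,
cross-talk between overlapping facial muscles, habituation across the
session, non-Gaussian EMG amplitude distributions, subject-specific
baselines, or missing data. Passing tests therefore show that the pipeline
recovers effects *of the assumed form* at the study's size and noise level —
not that real recordings meet those assumptions.

## Denoising

- **Filter family.** 4th-order Butterworth, applied forward–backward
  (`sosfiltfilt`), i.e. zero-phase with 8th-order magnitude response —
  standard sEMG practice with a monotone pass-band. High-pass cut-offs are
  muscle-specific: 30 Hz for the corrugator, 20 Hz for orbicularis and
  zygomaticus (facial muscles carry real myogenic power near the
  low-frequency edge, so the cut-off must not be higher than necessary).
- **Low-pass.** Nominally 500 Hz; at 1000 Hz sampling that equals Nyquist
  and is unrealizable, so the effective cut-off is `min(500, 0.45·fs)` =
  450 Hz at the study rate. Myogenic power above 450 Hz is negligible, so
  the narrowing is conservative.
- **Spectrum interpolation.** Run on half-overlapping 2 s Hann segments
  with canonical-dual-window synthesis (`ShortTimeFFT`), which tracks slow
  drift of the interference amplitude; signals shorter than two segments
  use a single whole-signal FFT. Per harmonic of 50 Hz up to the effective
  low-pass: magnitude bins within ±0.5 Hz of the harmonic are replaced by
  the linear interpolation of the mean magnitudes of the 1–3.5 Hz flanking
  bands on each side (excluding bins inside any other notch); phases are
  untouched, and bins outside every notch are untouched by construction.
  Harmonics at the spectrum edge with no stable flank on one side are left
  as-is. Whether to window, and the notch/flank widths, are this package's
  choices; they are exposed as parameters.
- **Order.** High-pass → interpolation → low-pass, fixed: band-limiting
  before interpolation would distort flank estimates near the cut-offs.

## Amplitude

- **Envelope.** Sliding RMS with window 0.25 s and hop 0.05 s (20 Hz
  envelope rate): long enough to smooth the EMG carrier, short enough to
  track expression dynamics. Both are parameters; MAV is available but the
  analyses use RMS. Window *i* covers `[i·hop, i·hop + window)` and is
  timestamped by its start.
- **Winsorization.** Asymmetric, exactly as the procedure defines it:
  values strictly below the 5th percentile are set to 0 (not to p5),
  values above the 95th are clipped to p95. Percentiles use linear
  interpolation (NumPy default); re-winsorizing is therefore only *nearly*
  idempotent (the re-computed p95 of clipped data interpolates marginally
  below the clip level), which the tests document. A symmetric variant
  exists via the percentile arguments but is not used by the analyses.
- **Normalization.** Per-subject per-channel min–max over the whole
  session, breaks included (the procedure normalizes per subject without
  excluding breaks). The minimum is the post-winsorization minimum (0
  whenever any value fell below p5). A zero-dynamic-range channel maps to
  all zeros with a `DegenerateChannelWarning`.
- **Sensor average** is computed after normalization, matching
  session-level normalized traces; whether the original analyses averaged
  before or after normalization is not documented, and this is the
  package's documented choice.
- The composition is scale-invariant: filtering and the FFT are linear,
  RMS is positively homogeneous, winsorization/min–max are
  scale-equivariant — so channel units (and amplifier gain) cannot reach
  any downstream result. Verified end to end at 1e-9.

## Epoching and aggregation

Videos are the aggregation unit: per-video means of the normalized
envelope, then unweighted means over the subject's videos in a condition
(not duration-weighted). Rating bins are 1–4 (negative/low) and 6–9
(positive/high); the midpoint 5 is excluded. Rating-level pooling (for the
correlations and the V-shape fit) is per subject per level: one point is
one subject's mean amplitude at one valence level. Subjects lacking a
condition yield no record, are logged, and drop out of paired tests
pairwise — with 1–9 rating bins this can reduce n below the cohort size,
and the tables report the realized `n_pairs`.

## Statistics

- **Wilcoxon signed-rank**: two-sided, normal approximation with
  tie-corrected variance and no continuity correction; zero differences
  discarded by default (Pratt handling available). Sign convention:
  `wilcoxon_paired(x, y)` has z > 0 when x tends to exceed y; table rows
  state `condition_a` and `condition_b` explicitly. Fewer than 5 usable
  pairs raises a degenerate-comparison error; family tables record such
  cells as flagged rows so the family stays structurally complete. The
  test suite bounds the normal approximation against exact enumeration
  (≤ 0.08 at n = 8, ≤ 0.05 at n ≥ 10) and cross-checks against an
  independent implementation.
- **Friedman**: within-subject mid-ranks, tie-corrected χ² with k − 1
  degrees of freedom; an all-tied matrix is reported as χ² = 0, p = 1.
  Pairwise follow-ups run only when the omnibus test is significant at
  0.05, and are reported uncorrected (the correction families are defined
  only for the amplitude analyses).
- **Bonferroni families** are exactly the design's: m = 6 (5 sensors + the
  average) for each rating-bin family, m = 18 (3 category pairs × 6
  modalities) for video type.
- **Stars**: ns above 0.05, then `*` (0.01, 0.05], `**` (0.001, 0.01],
  `***` (0.0001, 0.001], `****` ≤ 0.0001 — smaller p, more stars.
- **Manipulation check table**: means ± SDs are computed over all
  individual ratings per category (the scale on which such summary tables
  are printed); the Friedman/Wilcoxon tests run on per-subject
  per-category means.
- **Segmented Pearson** correlations use points with level in the closed
  segment ([1–5], [5–9], [1–9]); zero variance raises rather than
  returning NaN. **Quadratic trend** is an ordinary least-squares fit of
  `a·x² + b·x + c` with standard errors from the unbiased residual
  variance (NaN when there are no residual degrees of freedom); a > 0 is
  the V-shape signature.

## Problem sizes used by the validation suite

- Effect recovery runs one full-size cohort: 38 subjects × ~578 s × 5
  channels at 1000 Hz, fixed seed, through the complete pipeline.
- Type-I control runs 200 null cohorts (equal gains, zero coupling) at a
  reduced size chosen for Monte-Carlo throughput: 15 subjects, 6 videos of
  8 s, 250 Hz sampling with a 20–110 Hz carrier band. The familywise
  rejection rate of the Bonferroni-corrected valence family is required to
  stay within two Monte-Carlo standard errors of 0.05.
- Oracle-equivalence checks run ≥ 100 randomized small instances per
  operation against brute-force reimplementations (naive window loops,
  rank-definition Friedman, signed-rank enumeration).

## Known limitations

- The normal-approximation Wilcoxon p is inaccurate for very small n; the
  package refuses n < 5 and documents the approximation error rather than
  implementing the exact distribution.
- Spectrum interpolation assumes the true spectrum is locally smooth
  around each harmonic; narrowband myogenic features within ±0.5 Hz of a
  harmonic would be flattened with the interference.
- The 18-test video-type family on clean synthetic cohorts is typically
  fully significant, including corrugator contrasts involving neutral
  videos that are weaker or absent in real recordings — real corrugator
  activity is noisier (it engages in non-affective expressions such as
  concentration) than the category-gain model.
- Envelope window/hop and the normalization span are parameters because
  recorded datasets preprocessed with different choices can only be
  matched by adjusting them.
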