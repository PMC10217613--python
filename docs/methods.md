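# Methods

## The measurement problem

Obstructive sleep apnea (OSA) severity is conventionally graded by the
apnea–hypopnea index (AHI): the number of manually scored apneas (complete
breathing cessations) and hypopneas (partial reductions) per hour of sleep,
with severity cut points at 5, 15 and 30 events/h. Manual scoring is slow and
rests on somewhat arbitrary visual rules. `respenv` implements an alternative,
scoring-free severity measure: the breathing amplitude of a nasal pressure
recording is tracked through the *difference envelope* — the gap between the
signal's upper and lower envelopes — and summarized by four statistics.
Because airflow amplitude collapses during respiratory events, a night with
more (or longer) events shows a smaller and more variable difference envelope.

## Pipeline

### Preprocessing

1. **Artifact removal.** Annotated cannula-detachment segments longer than
   1 s are cut out and the remainder concatenated. Overlapping intervals are
   unioned before the duration rule, so a detachment annotated twice is
   removed once and the rule applies to total contiguous detachment time. An
   index map records each surviving sample's original index; all event
   bookkeeping is done on the original time axis through this map, because
   events are scored there.
2. **Low-pass filtering.** 4th-order Butterworth, 3 Hz cutoff, applied
   zero-phase (forward–backward, `sosfiltfilt`). Zero-phase was chosen
   because the analysis is offline and phase distortion would shift extrema
   against the annotations; the effective magnitude response is the squared
   single-pass response. The digital design uses the bilinear transform, so
   deep-stopband attenuation is slightly *stronger* than the analog
   prototype `(1+(f/3)^8)^-1` (at 128 Hz sampling: gain 3.7e-3 vs 3.9e-3 at
   6 Hz, 1.3e-7 vs 2.6e-7 at 20 Hz); in the breathing band the two coincide
   to within a few ppm. Filtering runs on the concatenated post-removal
   signal; splice discontinuities receive no special treatment.
3. **Sliding z-score.** Each sample is normalized by the mean and population
   standard deviation of the 5-min window centered on it, recomputed at
   every sample. Windows shrink (truncate) at the recording edges rather
   than being padded. A window with zero spread maps to output 0 — a
   flatline carries no respiratory information — and the cumulative-sum
   implementation treats variance below a 1e-12 relative floor as zero so
   that flat stretches cannot blow up on rounding residue.

Recordings below 32 Hz sampling are rejected rather than resampled.

### Envelope construction

The preprocessed signal is smoothed with a centered 0.5-s moving average;
local extrema of the smoothed trace are found by first-difference sign
changes (a plateau contributes its midpoint once). Because smoothing
displaces peaks, each candidate is snapped to the true extremum of the
*unsmoothed* preprocessed signal within a centered 1-s window; ties go to
the earliest sample and duplicates merge. The refined maxima (minima) are
interpolated with a shape-preserving piecewise cubic Hermite polynomial
(PCHIP) to form the upper (lower) envelope; PCHIP avoids the overshoot a
natural cubic spline would add between breaths. Outside the first/last
extremum the envelope holds the boundary value constant — cubic
extrapolation can diverge at recording edges and the choice affects less
than one breath per end. Maxima and minima are processed independently;
alternation is not enforced. The difference envelope is
`max(upper − lower, 0)`; the clipped fraction is reported as a quality
indicator.

### Parameters and epochs

Over a span of the difference envelope: AV (mean), MD (median), SD
(population standard deviation) and CoV = SD/AV. The population SD
convention is fixed for determinism; at 3 840 samples per 30-s epoch the
difference from the n−1 convention is negligible. CoV is 0 when AV = SD = 0
and undefined (flagged, excluded downstream) when AV = 0 with SD > 0, so
that infinities never reach the ROC stage.

Parameters are computed over the full night and over non-overlapping 30-s
epochs laid out from cleaned-signal sample 0; a trailing partial epoch is
dropped (a shorter window would bias SD). An epoch is labelled positive
when at least one of its samples maps into any scored apnea or hypopnea
interval — event types are not differentiated — and its total event-overlap
seconds are recorded for the duration-stratified analysis.

### Evaluation

Full-night parameters classify patients at AHI thresholds 5/15/30 plus an
extreme contrast (non-OSA, AHI < 5, vs severe, AHI ≥ 30); epoch parameters
classify pooled epochs (no per-patient weighting) as event/no-event. AUC is
the trapezoidal area under the empirical ROC, equal to the tie-corrected
Mann–Whitney statistic. Orientation is fixed a priori from the mechanism —
AV and MD classify with lower-is-positive, SD and CoV with
higher-is-positive — never chosen as `max(AUC, 1−AUC)`, which would bias
results upward. Correlation with AHI is reported as Spearman's ρ (primary;
AHI is heavily right-skewed) alongside Pearson's r. Distribution summaries:
per-value-bin event percentages (final bin open-ended for extremes),
per-severity-group histograms normalized by group patient count, and
per-duration-bin boxplot statistics (bins: exactly 0 s, then (0,5] … (25,30]
s of event overlap) with type-7 (linear-interpolation) quartiles and the
1.5·IQR whisker/outlier rule.

## Synthetic recordings

No clinical recordings ship with the package; the `synth` module generates
nasal-pressure-like signals with known ground truth:

    x(t) = A(t) · E(t) · D(t) · sin(φ(t)) + b(t) + ε(t)

- φ integrates a breathing rate of 0.25 Hz jittered uniformly ±10% per
  breath — the adult eupneic range;
- A is a slow lognormal amplitude drift (random-walk control points every
  30 s, step SD 0.1), emulating body-position and sleep-stage changes;
- E ramps to a per-event residual over 2 s with a half-cosine (apneas
  retain 5% of local amplitude, hypopneas a uniform 30–70%), so the
  envelope is not handed trivial step edges;
- D zeroes the carrier during cannula-detachment artifacts;
- b is a slow additive baseline wander (SD 0.1 relative, control points
  every 60 s) and ε white noise (SD 0.05 relative).

Events (≥ 10 s, 10–60 s uniform before feasibility squeezing, never
overlapping, ≥ 2-s gaps) are scheduled to realize a target AHI exactly, up
to event-count rounding; an infeasible target raises. Cohorts draw each
patient's target AHI uniformly within its severity stratum (severe:
30–90 events/h) and derive per-patient seeds from one master seed, so
everything downstream is a deterministic function of that seed.

What the generator does *not* emulate — and what passing tests therefore do
not show about clinical data: non-sinusoidal (flow-limited) breath shapes,
post-event recovery hyperpnea, cardiogenic oscillations, scorer
disagreement, and residual artifacts other than detachment. One observable
consequence: without recovery hyperpnea, the sliding z-score slightly
amplifies unobstructed breathing in event-rich windows, so the full-night
MD is not rank-monotone in AHI on synthetic cohorts even though epoch-level
MD discriminates events well; full-night MD was likewise the weakest
full-night classifier on clinical data.

## Problem sizes and numerical choices

Tests and the acceptance script use 30-minute recordings and cohorts of
40 patients (balanced across severity strata, or 20 non-OSA + 20 severe for
the discrimination checks), and 60–120-s signals for the per-signal
envelope invariants — sizes at which every stage's behaviour is already
asymptotic while a full run stays in the minutes range. Sliding statistics
are computed with cumulative sums (O(n)); the envelope stage is O(n) plus
O(breaths) refinement. All window widths round to the nearest sample;
centered windows of even width place the sample just left of center, a
convention shared by the smoothing, z-score and refinement stages and
pinned by the oracle tests.

## Known limitations

- Artifact detection (`detect_detachment`) is a convenience threshold rule
  on rolling peak-to-peak amplitude; analyses trust the annotation table.
- Epochs are aligned to the cleaned signal's start, not to any external
  30-s scoring grid; with artifacts removed mid-recording the two grids
  drift apart.
- No confidence intervals on AUCs; single-parameter classification only.
- EDF is read as stored (physical scaling honored, no unit conversion);
  EDF writing is out of scope.
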