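# Methods

## The generative model

`casum` simulates the readout situation of a multi-electrode slice
experiment in which calcium fluorescence is recorded from small groups
of co-imaged neurons (ROIs).  The model deliberately stays at the level
the readout can resolve:

- **Neuron.** A neuron is a threshold unit.  Its drive from a binary
  stimulation pattern **I** is the dot product with a non-negative
  lumped weight vector **w** (one entry per electrode, each entry
  absorbing electrode geometry, stimulated axon count, and synaptic
  efficacy), passed through a monotone dendrite-to-soma transform *f*
  and reduced by a subtractive inhibition offset.  If the result exceeds
  the spike threshold *T*, the neuron emits exactly one all-or-none
  calcium quantum — its unit amplitude in ΔF/F.  There are no membrane
  dynamics, no bursts, and no graded subthreshold calcium, matching a
  readout in which somatic calcium is a step function of spiking.
- **Cell group.** A group of 2–10 neurons is read out as the *sum* of
  its members' amplitudes plus Gaussian trial noise, clipped at zero.
  Noise-free group output is therefore bounded by the sum of the
  group's amplitudes (saturation) and is monotone in the set of active
  electrodes.
- **Graded limit.** A neuron constructed with `threshold == 0` is
  treated as a graded linear unit contributing `amplitude · max(drive, 0)`.
  This is not part of the default generator; it exists as the
  threshold-free limit in which scaling and gain/offset identities hold
  *exactly*, which the test suite uses as closed-form ground truth.
  The saturation bound applies to the thresholded (binary) regime only.

### Perturbations

- `scale_input`: multiplies the raw drive `I·w` by a factor `a`
  (default 0.75) before the transform — reduced stimulation current
  treated as a scaled effective input.
- `block_inhibition`: sets the subtractive offset to zero (the GABA-A
  block).  Inhibition is subtractive on drive, not divisive: tonic
  inhibition acts as a constant offset current in spiking cells, which
  is exactly the mechanism that produces an additive (offset) rather
  than multiplicative (gain) change in the I–O relation.
- `ltp`: multiplies the weights on one (tetanized) electrode by
  `ltp_factor` and, modelling slow homeostasis, all spike thresholds by
  `homeostatic_threshold_factor`.

### Generator defaults and what they emulate

| parameter | default | rationale |
|---|---|---|
| `n_electrodes` | 5 | protocol maximum; 31 binary patterns |
| `n_groups` | 15 | mid-range of the 7–20 ROIs recorded per slice |
| group size | {2..10}, mean 4 | truncated geometric `P(k) ∝ 0.70734^(k−2)`, decay solved so the mean matches the ~4 overlapping neurons estimated per ROI (uniform on {2..10} would give 6) |
| weights | lognormal, median 0.7, log-SD 1.0 (drive units) | a "wide range of effective weights": heterogeneous and heavy-tailed |
| `rho` | 0 | within-group weight correlation; log-weights mix a shared per-(group, electrode) factor and an independent per-neuron factor as `√ρ·g + √(1−ρ)·z` |
| thresholds | Normal(2.0, 0.3) truncated at 0 (drive units) | places single-electrode drives mostly below and multi-electrode drives mostly above threshold, the operating point at which a 25% current cut visibly truncates responses |
| amplitudes | lognormal, median 0.03 ΔF/F, log-SD 0.3 | per-neuron quanta of a few percent ΔF/F |
| `inhibition_offset` | 0.15 | mild tonic offset (≈7% of threshold); removing it lifts responses by several percent of the maximum without changing gain |
| `noise_sd` | 0.01 ΔF/F | ≈14% of the mean group response — realistic trial-to-trial scatter for single-trial ΔF/F |
| trials | 3 | protocol convention; trial aggregation is the arithmetic mean |

The weight/threshold operating point was chosen once so that the
default slices live in the physiological regime the analysis is built
for: most groups linear under both models, single-electrode responses
sometimes silent (zero-assigned), and the three perturbations producing
their characteristic signatures (see "What the re-enactments show").

**What the generator does not emulate:** dendritic geometry and
electrode placement, multi-spike bursts, indicator saturation and
bleaching, slow drift of electrode efficacy, correlated (non-white)
noise across patterns, and the saturation of network activity at high
input once inhibition is blocked.  Passing tests therefore show that
the *analysis chain* is correct and that the *mechanistic account*
(heterogeneous thresholds linearize group readouts; subtractive
inhibition ⇒ offset; homeostatic threshold increase ⇒ gain drop) is
self-consistent — not that real slices have these parameter values.

## Trace processing

Peak ΔF/F uses a 500 ms baseline window ending at stimulus onset and a
100 ms peak window after onset; both windows are half-open on the left
(`(onset−0.5 s, onset]`, `(onset, onset+0.1 s]`) — only the durations
are physiologically fixed, so the boundary convention is ours and is
applied consistently by the synthesizer and the measurement.  Area is
the trapezoidal integral of ΔF/F over the peak window; with a fixed
decay constant it is proportional to the peak, which is why the peak is
the working readout.

Synthetic transients rise in one sample to `baseline·(1+peak)` and
decay exponentially (default τ = 0.4 s) on a 122 Hz sampling grid, so
`compute_dff` recovers a configured peak to within one sample of decay
(≈2% at the default rate and τ).

The paired-pulse ratio fits a single-exponential decay to the first
response between its peak and the second onset (the dashed-extrapolation
procedure), subtracts the extrapolation, and divides the residual second
peak by the first.  Degenerate traces (non-positive first peak, too few
samples to fit) raise rather than return garbage.

Overlap counting on a depth-intensity profile: contiguous regions
brighter than a prominence threshold (default 20% of the profile
maximum — the criterion is not physiologically fixed, so it is a config
parameter) contribute the larger of their prominent-peak count and
`ceil(width / 30 µm)`, 30 µm being the single-soma width; the count is
scaled by `healthy_depth / imaged_depth` (≈2 for 150 µm imaged of a
300 µm healthy core).  Whether the peak-count and width criteria should
combine as a maximum is one reading of an under-specified rule; the
maximum is used because either criterion alone is a lower bound on the
number of somata.

## Summation models

- **Model 0** solves, per group, the least-squares problem
  `actual ≈ patterns @ W` on trial-mean responses over all patterns
  (`numpy.linalg.lstsq`; the full `2^N−1` design always has full column
  rank).  Weights are unconstrained in sign, as the objective is a pure
  error minimization.
- **Model 1** uses the group's measured single-electrode responses as
  fixed weights; an electrode whose singleton response is at or below
  the detection floor (default 0) is zero-assigned.  Predicted and
  actual responses are both divided by the group's mean response over
  all patterns.  Normalizing both axes keeps the 45° interpretation of
  the I–O curve; the reading in which only responses are normalized is
  available via `normalize_both_axes=False`.
- **I–O fit.** Points with predicted = 0 *and* actual = 0 are excluded
  (they carry no information about the transform); a group needs ≥ 3
  included points with positive prediction.  The through-origin slope is
  `Σxy/Σx²` and scatter is the **uncentered** statistic
  `R² = 1 − Σ(y−bx)²/Σy²`.  This is *not* the centered coefficient of
  determination: the denominator is the raw sum of squares of the
  responses, so the two statistics disagree whenever the response mean
  is far from zero, and the uncentered form is the more generous of the
  two for through-origin fits.  It is implemented exactly as printed
  because the linearity criterion (R² > 0.75, strict) is defined on it.
  At the least-squares through-origin slope it is guaranteed to lie in
  [0, 1].  The slope's 95% CI uses the t distribution with n−1 degrees
  of freedom and SE = √(SS_res/(n−1)/Σx²).
- **Sub-threshold responses** (at or below the detection floor) are set
  to zero before fitting, mirroring the minimum detectable level of
  cellular activation in the calcium readout.

## Perturbation analysis

`compare_conditions` regresses post against pre trial-mean responses
per group (OLS with intercept) and pooled across groups; points with
zero pre response are dropped.  This decomposition is model-free.

`slope_change_test` compares `log(actual/SSER)` across conditions with
a two-sample Student's t-test (paired available via config; two-sample
is the default because pattern sets may lose different points to the
zero rules in each condition).  `slope_changed` is `p < 0.05`.  The CI
criterion — post I–O slope inside the pre fit's 95% CI — is computed
and reported alongside (`ci_contains`) but does not drive the boolean.
Points where either axis is zero are dropped from the log-ratio test
(log undefined) and the dropped count is reported.

`summarize_population` reports the linear fraction (post condition),
the fraction with unchanged slope, the median % I–O slope change,
offsets as % of each group's maximum pre-condition response, and
Pearson correlations of per-group slope change and offset against
% potentiation.  % potentiation is defined as the relative increase of
the tetanized electrode's single-electrode response — the most direct
observable proxy for the induced weight change.

## What the re-enactments show (and their problem sizes)

All re-enactment cohorts use 10 slices × 15 groups (150 groups) at the
defaults above; the heterogeneity contrast uses a single 200-group
slice per condition.  These sizes keep every canned experiment under a
minute while leaving the population medians stable.

- **Scaling** (`a = 0.75`, trial noise set to 5% of the cohort's mean
  noise-free response): pooled cross-condition slope ≈ 0.78 with a
  small negative offset.  The fitted gain sits slightly *above* the
  scaling factor because neurons that stay above threshold respond
  identically in both conditions, and the truncation of sub-threshold
  responses appears as the negative offset.
- **Inhibition block**: pooled slope ≈ 1.0, mean offset ≈ +7% of the
  maximum baseline response, ~75% of groups keep their I–O slope.  A
  subtractive offset current produces an additive, not multiplicative,
  change.
- **LTP** (weights ×1.5 on one electrode, thresholds ×1.05): the median
  I–O slope change is negative but small (a few percent), and seed
  batches exist where it crosses zero — at modest potentiation the
  slope-lowering effect (the potentiated electrode's singleton response
  inflates the SSER while near-saturated combined responses cannot
  follow) and the slope-raising effect of the threshold increase
  (singleton responses, sitting near threshold, are suppressed more
  than combined ones) nearly cancel.  The documented calibration config
  (`LTP_CALIBRATION`: weights ×5, thresholds ×1.1) is dominated by the
  first effect and lands the median near −25% with ≈97% of groups still
  linear.
- **Heterogeneity contrast**: with heterogeneous uncorrelated weights
  (ρ = 0) ~90% of 200 groups are linear under Model 1; with strongly
  correlated weights (ρ = 0.95) and a shared expansive transform
  (f(x) = x², γ = 2 chosen as the mildest clearly expansive power) the
  fraction drops by several points.  The margin is a handful of
  percentage points, so single-seed comparisons can occasionally
  invert; the packaged experiment uses a documented fixed seed.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.Generator` seeded from
  named integer seeds (`SeedSequence`); identical configs reproduce
  byte-identical TSV outputs, recorded in a run manifest (config hash +
  file SHA-256).
- Pattern order is part of the file contract: ids `1..2^N−1`, bit *i*
  (0-based, LSB) of the id driving electrode *i+1*; `pattern_bits`
  strings are written electrode-1-leftmost.
- Thresholding is strict (`drive > T`), as is the linearity call
  (`R² > 0.75`).
- Groups whose mean response is zero cannot be normalized under
  Model 1 and are skipped with a logged warning; groups with fewer than
  3 usable I–O points are likewise skipped and counted.
- A t-test between two zero-variance, equal-mean samples returns NaN
  from the underlying routine and is reported as p = 1 (no change).
- The truncated-geometric group-size decay constant 0.70734 solves
  `Σ (k−4)·q^(k−2) = 0` on {2..10} to five decimals; the analytic mean
  of the documented distribution is 4.000.

## Known limitations

- The default-LTP gain decrease is directionally correct but small and
  seed-sensitive (see above); quantitative gain-change studies should
  use stronger potentiation (the calibration config) or larger cohorts.
- Model 1 slopes exceed 1 whenever tonic inhibition suppresses the
  singleton responses that form the SSER; this is a property of the
  estimator, not a failure of linearity.
- The trace synthesizer's one-sample rise makes peak recovery exact
  only up to one sample of decay; at 122 Hz and τ = 0.4 s this is a
  ≈2% downward bias.
- No conductance-based or otherwise biophysically detailed nonlinear
  summation model is included; the transform family is limited to
  identity, saturating (tanh), and expansive (power) shapes.
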