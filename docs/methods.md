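# Methods

This note documents the models implemented in `arisnn`, the defaults and the
reasoning behind them, and what the synthetic experiments can and cannot
show.

## Study design being modelled

Ten adults with chronic tinnitus heard two broadband-noise maskers (constant,
and 10 Hz amplitude-modulated) in separate 10-minute periods; tinnitus
loudness was rated 1–9 every minute, and 64-channel EEG (BioSemi, extended
10/20, downsampled to 256 Hz) was recorded before (T1) and after (T2)
stimulation. The ARI change score is the first post-offset rating minus the
final baseline rating; a participant is a *responder* when that score is
negative in **both** conditions. One participant whose highly variable
tinnitus made them an outlier is excluded from modelling via an explicit
configuration list, never inferred from data — leaving 6 responders and 3
non-responders. Each analysed recording is 15 s (3840 points) cut into 20
non-overlapping 192-point samples.

## Spike encoding

Threshold-based representation (TBR): per channel, per sample, the signal is
differenced and a spike of +1/−1 is emitted when the difference exceeds
±θ_c, with θ_c = α·SD(differences), α = 0.5 by default. Choices worth
noting:

- Thresholds are computed **per channel, per sample**, keeping samples
  statistically independent for cross-validation.
- The SD is the population SD of the consecutive differences of that sample.
- The first time step carries no spike, so spike trains keep the sample
  length (192).
- A constant channel has θ_c = 0 and emits no spikes (strict inequalities).
- Consequence of the relative threshold: encoding is invariant to scaling a
  channel by a positive constant, so amplitude effects only reach the model
  through waveform shape and cross-channel timing, not absolute size.

Decoding accumulates spike·θ_c steps from a start value; the reconstruction
error of each step is bounded by max(|Δx| − θ_c, θ_c), which for the signals
used here keeps the cumulative error well below θ_c·T (verified by a direct
error-recursion oracle in the tests).

## Reservoir

- **Geometry.** 1471 neurons at the centres of 1-cm³ voxels. The bundled
  coordinate file is a *synthetic* stand-in (grid voxel centres inside a
  brain-sized ellipsoid, 70 × 85 × 62 mm semi-axes) because the
  atlas-derived list is not redistributable; it preserves the neuron count,
  1-cm spacing, and head-like extent. Electrode positions come from the
  standard BioSemi-64 montage (via `mne`), affine-rescaled to the template
  extent, and each channel drives its nearest neuron (ties to the lowest
  index). With the bundled template all 64 channels map to distinct neurons.
- **Wiring (small-world rule).** Each ordered pair within radius r connects
  with probability p₀·(1 − d/r). Defaults: r = quarter of the template
  bounding-box diagonal (≈ 58 mm), p₀ = 0.15, 20% inhibitory connections,
  initial magnitudes Uniform(0, 0.1). This yields ≈ 2.9k–30k connections
  depending on template size (≈ 28k for the bundled one). The linear decay
  is one concrete choice of "probability decreasing with distance"; the
  analytic edge-count expectation Σp(d_ij) is exposed for testing.
- **Dynamics.** Discrete-time LIF: v[t] = λ·v[t−1] + Σ W_ij·s_j[t−1] +
  input drive, firing at v ≥ θ with reset to 0 and a 1-step refractory.
  Defaults θ = 0.5, λ = 0.9, input gain 0.5 (so a single positive input
  spike fires its input neuron). These constants are package defaults —
  plausible round values, all overridable in configuration.
- **STDP.** Nearest-spike additive rule with a 1-step window:
  potentiation (+a_plus) when the postsynaptic neuron fires at t and the
  presynaptic fired in [t−window, t−1]; depression (−a_minus) when a pre
  spike at t−window was followed by no post spike in (t−window, t]. Judging
  depression *after* the window means a single causal pairing changes the
  weight by exactly +a_plus, which also pins down the discretization
  unambiguously. Magnitudes clip to [0, w_max = 1]; the synapse sign (type)
  never flips; the wiring is fixed at initialization. Defaults
  a_plus = a_minus = 0.01, one epoch, membrane state reset between samples
  (sample order affects only the weight trajectory, and is fixed to dataset
  order).
- **Model comparison.** Group models are trained on concatenated group data
  ({responder, non-responder} × {AM, C} × {T1, T2} — eight models);
  per-subject models on each subject's 20 samples. T2 and T1 models that
  share an initialization are compared by elementwise subtraction, and every
  model is summarized by its activation level, the mean |W_ij|.

## Readout and cross-validation

One output neuron per training sample: weights initialized mod^rank (rank of
each reservoir neuron's first spike, mod = 0.9, silent neurons 0), then
adjusted by +drift for each later spike and −drift for each later silence
(drift = 0.25) — so the vector blends first-spike order with rate
information. Prediction takes the k = 1 nearest output neuron (Euclidean);
ties at k > 1 go to the class of the nearest neighbour. LOOCV leaves out one
*sample* by default, matching the 180-fold design (20 samples × 9 subjects);
this leaks subject identity between folds by construction, so a
`cv_unit="subject"` option leaves out whole subjects instead. Readout
vectors depend only on their own raster, so LOOCV reuses precomputed vectors
per fold.

The classification experiment uses only baseline (T1) samples: per
condition, the reservoir is STDP-trained on all T1 samples, each sample's
raster is collected from the trained reservoir, and LOOCV predicts the
responder label determined at T2.

## Statistics

- `confusion_metrics`: per-class accuracy = 100·diagonal/row sum, total =
  100·trace/total, reported to 2 decimals.
- `summarize_column`: mean and n−1 SD, rounded half-up to 1 decimal.
- Channel profiles: for each channel, the mean |W_ij| over connections
  incident to the channel's input neuron and its direct partners. Absolute
  weights are used (profiles of subtraction models use |ΔW_ij|); both the
  neighbourhood and the magnitude choice are the package's aggregation
  definition.
- Sites: the eight temporal electrodes {F7, F8, FT7, FT8, T7, T8, TP7, TP8}
  form the temporal site; other lateral channels are assigned by label
  prefix (Fp/AF/F frontal; FC/C frontocentral; CP/P centroparietal; PO/O
  occipitoparietal), odd numbers left / even right, midline excluded. Every
  lateral channel lands in exactly one of the 10 cells.
- `rm_anova`: mixed design with any number of within factors and one
  between factor. Each within effect (and its interaction with group) is
  tested univariately via orthonormal contrast scores, with the
  effect-by-subject interaction as error; the between effect is tested
  against subjects-within-groups. Sums of squares are Type III (unweighted
  group means — relevant here because group sizes are 6 vs 3);
  Greenhouse–Geisser ε comes from the pooled within-group covariance of the
  contrast scores (ε = 1 when an effect has 1 df); η_p² =
  SS_effect/(SS_effect + SS_error), which equals F·df₁/(F·df₁ + df₂). The
  engine is verified against a brute-force sums-of-squares oracle and
  against an independent mixed-ANOVA implementation on balanced designs.
  p-values are reported for description only and never drive automated
  decisions.

## Synthetic cohort generator

Defaults reproduce the analysed study conditions: 6 responders + 3
non-responders, 256 Hz, 15 s, 64 channels. Each channel is pink (1/f) noise
(SD 1.0) plus five band oscillations (2, 6, 10, 20, 40 Hz; base amplitudes
0.8, 0.6, 1.0, 0.4, 0.2) whose amplitude factors (Uniform 0.5–1.5) and
phases are **redrawn every 192-sample block**. A shared 10 Hz source is
mixed into the eight temporal channels with gain g = g₀·(1 + effect·δ),
g₀ = 1, where δ = +1 for responders at T1, −1 (AM) / −2 (C) for responders
at T2, and 0 for non-responders.

Two deliberate properties:

- **Block-wise randomization.** Redrawing amplitudes/phases per analysis
  block makes the 192-point segments exchangeable and removes persistent
  subject signatures. Without this, sample-level LOOCV would largely
  classify subject identity, and the effect-free null below could not hold.
- **The null and the demonstration condition.** With effect_size = 0 the
  classes are identical in distribution (a responder and non-responder
  recording with the same seed are bit-identical), so LOOCV accuracy must
  sit at the readout's exchangeability null, P(nearest neighbour shares the
  label) = Σ_c n_c(n_c−1)/(n(n−1)) ≈ 55% at 120/60 — note this is *below*
  the 67% majority rate, the correct chance line for a 1-NN readout.
  Because TBR normalizes amplitude per channel, the class gain becomes
  classifiable only through the synchrony it induces across temporal
  channels; accuracy grows monotonically with effect size, and
  effect_size = 8 is fixed as the documented strong-coupling demonstration
  (≥ 90% LOOCV accuracy at study scale), which is also the generator
  default.

What the generator does **not** emulate: volume conduction/lead fields,
artifacts (blinks, line noise), non-stationary subject traits, or any
empirically calibrated responder-vs-non-responder EEG difference — no
quantitative description of that difference exists to calibrate against. A
passing synthetic pipeline therefore demonstrates correctness and
sensitivity of the machinery, not clinical effect sizes.

## Problem sizes and determinism

The synthetic classification experiments run at full study scale (9
subjects × 20 samples × 192 steps, 1471 neurons, ≈ 28k connections; about
10 s per condition on one CPU). Unit tests use hand-wired toy reservoirs
and a 27-neuron lattice where exact oracles exist. All randomness flows
from explicit integer seeds (cohort seeds expand through `SeedSequence`
spawn keys per subject/condition/timepoint), and identical configurations
reproduce bit-identical outputs.

## Known limitations

- The reservoir constants (LIF, STDP rates, SWC shape, readout mod/drift)
  are declared defaults, not values recovered from data.
- Sample-level LOOCV shares subjects between train and test folds; use
  subject-level folding for generalization claims.
- The ANOVA requires a complete, balanced within-subject design and at
  least two subjects per group.
- Channel-profile aggregation (neighbourhood + absolute weights) is one
  reasonable definition among several; alternatives would change Figure-like
  per-channel summaries but not the trained models.
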