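# Methods

This note documents the models, statistics, numerical choices and
limitations of the package, in the order of the pipeline.

## Task design

One session presents 288 cue-outcome trials: three 72-trial stable blocks
followed by a 72-trial volatile block of three 24-trial sub-blocks. The
expected pairing (vertical cue → aversive outcome, horizontal cue →
omitted outcome) holds with probability 5/6 in the stable blocks and
1/6, 1/2, 5/6 in the volatile sub-blocks. Probabilities are realized as
exact counts (probability × block length, rounded): 60/12
expected/unexpected per stable block and 4, 12, 20 expected trials in the
volatile sub-blocks. Realizing counts exactly — rather than sampling
i.i.d. — is the only way every simulated subject sees identical
contingency totals, which the analysis assumes; randomness enters only as
a seeded permutation of the fixed label multiset within each block (one
seed per stable block, one for the volatile block, whose sub-block
generators are spawned deterministically). Balanced counts also hold for
cues (36/36), outcomes (36/36) and aversive subtypes (6 of each of 6 per
epoch). Unexpected-contingency positions are additionally balanced across
cue types (e.g. 6 vertical-omitted and 6 horizontal-aversive per stable
block); a switch disables that extra constraint, in which case the split
is randomized. Odd realized counts are rejected as configuration errors
rather than silently rounded, because they cannot satisfy the balance
invariants.

The first stable block is labeled `excluded` by default (movement
habituation); the analyzed view is always the 216 trials of the ES/LS/VL
epochs. Trial timing defaults: 1-s cue, 0.5-s inter-stimulus interval,
2-s outcome, 0.7-s inter-trial gap (4.2 s per trial, matching a 72-trial
block in ≈5 min).

## The binary hierarchical Gaussian filter

The observer receives the contingency bit u_k per trial. State: level-2
posterior mean/variance (μ₂, σ₂) over the contingency tendency and
level-3 posterior (μ₃, σ₃) over log-volatility. Tonic parameters ω₂, ω₃
set the baseline diffusion of the two levels. Updates per trial, in
order: prior predictions μ̂₁ = s(μ₂), μ̂₂ = μ₂, μ̂₃ = μ₃; predicted
variances σ̂₁ = μ̂₁(1−μ̂₁), σ̂₂ = σ₂ + exp(μ₃+ω₂), σ̂₃ = σ₃ + exp(ω₃);
level-2 posterior σ₂ ← (σ̂₁ + 1/σ̂₂)⁻¹, μ₂ ← μ₂ + σ₂δ₁ with
δ₁ = u − s(μ₂); level-3 posterior via the volatility weight
w₂ = exp(μ₃+ω₂)/σ̂₂, r₂ = (exp(μ₃+ω₂) − σ₂)/σ̂₂, the variance-scaled
level-2 surprise δ₂, σ₃ ← σ̂₃/(1 + σ̂₃w₂(w₂ + r₂δ₂)/2) and
μ₃ ← μ₃ + σ₃w₂δ₂/2.

The emitted 13 trajectories: α₁…₃, μ̂₁…₃, σ̂₂, σ̂₃, unc₁…₃, ε₂, ε₃.
Numerical and interpretive choices:

* **Defaults** μ₂⁽⁰⁾ = 0, σ₂⁽⁰⁾ = 1, μ₃⁽⁰⁾ = 1, σ₃⁽⁰⁾ = 1, ω₂ = −2,
  ω₃ = −6 are the canonical binary-HGF priors. Downstream use is Pearson
  correlation, which is invariant to affine rescaling of the trajectories,
  so conclusions are insensitive to moderate changes here; all values are
  configurable.
* **ε₃ form.** The default computes ε₃ = σ̂₂δ₃/σ₃ with δ₃ the generic
  variance-scaled level-3 surprise. A config switch
  (`epsilon3_form="canonical"`) substitutes the μ₃ update increment
  σ₃w₂δ₂/2, the more common definition of the volatility
  precision-weighted prediction error; it is off by default so the
  default output matches the form stated with the task.
* **α₁ singularity.** α₁ = (s(μ₂ᵏ) − s(μ₂⁽ᵏ⁻¹⁾))/δ₁ is undefined when
  the prediction error vanishes; within a guard tolerance (default 1e-8)
  α₁ is emitted as NaN and treated as missing downstream (pairwise
  dropped in correlations). The denominator is taken as δ₁ (prediction
  error before the update), making α₁ the effective level-1 learning
  rate: change in predicted probability per unit prediction error.
* **Degenerate variances.** A non-positive σ₃ after the update aborts
  with the trial index rather than clamping; clamped trajectories would
  silently corrupt the regressors.

The forward pass is validated against a straight-line re-evaluation of
every update formula (independent oracle) to 1e-10 relative tolerance.

## Synthetic recordings

The generator produces deconvolved-activity matrices directly (the
pipeline's input domain); it does not simulate calcium kernels, imaging
frames, or source extraction. Per cell: a stimulus-type-specific temporal
kernel (Gaussian bump, peak latency uniform over the outcome window —
emulating retinotopy, where each moving/looming stimulus reaches a cell's
receptive field at a different time), per-type amplitude heterogeneity,
and a cue-response kernel. Trial amplitude = base × epoch multiplier ×
photobleach decay × (1 + linked-parameter gain) × truncated-Gaussian
trial noise (CV 0.3), plus half-normal frame noise (σ = 0.05). About 5% of
trials receive a large platform excursion (> 0.25 mm), exercising the
exclusion filter.

Cohort presets encode the qualitative epoch patterns of the conditions
they emulate, as sign patterns, not magnitudes: wild-type SC and V1-axon
presets attenuate aversive responses in LS (multiplier 0.65) with the
modulation weighted toward the late half of the response window;
the mutant SC preset over-enhances in VL (1.35) weighted toward the early
half; V1-block, retinal-axon and mutant V1-axon presets are flat. Half of
cells are aversive-responsive; a quarter of cue-responsive cells are
orientation selective (vertical-preferring 60%). Linked subsets (20% of
cells in the SC presets) have gain coupled to volatility-level parameters
(wild type) or outcome-level parameters (mutant), gain 0.5 on the
standardized parameter.

Photobleaching is injected as g(k) = a·k^b + c (defaults 0.5, −0.3, 0.7)
over the *presented* trial index, since bleaching is monotone in time;
the analysis nevertheless fits and tiles a within-epoch curve, as the
trajectory normalization defines it. Pupil traces: baseline diameter set
from the preset's median area (0.79 mm² wild type, 0.62 mm² mutant),
cue-locked constriction and aversive-outcome dilation as alpha-function
transients (dilation per-epoch; the wild-type preset dilates less in VL),
plus smoothed Gaussian noise.

What the generator does **not** emulate: correlated noise across cells,
eye movements, slow state drift (arousal), non-Gaussian response
statistics, omitted-outcome responses, or any mouse-level random effect
beyond the seed. Passing tests therefore demonstrate the pipeline's
correctness and calibration under these idealized conditions, not
robustness to every property of real recordings.

## Population response statistics

Z-scoring is per cell within each analysis epoch (a switch allows
whole-session scope); zero-variance cells are flagged and excluded.
Responsiveness thresholds: peak trial-averaged z > 1 (somata) or 0.75
(axonal boutons). The outcome window is the 2-s outcome period; the cue
window the 1-s cue period; the early/late component split is at the
window midpoint (the boundary is not otherwise constrained).

The omnibus test is a sequential (type-I) fixed-effects ANOVA on z̄ with
blocks ordered group, mouse-within-group, cell-within-mouse, epoch,
group × epoch, mouse-within-group × epoch. Degrees of freedom are taken
from incremental column-space ranks, so the nested codings (which are
collinear with their parents) receive correct df. Including
cell-within-mouse makes the residual the cell × epoch interaction — the
error term that matches the epoch contrasts. Without it, between-cell
amplitude heterogeneity inflates the residual and the interaction test
becomes arbitrarily conservative; with it, the interaction p-value is
uniform under a flat (no-modulation) cohort, which the acceptance suite
verifies over 200 seeds.

Tukey-Kramer pairwise epoch comparisons use the studentized-range
distribution with the same within-cell error term (MSE from the
cell × epoch residual, df = (n_cells − 1)(n_epochs − 1)). This matters
because Δz is zero-sum per cell: a pooled MSE on Δz underestimates the
contrast variance by E/(E−1) and inflates the family false-positive rate
(measured ≈12% under flat cohorts versus ≈5% with the within-cell error
term). The same error-term logic applies to the pupil Δa statistics, with
animals as blocks.

Orientation selectivity (not otherwise defined by a threshold) is a
per-cell two-sided Mann-Whitney test between vertical- and
horizontal-cue trial responses at α = 0.05; per-animal preference counts
are tested by χ² with Bonferroni correction across animals, and
per-animal median response differences compared between genotype groups
by a two-sample Kolmogorov-Smirnov test.

## Neuronal trajectories

Per-cell aversive-trial responses z̄_k (outcome-window mean of the
within-epoch z-scores; excursion-excluded trials carried as missing so
trial alignment is preserved) are normalized per stimulus type: the mean
over each type's 18 trials (6 per epoch × 3 epochs) is subtracted, making
each type's trials exactly zero-mean.

The photobleaching curve f(k) = a·k^b + c is fit (multi-start nonlinear
least squares; exponents −1, −0.5, −0.1; a initialized to first−last,
c to the last value; best SSE kept) to the *population mean* trajectory
folded across the three epochs, i.e. a single curve over the within-epoch
trial index k = 1…36. Folding is implied by averaging across epochs; a
switch to the global index is not provided because the tiled-subtraction
step below defines k as within-epoch.

Each cell then loses a scaled tiled copy: Δz_k^res = Δz_k − d·f(k), with
f restarting at k = 1 each epoch and a *single* scalar d per cell, so
epoch-level contrasts (the contextual modulation of interest) are not
absorbed. d is the least-squares projection coefficient of the cell's
trajectory on the tiled curve, computed over the cell's non-missing
trials — this makes the residual's Pearson correlation with the curve
exactly zero, strictly inside the ±0.05 requirement, and is the unique
scale that does so optimally. A constant fitted curve yields d = 0 with a
warning.

## Correlation screening and inference

Pearson correlations of each residual trajectory with each of the 13
observer trajectories (aversive-trial subset, 108 trials), missing values
dropped pairwise; two-sided p via the t transform. q-values follow
Storey's method: π₀ estimated on a λ grid (0.05…0.95 step 0.05) with a
cubic-polynomial smoother evaluated at λ = 0.95 (a scalar λ selects the
fixed-λ estimator, used by the brute-force test oracle), then the
step-up q computation. p-values are pooled across all cell × parameter
pairs before conversion (per-parameter pooling available via a switch).
Significance is q < 0.05.

The polarity-bias test statistic per parameter is
(#positively significant − #negatively significant) cells. The null
permutes each cell's trajectory across trials independently per
repetition — destroying temporal alignment while preserving each cell's
marginal distribution — and re-runs the full correlation → pooled-q
pipeline each time (10,000 repetitions by default); two-sided p is the
null exceedance of |statistic| with the +1 correction, and q across the
13 parameters is Benjamini-Hochberg (a small fixed family). Parameters
with no significant cells report p = 1. Several observer parameters are
near-duplicates (e.g. μ̂₃ and unc₃ are affinely related); the screen
reports the 13 × 13 parameter correlation matrix, and no decorrelation is
applied — the procedure is deliberately univariate, and coupling-recovery
claims accept a collinear parameter (|r| > 0.8) as a hit.

Group comparisons of significant-cell counts are χ² on 2×2 tables
(without continuity correction, matching Σ(O−E)²/E), with BH FDR over the
comparison family; zero margins raise an error advising an exact test.

## Pupillometry

Area from the long-axis diameter, A = π(D/2)²/calibration with
6 × 10³ px² = 1 mm² (the long axis is invariant to gaze direction for a
circular pupil on a spherical eye). Non-positive or missing diameters are
carried as missing; a trial is dropped when more than 20% of its baseline
or window frames are missing (a conservative default; the missing-frame
policy is not otherwise constrained). A₀ is the mean over the 10 frames
before outcome onset; ā averages a(t) over the 2-s outcome window;
Δa = ā − ⟨ā⟩_epochs. The session median area is taken over all frames.
Group tests: Mann-Whitney U on median areas, group × epoch ANOVA and
Tukey-Kramer on Δa with animals as the error blocks.

## Receptive fields

The checkerboard grid defaults to 19 × 15 fields (3.7° × 2.9° fields
covering ≈70° × 44°), 4 Hz, 10 min, binary {0, 1} per field. The
response-weighted average subtracts each field's empirical temporal mean
before weighting; kernels span a 0.5-s window at 16.7-ms bins (lag 0 =
simultaneous). Peak latency is the lag maximizing spatially-summed
|kernel|. The spatial slice at peak latency is fit by a rotated 2-D
Gaussian (nonlinear least squares, moment initialization, bounded SDs);
RF size = SD_long + SD_short (twice the mean SD). Fits with R² ≤ 0.2 or an
SD spanning the grid are flagged non-convergent and the size left
missing. The synthetic unit is linear-Gaussian with an additive offset
holding the trace non-negative; reverse correlation is invariant to the
activity scale and, for zero-gain units, yields a structureless kernel.

## Problem sizes and runtime

Defaults match the study conditions (216 analyzed trials, 30.9-Hz frames,
six aversive types). The test and acceptance runs use desk-scale cohorts
chosen as the smallest sizes at which each property is
well-powered: pattern-recovery cohorts of 3-5 mice × 40-80 cells;
type-I calibration on a reduced design (24-trial blocks, two aversive
types, 200 seeds) whose calibration is invariant to trial count; polarity
false-flag calibration on 100 replicate 30-cell null cohorts with 200
permutations; the decay-removal bound on a 1000-cell cohort; the
receptive-field oracle on 50 units over a 16 × 12 grid with the full
10-min stimulus. A full default pipeline run (two presets, 4 mice × 100
cells, pupillometry and RF stages) completes in a few minutes on one
core.

## Known limitations

* The nested ANOVA treats mouse and cell as fixed effects; no
  random-effects variance components are estimated. With few mice and
  strong mouse-level effects a mixed model would be more appropriate.
* Storey's smoother π₀ estimate is unstable for small families
  (m ≲ 100); the polarity and group-comparison families therefore use BH.
* The decay model assumes a shared population curve shape; cells whose
  bleaching deviates in shape (not just scale) retain structure that can
  correlate with slowly varying observer parameters.
* The trajectory analysis uses aversive trials only; cue responses are
  excluded from observer correlation by design.
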