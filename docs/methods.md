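# Methods notes

This note records the scientific and numerical choices behind
`featloop`, in the spirit of a model-description appendix: what each
component assumes, which parameters matter, and where the design was
genuinely open.

## Orientation geometry and tuning estimation

All orientations live on a 180° circle (a grating and its 180°
rotation are the same stimulus), so every angular operation doubles the
angle inside trigonometric functions and offsets are reported on
[0, 90°].  Preferred orientation is the argument of the complex vector
sum of mean responses over the four grating orientations, and the
orientation selectivity index (OSI) is the magnitude of that sum
normalized by Σ|R(θ)|.  Two consequences worth making explicit:

* Responses can be negative after baseline subtraction of z-scores.
  They enter the complex sum signed, and only the denominator takes
  absolute values, exactly as the estimator is defined.  The OSI is
  therefore bounded by 1 but a strongly "anti-responsive" cell can have
  a well-defined preference.
* A vanishing vector sum (|z| ≤ 1e-12) has no defined preference; the
  estimator returns the convention value 0° with a degenerate flag.
  Flagged cells never pass the selectivity filters, so the convention
  value cannot leak into tuning-dependent analyses.

Tuning-dependent analyses use strict filters: cells with OSI > 0.4,
ensembles with OSI > 0.3 (an OSI of exactly 0.4 is excluded).  With a
four-orientation design the realizable tuning offsets are {0°, 45°,
90°}; pair-level offsets computed from continuous preference estimates
are assigned to the nearest of the three bins, with no interpolation.

## Preprocessing

Fluorescence is z-scored per neuron within each experimental block
(population standard deviation, ddof = 0); a zero-variance trace gets
an epsilon-floored divisor (1e-12) and a warning, producing zeros
rather than propagating NaNs.  Trial responses are baseline-subtracted
against a pre-stimulus window and reduced to a scalar by the mean over
the evoked window; the reducer is configurable (`peak`, `integral`)
because nothing downstream depends on the choice, but the mean is the
default.  Windows are specified in frames internally with a
seconds-to-frames converter (floor), since acquisition rates vary with
plane count.  Holographic targets are matched to imaged centroids
one-to-one, greedily by global Euclidean distance — when two targets
claim one centroid the nearer wins and the loser rematches — and any
assignment beyond 12 µm is excluded.  The greedy policy is
deterministic, which the matching tests rely on.

## The decoder assay

The decoder is a one-vs-rest linear SVC with an L1 penalty
(`sklearn.svm.LinearSVC`, `penalty="l1"`, `dual=False`), trained on the
visual-trial responses of non-targeted pyramidal cells — all of them,
regardless of tuning.  The feature set excludes (i) every targeted
neuron and (ii) every neuron within a photoactivation-zone radius of
any target, 30 µm by default.  The radius is an assumption (the
off-target spread of holographic excitation is setup-specific) and is
exposed as a parameter; a leakage guard raises if a caller constructs a
feature set violating either exclusion, because a single targeted cell
carrying the photostimulation artifact would dominate every probe
statistic.

The penalty strength C is either given or selected by stratified
5-fold cross-validation over {0.01, 0.1, 1, 10}; the original strength
is unknown, and with well-separated synthetic classes the choice is
flat, so tests pin C = 1 for determinism and speed.  Prediction ties
break toward the lowest class orientation.  Weights below 1e-10 in
absolute value count as zero when defining "decoder-informative"
neurons — coordinate-descent solvers leave numerical dust that should
not count as selected features.

ΔPrediction is the angular difference between the predicted
orientation and the stimulated ensemble's preference; with four
equally spaced classes the chance-level error is exactly 45°, which is
subtracted so that 0 is chance, −45° is perfect completion and +45°
perfect suppression.  Baseline (OFF) decodes of the same trials serve
as the session-specific control in paired comparisons; decoder-error
analyses on visual trials require an explicit independent training
block (a `train_block` flag in the trial metadata) so that test trials
are never seen in training.

The modality check fits Gaussian mixtures with 1–5 components to
bootstrap resamples of per-ensemble decoder outputs (resampling at the
ensemble level, which is the exchangeable unit) and selects the
component count by AIC per replicate, reporting the distribution and
mode.

## Evidence and explaining away

Evidence for a class is the dot product of a population activity
vector with that class's weight vector, intercepts excluded: the
projection is meant to measure pattern alignment, and intercepts cancel
in every ON−OFF contrast anyway.  Both entry points are provided —
trial-averaged vectors for ensemble-level evidence curves, single-trial
rows for explaining-away — because the two analyses operate at
different levels.  When evidence is re-indexed by tuning offset from
the ensemble, the two classes at 45° offset are averaged (not summed)
so values are comparable across stimuli.

The explaining-away index for an ON trial is the mean flanking-class
evidence of same-stimulus visual-only (OFF) trials minus the trial's
own flanking evidence; positive values mean photostimulation
suppressed the competing interpretations.  The change in
correct-orientation evidence is computed alongside with the same OFF
reference.  Trials are grouped by the offset between the stimulus and
the ensemble preference: aligned (< 45°), misaligned (> 45°), with the
boundary (= 45°) kept as its own bin rather than folded into either.

Tuning-curve normalization for ON/OFF comparisons computes the offset
correction from the unperturbed (OFF) condition only — adding
|min(OFF)| when the minimum is negative — and divides both conditions
by the corrected OFF peak, so an ON curve identical to OFF also peaks
at exactly 1.  Cells whose corrected OFF curve is flat at zero are
excluded with a warning.  The operation is idempotent on already
normalized non-negative curves.

## The ring model

The network is a ring of N = 180 rate units with uniformly spaced
preferred orientations; inhibition appears as negative interactions
between units rather than as an explicit interneuron population.
Parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| κ_ff | 10 | feedforward von Mises concentration |
| ff_amplitude | 2.5 (z-drive units) | feedforward peak |
| ff_noise_sd | 0.1 | per-trial Gaussian noise on FF input |
| κ_exc | 4.0 | E→E concentration |
| κ_inh | [−3.6, 3.6] | I→E concentration; negative = anti-tuned |
| α | 0.001 | leak rate per step |
| T | 200 | steps per condition |
| sigmoid | min 0, max 10, slope 3, threshold 2 | rate function |
| S_exc | floor 0.05, max 1, slope 0.3, threshold 20 | excitatory gain of n_active |
| S_inh | floor 0.1, max 1, slope 0.3, threshold 20 | inhibitory gain of n_active |
| active_threshold | 0.01 | rate counting a unit as active |
| untuned masks | Poisson(3), scaled to ±0.1 | background connectivity |
| clamp_rate | 10 | rate at which clamped units are held |

The printed sigmoid and scaling expressions are implemented as standard
bounded logistics, min + (max − min)/(1 + exp(−slope·(x − threshold))),
the only reading consistent with a saturating activation.  The two
gain functions differ only in their floor; since the floors dominate at
sparse activation, inhibition outweighs excitation roughly 2:1 for
small active counts and the two converge toward 1 as the network
recruits — the mechanism behind the sparse/dense asymmetry.  The
untuned inhibitory background enters the drive unscaled, exactly as the
drive equation is written.

**Weight normalization.**  Tuned weights are von Mises kernels
normalized as circular *densities*: W(Δθ) = exp(κ·cos 2Δθ)/(π·I₀(κ)).
This keeps the summed synaptic budget of a kernel invariant to its
concentration, so sweeping κ_inh reallocates a fixed amount of
inhibition across tuning offsets instead of changing total inhibitory
gain.  The choice was made after examining the alternatives: peak
normalization (dividing by exp|κ|) equalizes E and I peak weights, and
since S_inh ≥ S_exc always, co-tuned drive is then net-inhibitory for
every clamp size — the dense-clamp regime never flips to elevation —
and the HWHM is non-monotone in κ_inh; raw exp(κ·cos 2Δθ) weights make
total excitation grow as I₀(κ_exc) and destabilize the ring globally
at intermediate κ_inh.  Density normalization is the reading under
which the model exhibits the full phenomenology: sparse clamps recruit
dominant co-tuned inhibition (suppression of co-tuned unclamped
units), dense clamps tip the balance to recurrent excitation
(elevation), output tuning sharpens monotonically and peak rate falls
as inhibition becomes co-tuned, and nearby stimuli decorrelate.

**Other numerical choices.**  Rates start at r(0) = 0; trajectories
are then bounded by max(sigmoid ceiling, clamp_rate), and with zero
recurrent weights the linear recursion converges geometrically to
f(FF) at rate (1 − α), which the tests check in closed form.  Clamped
units are reset to clamp_rate after each update; clamp runs use zero
feedforward input by default (whether the background drive stays on
during clamping is not determined by the drive equation, and zero is
the cleaner control).  clamp_rate defaults to the sigmoid ceiling so a
clamp both exceeds the active threshold and saturates the rate
function.  The feedforward amplitude must exceed the sigmoid threshold
(2) for input alone to drive activity; the default 2.5 is chosen so
the population peak does not ride the sigmoid ceiling, leaving
headroom for inhibitory tuning to modulate peak rate — at amplitude 5
the peak saturates identically for every κ_inh.  With α = 0.001 and
T = 200 the network traverses only ≈18% of the distance to its fixed
point; all "final activity" metrics are therefore snapshots of a slow
transient, which is intentional — the orderings across κ_inh, not
absolute rates, are the model's outputs.  Both parameters are
configurable, and the convergence test exercises the large-T limit.

HWHM of a population curve is measured from the curve minimum
(baseline) to the maximum, locating half-height crossings on either
side of the peak by linear interpolation on the orientation ring and
averaging the two sides; a flat curve returns NaN.

The sweep covers stimuli 0–90° in 5° steps (the other half of the
orientation circle follows by rotation symmetry, which is also a
tested invariant) with feedforward noise off, so orderings across
κ_inh are exact rather than trial-averaged.

## The synthetic generator

The generator emulates exactly the statistical structure the analyses
consume: scalar per-trial responses equal to a von Mises tuning curve
(peak amplitude 1 z-unit, per-neuron concentration drawn uniformly
from [0.5, 4] so the OSI > 0.4 filter separates a genuinely mixed
population) plus additive Gaussian noise (σ = 0.1 z-units, matching
the trial-noise scale used in the network model), balanced over the
four orientations at 20 trials each.  Noise is applied to the scalar
response, not to frames: every downstream analysis operates on
scalars, and frame-level synthesis would only exercise the reducer.
Default population counts mirror a typical imaging session (≈1,400
neurons); tests run at ≤300 neurons, which preserves every qualitative
result at a fraction of the cost.

Photostimulation effects are Δθ-dependent kernels, linear between
anchors at 0° and 90° (the design only realizes three offsets), scaled
by a monotone logistic gain of ensemble size, with cell-type presets:
like-to-like SST recruitment (+0.6 → +0.1 z-units, size-scaled),
untuned PV suppression (−0.2 flat), and a size-dependent PC kernel
that blends from net suppression of the co-tuned pattern (−0.25 at 0°,
+0.1 at 90°) for sparse ensembles to like-to-like completion (+0.35 at
0°, −0.1 at 90°) for dense ones, crossing over around five targets.
Targeted members are driven to a fixed large amplitude (5 z-units).
Each photostimulation trial emits a paired baseline (OFF, pure noise)
and stimulation (ON) row so paired decoder contrasts are testable.  An
optional per-ensemble amplitude jitter models the across-ensemble
effect variability seen in real experiments without asserting any
particular variance.

For visual-plus-photostimulation sessions the generator emits an
independent visual-only training block plus interleaved ON/OFF test
trials, and supports either an offset-kernel effect (e.g. Gaussian
suppression of cells tuned ≈45° from the stimulus, gated to
ensemble-aligned trials) or a structured per-trial effect such as
removing the flank-stimulus response component of ensemble-co-tuned
cells.

What the generator does **not** emulate: calcium dynamics and
spike-to-fluorescence transforms, spatial off-target excitation
(lateral/axial point-spread), correlated (shared) trial-to-trial
variability, behavioural covariates, and non-stationarities across
blocks.  Passing recovery tests therefore show that the estimators are
correct under the assumed response model — independent Gaussian noise
around a von Mises mean plus additive stimulation effects — not that
they are robust to everything real recordings contain.

## Inference toolkit

Permutation tests shuffle group labels (default 10,000 resamples) and
use the add-the-observed correction p = (1 + #{|T*| ≥ |T|})/(n + 1),
which guarantees p ≥ 1/(n+1) and exact validity under exchangeability;
the statistic (mean or median difference) is a required argument with
no silent default.  Bootstrap CIs are percentile intervals of the
resampled mean (default 10,000 resamples) — the simplest defensible
method, recorded in the output.  Group comparisons are gated by
Shapiro–Wilk at α = 0.05 per group, dispatching to
t-test/ANOVA or Wilcoxon/Mann–Whitney/Kruskal–Wallis; the gate is
statistically debatable but is reproduced as specified, and the chosen
branch is recorded in every result.  Benjamini–Hochberg adjustment is
the standard step-up with monotonicity enforcement.  All resampling is
deterministic under a seed.

Calibration is verified empirically in the acceptance tests: the
permutation test rejects 4–6% of 2,000 null simulations at α = 0.05,
and the percentile bootstrap covers the true mean in 93–97% of 1,000
Gaussian samples at n = 50.

## Problem sizes

Test and acceptance runs use 300-neuron synthetic sessions (240 PC /
40 SST / 20 PV) with 20 trials per orientation, ensembles of sizes
1–25, 999–10,000 permutation resamples, 1,000–2,000 simulation
replicates, and the full 5 × 19 κ_inh sweep at N = 180, T = 200.  The
complete suite runs in well under a minute on one CPU.

## Known limitations

* The decoder is the package's single classifier family; nonlinear
  decoders and direction (8-class) decoding are out of scope.
* The ring model has no explicit interneuron populations, no spiking,
  and no stability-theoretic characterization; conclusions are
  orderings across κ_inh, not dynamical-regime claims.
* The explaining-away sign structure for *subgroup* decoders (co-tuned
  vs anti-tuned feature subsets) depends on the empirical weight
  structure of real populations; under the generator's additive linear
  effects the subgroup-restricted flank-class weights take the
  opposite sign, so the package asserts the subgroup machinery's
  contract rather than a particular sign.
* Ensemble membership is taken as declared; no significance criterion
  for photoactivation of individual members is applied.
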