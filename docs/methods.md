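# Methods

This note documents the models, algorithms and numerical choices behind
`oualt`, and what the synthetic-data pipeline does and does not establish.

## Decision model

Choices between a more equal and a more unequal token allocation are
modelled as leaky (Ornstein-Uhlenbeck) evidence accumulation.  The
momentary evidence for the equal option over the unequal one is the
Charness-Rabin utility difference

    VD = (1 - ω) E_self + ω E_other - [(1 - ω) I_self + ω I_other],

where `(E_self, E_other)` are the payoffs of the more equal option,
`(I_self, I_other)` those of the more unequal one, and ω ∈ [-1, 1] is the
weight on the other's payoff (the altruism weight).  Accumulated evidence
starts at the bias β and evolves in dt = 1 ms steps,

    EA(t+1) = EA(t) + (λ EA(t) + κ VD) dt + ξ_t ,

with absorbing thresholds at ±α (+α ⇒ equal choice), leak λ (1/s), drift
modulator κ, and response time = accumulation time + non-decision time τ.
Accumulation is cut off at the 3 s response deadline (timeout).

**Noise convention.** The per-step Gaussian increment ξ_t has scale
σ·√dt with σ fixed at 1.4, making σ a diffusion coefficient per √s and
giving the process a proper continuum limit; this is the package default
and the convention under which all reported parameter values live.  A
`literal_noise` flag instead uses scale σ per 1 ms step.  The literal
reading is dimensionally inconsistent with the regime the parameters
describe — per-step noise of 1.4 against thresholds near 1.2 terminates
accumulation within a few milliseconds and cannot produce ~0.8 s response
times — so it exists for completeness only.

**Zero-leak oracle.** At λ = 0 the model is a drift-diffusion process and
the upper-bound probability has the closed form
`(e^{kb} - 1) / (e^{kb} - e^{-kc})` with k = 2v/σ², b = α + β, c = α - β.
The validation table compares simulated choice fractions with this
formula at a threshold enlarged by the continuity correction for
discretely monitored barriers, 0.5826·σ·√dt per side; without the
correction the Euler scheme's boundary-overshoot bias (~0.007 in
probability at dt = 1 ms) is resolvable at 4×10⁴ simulations.

## Trial design

The 416-trial schedule crosses 2 inequality contexts × 4 reference
allocations × 26 alternatives × 2 trial sets.  DIS references are
24/74, 24/98, 46/74 and 46/98 tokens (self/other); ADV references are the
mirror images.  Trial set 2 repeats set 1 with a -1/0/+1 token jitter per
payoff, redrawn when it would break context purity, exceed the ±19 payoff-
change range, make a payoff negative or create an inequality tie.  The
jitter is drawn once per (reference, alternative) and applied sign-flipped
in ADV, so the two contexts carry identical multisets of absolute payoff
changes.

The 26 alternative offsets per reference are a package default (exposed as
a parameter of `generate_schedule`): per half, seven self/other trades
with |Δother/Δself| below 1, one dominated and one dominating option (both
payoffs moving in the same direction), two pure other-payoff changes, and
"give" options whose indifference points sit at ω* ≈ 0.05 and ω* ≈ 0.21.
This grid was fixed once so that, at the group-mean parameters below, the
simulated cohort reproduces the printed behavioural regime; the exact
published grid is not recoverable from text.

## Synthetic cohort

Group-mean generating parameters (per context):

| parameter | DIS | ADV | units |
|---|---|---|---|
| ω (altruism weight) | 0.10 | 0.15 | – |
| α (threshold) | 1.34 | 1.11 | evidence |
| β/α (start bias) | +0.10 | -0.15 | – |
| κ (drift modulator) | 0.7 | 0.7 | evidence · token⁻¹ · s⁻¹ |
| λ (leak) | -1.0 | -1.0 | s⁻¹ |
| τ (non-decision time) | 0.30 | 0.30 | s |

ω and α sit at the reported group means; κ, λ, τ and β/α were calibrated
once so that the cohort reproduces the reported regime: P(equal) ≈ 0.72
in DIS and 0.30 in ADV; equal choices faster than unequal in DIS and the
reverse in ADV; overall responses faster in ADV; model sensitivity/
specificity above 83% and balanced accuracy above 89% per context.
Between-participant draws are truncated normals with small SDs (e.g. 0.03
for ω), i.e. a cohort tightly concentrated around the mean regime.

Known departures from the printed regime, accepted during calibration:
simulated unequal-choice RTs in DIS (≈1.2 s) are slower than the printed
0.91 s, and mean ADV RT (≈0.72 s) is slightly fast.  Both are direct
consequences of fixing σ = 1.4, the printed thresholds, and a grid that
keeps choices predictable enough to reach the printed accuracy bounds.

**Build-up rates.** In this regime the across-participant correlation
between the -300..-100 ms build-up rate and κ is *negative*: faster
accumulators cross earlier and spend less of the fixed pre-response
window accumulating, so their trial-averaged ramp in that window is
shallower.  The package therefore validates the slope estimator on known
ramps and the positivity of the planted ramp, and does not claim to
reproduce the positive rate-drift correlation reported for measured EEG.

## Model fitting

The likelihood of an observed (choice, RT) pair is read off a joint
choice × RT-bin histogram (bin width 0.1 s over 0..3 s) built from
`n_sim` model simulations of the trial's value difference, smoothed with
a pseudocount of 1: p = (c + 1) / (n_sim + B) for B = 60 cells.  Trials
sharing a value difference share the histogram.  Observed and simulated
timeouts are excluded.

Estimation is differential evolution (rand/1/bin), 60 population members
× 150 iterations × 3000 simulations per evaluation at full scale; the
package's scaled-down setting (30 × 60 × 500) is used for the self-
consistency and recovery studies.  One standard-normal matrix drawn per
fit supplies the simulation noise for every candidate and iteration
(common random numbers), so the objective is deterministic and the best
objective is non-increasing over iterations.  Inside the likelihood the
OU recursion is advanced in exact AR(1) blocks of 10 unit steps with
boundary checks every 10 ms — far below the 100 ms histogram resolution;
behaviour generation always uses the native 1 ms stepping.  Starting
points are parameterized as a fraction of α (bounds ±0.9) so the |β| < α
constraint is respected for every candidate.  Default bounds: α ∈ (0.1, 4],
κ ∈ [0, 2], ω ∈ [-1, 1], λ ∈ [-5, 5], τ ∈ [0.1, 0.8] s.

Model variants: `OU_full` (6 parameters × 2 contexts), `DDM` (λ ≡ 0),
`OU_shared_omega` / `OU_shared_alpha` / `OU_shared_both` (parameters tied
across contexts, fitted jointly), and `OU_order` (absorbing bounds mapped
to first/second-presented option).  BIC = k ln n - 2 lnL with n the
decided trial count.  Predicted choice for accuracy metrics is the modal
choice over 500 simulations per trial.

## Synthetic EEG

Epochs are 500 Hz, response-locked -1000..+200 ms or stimulus-locked
-500..+1000 ms.  Background noise is 1/f-amplitude (pink) noise, made
spatially coherent with a Gaussian distance kernel (scale 1 lattice
spacing) over a 128-channel equidistant hexagonal montage; labelled
parietal, centroparietal and centrofrontal sets are 7-channel hexagons.

* Response-locked epochs add w_c · EA_i(t) on parietal channels only
  (Gaussian-tapered weights), where EA_i is the trial's model-predicted
  trace (average of 500 response-locked simulated paths, flat-padded
  outside -600..-100 ms).  SNR (default 1.5) is defined on the dynamic,
  mean-removed part of the planted signal, since the flat padding carries
  no information.  The default reproduces held-out R² ≈ 0.85-0.97,
  bracketing the reported 0.82/0.84.
* Stimulus-locked epochs add, in rectangular windows, amplitudes linear
  in the standardized payoff changes: a self-payoff coefficient that
  flips sign between contexts in an early (240-360 ms) and, reversed, a
  late (440-800 ms) centroparietal window; and an other-payoff
  coefficient in the centrofrontal 320-400 ms window of the DIS context
  whose sign follows the MA/LA group and whose magnitude grows with
  ω(DIS).
* Gamma coupling: per-trial bursts at a frequency drawn from 64-79 Hz,
  Hann-tapered over -520..-460 ms (20 ms ramps), on centrofrontal and
  parietal sets.  MA participants receive a fixed 90° cross-region lag;
  LA participants an amplitude-matched burst with trial-random relative
  phase.

## EEG analyses

**Model-based EA regression.** Trials are split into even and odd halves.
Stage 1 (even): per channel, the stacked 250-sample × trial voltages are
regressed on the model EA predictions; the t statistic uses a standard
error clustered by trial, because EEG noise is strongly autocorrelated
within an epoch and only trials are exchangeable (a pooled-sample SE is
badly anticonservative under 1/f noise).  Channels survive at Bonferroni
p < 0.05 across channels and must additionally keep their averaged
waveform within one standard error of the gain-rescaled model prediction;
the band combines the across-trial SEM of the model traces with the SEM
of the averaged ERP, as both are trial averages with sampling noise.
Stage 2 (odd): the selected-channel average waveform is regressed on the
mean model trace; R² is reported.  Build-up rate is the OLS slope of the
grand-average waveform over -300..-100 ms (µV/s).

**Stimulus-locked GLM.** Each epoch is averaged in 25 windows of 40 ms
over 0..1000 ms and regressed on [1, z(ΔS), z(ΔO)] per channel × window,
with payoff changes standardized within participant × context; collinear
regressors raise an error naming the problem.

**Cluster permutation.** Point-wise t maps (paired: within-participant
differences with sign-flip permutations; independent: Welch t with
group-label permutations) are thresholded at two-sided p < 0.05.
Supra-threshold points cluster over sensor adjacency plus adjacent time
bins (adjacent 1 Hz steps for time-frequency grids), positive and
negative polarities separately; sensor-space clusters must span at least
3 distinct channels.  Cluster mass is Σt; the corrected p-value is the
exceedance fraction of the permutation distribution of the maximum
|mass| (5000 shuffles at full scale).  Calibration note: with spatially
*independent* noise the 3-channel rule makes null clusters so rare that
p-values sit at the Monte-Carlo discreteness floor and the test is very
conservative; under spatially and temporally correlated exchangeable
noise — the realistic null, and what the synthetic generator produces —
measured FWER is ≈0.045, and exact enumeration of all 924 label splits
for a 6-vs-6 contrast reproduces 0.05.

## Connectivity

Cross-spectral densities use DPSS multitapers with 8-cycle windows in
0.02 s steps and ±0.3·f frequency smoothing on a 16-100 Hz, 1 Hz grid —
a time-(full-)bandwidth product of 4.8, hence 3 tapers at every
frequency.  Cells whose window extends beyond the epoch are flagged
undefined.  For trial-wise imaginary components I_j, the debiased squared
weighted phase-lag index is

    dWPLI = [ (Σ I_j)² - Σ I_j² ] / [ (Σ |I_j|)² - Σ I_j² ],

averaged over all A×B channel pairs; it is 1 under perfectly consistent
lag, has ~zero expectation under independent phases, may be slightly
negative under the null, and is undefined (NaN) when the denominator
vanishes, e.g. for strictly zero-lag coupling.  Group contrasts run the
independent-sample cluster permutation over the 30-90 Hz × pre-response
grid with time/frequency adjacency and no channel-count rule.

## Problem sizes used in validation

The self-consistency and recovery studies use 8 synthetic participants ×
416 trials with the scaled-down estimation setting; the accuracy cohort
draws ω tightly around the group means, the recovery cohort places ω(ADV)
evenly over 0.05..0.25 (mean 0.15).  EEG validations use 64-128 channel
montages, 200-416 trials, and 10 seeded replicates for detection-rate
claims; permutation calibrations use 200 replicates of a 16-channel × 10-
bin grid with 300-500 shuffles.  These sizes are the package's validation
defaults; all are parameters of the corresponding functions.

## Limitations

* The generator plants the *model's own* signals in noise; passing tests
  show the analysis chain recovers what it is designed to recover, not
  that the model describes measured brains.
* No artifacts, filtering, re-referencing or trial rejection are
  simulated by default (an optional dropout exists in the pipeline
  configuration); real preprocessing is out of scope.
* The published alternative-offset grid and parameter bounds are not
  printed in text; the defaults here are documented stand-ins, and both
  are overridable.
* Histogram-based simulated likelihoods are biased for very small
  `n_sim`; recovery studies use ≥500 simulations per evaluation.
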