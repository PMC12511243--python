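# Methods

This note documents the models and procedures implemented in `ppgbp`,
the parameter choices that matter, and what the synthetic cohort does
and does not establish about real data.

## Synthetic population

**What it emulates.** A cohort of 56 subjects, one single-channel
finger-PPG recording each (100 samples/s) paired with one cuff reference
measurement of SBP/DBP. The AHA category mix is 30/20/25/25%
(normal/elevated/stage-1/stage-2), allocated exactly by largest-remainder
rounding; pressures are drawn uniformly inside each category's band
intersected with the population ranges SBP ∈ [97, 164] and
DBP ∈ [57, 109] mmHg. The AHA cut-offs are hard-coded (2017 convention):
normal SBP < 120 and DBP < 80; elevated SBP 120–129 and DBP < 80;
stage 1 SBP 130–139 or DBP 80–89; stage 2 SBP ≥ 140 or DBP ≥ 90, the
higher category winning. A uniform draw within bands is the least
committal distribution consistent with the category mix and the ranges;
nothing else about the BP distribution is assumed.

**Beat model.** Each cardiac period T = 60/HR contributes
s(t) = A_s·exp(−(t−0.15T)²/2w_s²) + A_d·exp(−(t−0.15T−d)²/2w_d²): a
systolic Gaussian early in the cycle plus a smaller, delayed diastolic
Gaussian. Beats are phase-locked to t = 0 (no respiratory modulation),
a 0.1 Hz sinusoidal baseline drift (amplitude 0.1 a.u.) and white
Gaussian noise (default σ = 0.02 a.u., i.e. a few percent of the pulse
amplitude) are added. The defaults give clean but not noiseless
waveforms, comparable to a well-seated transmission probe.

**Morphology–BP coupling.** Waveform parameters are smooth functions of
the subject's BP, so BP is genuinely recoverable from morphology — the
premise of the whole analysis:

| parameter | map | default range |
| --- | --- | --- |
| systolic amplitude A_s (a.u.) | 0.5 + 0.004·(SBP−97) | 0.50–0.77 |
| diastolic amplitude A_d (a.u.) | 0.2 + 0.002·(DBP−57) | 0.20–0.30 |
| diastolic delay d (s) | 0.35 − 0.0015·(DBP−57) | 0.27–0.35 |
| heart rate (bpm) | 65 + 0.15·(SBP−97) | 65–75 |
| widths w_s, w_d (s) | 0.10, 0.12 | fixed |

Multiplicative log-normal jitter (relative scale 0.02 by default, 0
disables) individualises each subject. These linear maps are a stand-in:
no quantitative morphology–BP relation is established by a single cuff
reading per subject, so the maps encode only the *direction* of
well-known physiological trends (stiffer, higher-pressure beds → larger
systolic wave, earlier and relatively larger reflected wave, higher
rate). Consequently, passing tests demonstrate that the pipeline can
recover a BP signal *of this idealized form*; they do not certify
accuracy on real cohorts, where the coupling is weaker, confounded and
subject-specific.

A corollary worth noting: because the diastolic wave overlaps the
systolic peak slightly, the per-beat maximum carries a small
DBP-dependent term (bounded by ≈0.03 a.u. for the default maps). The
generator's amplitude-vs-SBP monotonicity is therefore exact only up to
that leakage, and the tests check it with exactly that tolerance plus a
rank-correlation floor.

## Conditioning

Windows of 30 s with 25 s overlap (5 s stride): a T-second recording
yields ⌊(T−30)/5⌋+1 windows, so a 120 s recording yields **19** windows,
and a 56-subject cohort 1064 segments. (A 20-per-subject count — 1120
segments — would require 125 s of signal; the run log prints the
arithmetic on every run so the distinction is never silent.)

Each window is filtered with a Chebyshev type II band-pass designed as
`cheby2(N=4, rs=30 dB, [0.4, 8] Hz)` — the conventional reading of a
"4th-order" band-pass design call, which yields an order-8 transfer
function — applied forward-backward (`sosfiltfilt`), so the phase is
exactly zero and the effective magnitude is the squared design response
(stopband floor 10⁻³ instead of 10⁻¹·⁵). Offline processing makes
zero-phase filtering free, and it matters here: group delay would
desynchronize the three channels that the derivative features compare.

Normalization is per-window min–max to [0, 1] (constant windows map to
0.5). VPG and APG are first differences — *not* scaled by the sampling
rate, so their units are per-sample — each smoothed with a
Savitzky–Golay filter (window 9 samples, order 3; overridable). The
window/order defaults were chosen once as the smallest smoother that
suppresses difference-amplified noise without flattening the diastolic
inflections at 100 samples/s.

## Features

19 statistics × 3 channels = 57 features named `STAT(CHANNEL)`
(e.g. `KTE_IQR(PPG)`), in a fixed order. Conventions, fixed so that all
oracle tests are exact:

* central moments use the population (÷n) convention; kurtosis is
  non-excess (normal ≈ 3); skewness/kurtosis of a constant signal are
  defined as 0;
* IQR uses linear-interpolation (type-7) quantiles;
* zero-crossing rate counts strict sign flips per adjacent pair, zeros
  inheriting the previous nonzero sign. On the normalized PPG itself the
  signal is non-negative, so `ZCR(PPG)` is structurally 0 — it is kept
  for schema completeness and scores 0 in every selector;
* Shannon entropy is estimated from a 16-bin equal-width histogram over
  [min, max] (fixed bins keep values comparable across segments);
* instantaneous energy is E(n) = x(n)²; the Kaiser–Teager operator
  ψ(n) = x(n)² − x(n−1)x(n+1) is computed for interior samples only
  (length n−2, no boundary padding — padding would fabricate energy).

## Feature selection

* **F-test**: one-way ANOVA F of each feature across the four AHA
  categories — the only classes defined for this cohort; the same
  classes stratify the CV. Because the classes are target-independent,
  the F ranking is shared by SBP and DBP. Constant features score 0 with
  a warning.
* **mRMR**: greedy forward selection in the difference (MID) form,
  relevance = |Pearson r(feature, target)|, redundancy = mean |Pearson r|
  to the already-selected set. The difference form is preferred to the
  quotient form because it stays well-behaved when redundancy ≈ 0.
* **RReliefF** (regression Relief): k = 10 nearest neighbors by
  Manhattan distance on min–max-scaled features, every instance used as
  a query (m = n, hence fully deterministic), neighbor influence
  decaying as exp(−(rank/50)²) normalized to sum 1; weights combine the
  probabilities that feature differences accompany target differences,
  and lie in [−1, 1].

All ties everywhere break lexicographically by feature name, making each
ranking bitwise reproducible. Selector hyperparameters (neighbor count,
bin counts, standardization) are explicit package choices — defensible
defaults, not recovered settings of any particular prior analysis.

## Models

Seventeen variants, hyperparameters fixed (no search), features z-scored
on the training fold only:

| family | variants | key constants |
| --- | --- | --- |
| linear | simple; interactions (mains + pairwise products); robust (IRLS, Tukey bisquare c = 4.685); stepwise (forward–backward over mains + interactions, AICc, ≤15 terms) | singular designs get a 10⁻⁸ ridge jitter with a warning |
| tree | fine / medium / coarse | min leaf 4 / 12 / 36 |
| SVR | linear; quadratic; cubic; fine/medium/coarse Gaussian | C = iqr(y)/1.349, ε = iqr(y)/13.49; Gaussian kernel scale √p/4, √p, 4√p (γ = 1/scale²) |
| GPR | squared-exponential; Matérn 5/2; exponential (Matérn ½); rational quadratic | constant mean (normalized y), amplitude × kernel + white-noise term, hyperparameters by marginal-likelihood maximization (L-BFGS, single start → deterministic) |

## Evaluation protocol

Stratified K-fold CV (K = 10, strata = AHA category): rows of each
stratum are shuffled with a seeded RNG and dealt round-robin, so stratum
proportions are preserved to ±1 row per fold. **By default folds split
at the segment level**: overlapping sibling segments of one subject can
land on both sides of a split, which inflates apparent accuracy — it is
precisely the regime in which near-perfect pooled r² values arise for
flexible models. The package keeps segment-level splitting as the
default protocol and logs it prominently; passing
`group_by_subject=True` assigns whole subjects to folds for the honest
generalization estimate. Both modes share everything else.

Metrics over pooled held-out predictions (and per fold): MAE, MSE,
RMSE = √MSE, r² = 1 − MSE(model)/MSE(baseline) with the baseline
predicting the reference mean (identical to the classical coefficient of
determination; it can be negative). Bland–Altman agreement:
bias = mean(d), limits of agreement bias ± 1.96·sd(d) (sample sd), and
the exact t interval bias ± t₀.₉₇₅,ₙ₋₁·sd(d)/√n for the bias CI.

The grid (3 selectors × 17 models × 2 targets = 102 cells) shares one
fold assignment per run; per-cell failures are flagged rows, never
aborts. Best models per (selector, target) are ranked by pooled MAE.

## Problem sizes

The default test and acceptance cohorts use 56 subjects with 30–45 s
recordings (1–4 segments per subject, 56–224 rows); the full grid on a
224-row table completes in well under a minute per GPR cell, and the
windowing arithmetic of the full 120 s protocol is exercised on an
actual 120 s recording. Nothing in the implementation depends on these
sizes; `PopulationConfig(duration=120.0)` reproduces the full
1064-segment layout.

## Numerical and degenerate-input rules

* constant window → normalized to 0.5; constant feature → selector
  scores 0 (F, mRMR relevance) or ≤ informative weights (RReliefF);
* constant reference in r² → reported as missing with a warning;
* identical rows in RReliefF, constant targets in mRMR/RReliefF, strata
  smaller than K, recordings shorter than one window → explicit errors
  naming the offender;
* GPR white-noise bound reaches 10⁻¹², so the zero-noise cohort can be
  interpolated; stepwise AICc guards n − k − 1 > 0.

## Known limitations

* The synthetic morphology–BP maps are linear stand-ins; effect sizes on
  real data will differ, and results here bound the pipeline's sanity,
  not its clinical accuracy.
* The beat model omits respiratory amplitude/phase modulation, motion
  artifacts, probe-coupling drift and inter-beat variability beyond the
  per-subject jitter.
* Segment-level CV is optimistic by construction (see above); the
  subject-level mode is the honest protocol for generalization claims.
* SVR/GPR hyperparameter presets are fixed "coarse/medium/fine" grades,
  not tuned per dataset.
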