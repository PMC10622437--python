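# Methods

This note documents the statistical procedures `wmaze` implements, the
assumptions of its synthetic session generator, the numerical conventions that
are not forced by the science, and the known limitations of the methods. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Task model

A session is a sequence of trials of a T-maze delayed non-match-to-place
task. Each trial carries 11 salient event timestamps defining 10 phases;
events 1–5, 5–7 and 7–11 bound the encoding (E), maintenance (M) and
retrieval (R) periods. Mistake trials earn no second reward, so events 9 and
10 do not exist and phases 8–10 are undefined for them. Phase durations vary
trial to trial because the animal moves freely; the enforced delay makes the
maintenance period at least several seconds long.

## Synthetic session generator

The generator produces the statistical structure the analyses assume, not a
biophysical simulation.

- **Events.** Phase durations are `median × LogNormal(0, σ)` with
  `σ = sqrt(ln(1 + CV²))`, so `duration_jitter` is the coefficient of
  variation and the configured medians are the population medians exactly
  (the multiplier's median is 1). Sample sides are drawn i.i.d. and flipped
  whenever a fourth consecutive identical side would occur, reproducing the
  task's pseudo-randomization. Outcomes are Bernoulli(`p_mistake`); mistake
  trials keep their final event (end of the unrewarded choice run) so the
  trial still has a temporal extent.
- **Units.** Fractions `(f_E, f_M, f_R)` of units are tuned to the three
  periods (the remainder untuned). E/R units fire a Poisson(`burst_spikes`)
  burst uniformly within one planted phase of their period per trial.
  Maintenance units form the delay sequence: unit with rank r (of n) centers
  its burst at fraction `(r + 0.5)/n × sequence_span / maintenance_median`
  of each trial's actual delay span, so the sequence co-varies with the
  trial's duration and survives time warping. All units add a homogeneous
  Poisson background (`background_rate`, default 0.05 Hz).
- **Mistake degradation.** On mistake trials, maintenance-unit spike times
  receive additional Gaussian jitter with s.d.
  `mistake_jitter_frac × sequence_span` (default 0.25 × 7.5 s). This is a
  stand-in: the recorded phenomenon is a deterioration of the delay sequence
  on mistakes, with no generative model available, so any mechanism that
  disperses spike timing relative to the planted order would do.
- **Traces.** Spikes are binned at `rate` (default 20 Hz, the common rate of
  both recording modalities emulated) and filtered with an exact exponential
  IIR kernel (unit amplitude at the spike bin, decay `kinetics_tau`,
  default 0.5 s — a GCaMP6-like decay); Gaussian noise of s.d. `1/snr` is
  added (`snr = inf` gives noiseless traces). The binned spike counts are
  exposed unchanged as the *deconvolved* channel: spike inference from
  fluorescence is out of scope, and this channel stands in for its output.
  Real deconvolution residue (missed spikes, amplitude uncertainty,
  continuous amplitudes) is **not** modeled, so passing recovery tests shows
  the statistics behave correctly given clean deconvolution, not that
  deconvolution itself is benign.
- **Defaults.** 150 trials × 60 units per session, E/M/R fractions
  0.2/0.6/0.2 (maintenance-dominant, as in the population the pipeline was
  designed around), median phase durations (3, 1.5, 2, 1, 2.5, 5, 3, 1.5, 2,
  2) s — a ~23.5 s trial with a 5-s minimum-style delay — `p_mistake` 0.25
  (roughly one mistake per four trials), CV 0.25, SNR 5.
- **Randomness.** One seed per session, split into independent child streams
  for the event and trace stages (`numpy` `SeedSequence.spawn`), so each
  stage is reproducible in isolation.

## Alignment

ΔF/F uses `F₀` = mean fluorescence in the `baseline_window` (default 1 s)
immediately before event 5, per trial; the z-score divides by the sample
standard deviation (ddof = 1 — the convention is not dictated by the science
and is configurable in the sense that `Baseline` accepts any σ) of the same
window. A zero σ or an out-of-recording window raises rather than emitting
infinities.

Segment-wise resampling maps each phase onto
`round(median duration × rate)` bins (minimum 2) by linear interpolation on
an endpoints-inclusive grid. Linear interpolation is the minimal assumption:
it is monotone, exact on constants, and affine within each phase. Median
durations are pooled over all trials of the dataset by default (per-group
pooling is available by passing explicit targets). For mistake trials the
retrieval tail is anchored on the events that exist — the segment from event
8 to event 11 is stretched across the bins of phases 8–10 — and
`phase_valid` marks those phases invalid so that window statistics drop them
pairwise rather than imputing. Bins are half-open `[t, t + 1/rate)` in
seconds from session start.

A known wrinkle of the endpoints-inclusive grid: a phase's content occupies
`n` bins whose left edges span `(n−1)/rate` seconds, so a warp–unwarp round
trip carries a skew of up to one source sample per phase. The test suite
bounds round-trip error by this skew times the signal's derivative.

## Phase preference

For every unit and window (10 phases or 3 periods), the per-trial mean of
the deconvolved signal over the window's *original* (unwarped) time span is
compared against the pooled means of all other windows with a one-sided
(greater) Wilcoxon rank-sum test — "preferentially active" is directional.
Pooling is unweighted across windows. Significance is stored as −log₁₀(p);
preference calls threshold at p ≤ α inclusive (default α = 0.01); the
preferred window is the argmax of −log₁₀(p) with ties resolved to the
earlier window. Fully tied inputs give p = 1, not an error. Co-activity
matrices are `Bᵀ B / n_units` for the binary call matrix `B` — symmetric,
with the per-window active fraction on the diagonal.

Period-preference enrichment uses two binomial views: each period's count
against Binomial(n_units, 1/3) (one-sided), and each period pair's counts
against Binomial(count_a + count_b, 1/2) (two-sided) — the latter asks
directly whether more units prefer one period than another. P-values from
several animals combine via Fisher's method (−2Σln p ~ χ²(2k)).

## Time-resolved ROC

For a two-class trial contrast, each repetition draws `n_draw` (default 100)
trials per class — with replacement only when the class has fewer trials
(mistakes are typically scarce) — smooths each trial with a centered 3-bin
boxcar (truncated at the edges), and computes the per-bin AUC by the
Mann–Whitney identity (ties count ½). `n_rep` (default 20) repetitions give
mean ± s.e.m.; the null trace repeats the procedure with a fresh label
permutation per repetition, preserving class sizes. Per bin, real and
shuffled AUC draws are compared with a two-sided rank-sum test and the
p-values are Benjamini–Yekutieli adjusted across the bins of the analyzed
span (BY is valid under arbitrary dependence across bins).

**Known limitation.** The `n_rep` subsample AUCs are not independent
replicates: they cluster around the dataset-level AUC, which under a global
null is itself as variable as a single shuffle draw (s.d. ≈ 1/√(6N) for N
trials per class). Treating the draws as independent makes the per-bin
rank-sum anticonservative at the dataset level, so the frequency of
BY-significant bins on label-exchangeable sessions exceeds α and grows as
sessions shrink — the calibration test in the acceptance suite measures this
directly at 150-trial sessions and documents the measured rate rather than
assuming nominal control. Conclusions from `sig_mask` should therefore rest
on effect sizes (`auc_mean` far from 0.5 over contiguous spans), not on
isolated significant bins. A dataset-level permutation test of the observed
AUC against many full shuffles would be calibrated, but is a different
procedure and is deliberately not substituted here.

## Orderability (BDO / ABDO)

Within the analysis span (default: the maintenance period; any phase set is
accepted), each unit–trial signal is baseline-subtracted (per-unit, per-trial
minimum by default, guaranteeing nonnegativity; a percentile baseline is
available — which scope the original analysis used is not determinable, so
both are exposed) and normalized to p(t) = x(t)/Σx(t). The center of mass
μ = Σ t·p(t) uses 1-based bin coordinates. Silent unit–trials (Σx = 0) are
flagged invalid for that trial only. For a pair (i, j), f_ij is the fraction
of co-valid, tie-free trials with μ_j > μ_i — exact ties are excluded from
the count, which preserves f_ij + f_ji = 1 over counted trials (ties have
measure zero for floating-point centers but occur in integer-valued toys) —
and BDO_ij = 2f_ij − 1. Pairs with no co-valid tie-free trial are
*unorderable*: stored as 0 with a mask and excluded from
ABDO = mean |BDO_ij| over orderable off-diagonal pairs, so NaN never
propagates. Units are ordered by descending row-mean BDO (earliest first).

The permutation test shuffles unit labels independently within every trial
(centers and validity move together), recomputes ABDO `n_perm` times
(default 1000), and reports the add-one estimator
p = (1 + #{null ≥ observed})/(1 + n_perm), which is never zero. Because
label shuffles preserve each trial's multiset of centers, the null ABDO
concentrates near its combinatorial expectation (~√(π/2)/√n_trials per pair
scale) rather than zero; planted sequences exceed every draw at realistic
noise.

## Sequence train/test validation

Correct trials are split into random disjoint halves (train takes the odd
extra). Per unit, the peak time is the argmax (earliest bin on ties) of the
trial-averaged signal over the span, in seconds on the resampled timebase;
units with an identically zero mean trace are flagged and excluded from
shift statistics. Max-normalization of the mean trace (used for the exported
sorted matrices) does not move the argmax. Shifts are |peak − peak_train|;
medians and 75th percentiles use linear interpolation between order
statistics (the convention must be fixed somewhere; this is numpy's
default). Test and mistake shifts are compared per unit with a two-sided
Wilcoxon signed-rank test dropping zero differences; all-zero differences
give p = 1 by definition.

## L2 population decoding

Per bin, the Euclidean norm over units of the difference between the two
conditions' mean population vectors. The permutation null re-draws the class
assignment (class sizes preserved) `n_perm` times; per-bin
p = (1 + #{null ≥ observed})/(1 + n_perm), reported as −log₁₀(p) with **no**
multiple-testing correction — the trace is a descriptive significance
profile, and readers should expect ~α·n_bins bins above −log₁₀(α) under the
null. Unit means are not standardized by default (the deconvolved scale
carries information); a per-unit z-scoring flag exists for populations with
heterogeneous amplitude scales. Per-unit predictive counts use a two-sided
rank-sum on window means at α = 0.01 and a window-level exact binomial tail
P(X ≥ count | n_units, α), i.e. a null in which every unit is independently
"predictive" with probability α.

## Problem sizes in the test suite

Calibration and recovery checks choose session sizes that make their
statistical claims sharp while keeping the suite fast: the phase-preference
null uses 200 sessions of 16 units × 40 trials with *equal* median phase
durations (2 s each) and 6-Hz background so that window means are
exchangeable across windows and quasi-continuous — the regime in which a
rank test's nominal α is meaningful; the ABDO null uses 200 sessions of 12
units × 25 trials with 300 permutations (the add-one p can reach 0.01 from
~250 permutations up); the ROC null uses 200 bulk sessions of 150 trials;
recovery uses one 60-unit × 150-trial planted session plus 100 seeds of
30 × 60 sessions for the mistake-shift comparison. The acceptance script's
analytic targets need only 10–20 trials of constructed centers.

## Limitations

- The generator's unit classes are disjoint and its tuning stationary;
  mixed-selectivity or drifting units are not emulated.
- The deconvolved channel is exact; statistics' robustness to deconvolution
  error is untested here.
- The ROC shuffle comparison is anticonservative at the dataset level (see
  above); its masks are descriptive.
- Mistake-trial structure beyond sequence-timing dispersal (e.g., altered
  rates, behavioral covariates) is not modeled.
- Rank-based tests on low-rate count data are conservative through tie
  discreteness; the calibration regime documents where the nominal α holds.
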