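# wmaze

Trial-aligned analysis of neural population activity in a T-maze
delayed non-match-to-place (DNMTP) working-memory task.

In this task a freely moving mouse samples one maze arm, holds its location in
working memory across an enforced delay, and is rewarded for choosing the
opposite arm. Eleven salient events per trial (run starts, junction turns,
rewards, licking bouts) define 10 trial phases grouped into three periods —
encoding (events 1–5), maintenance (5–7) and retrieval (7–11). Because the
animal moves freely, every phase has a different duration on every trial, and
the central preprocessing problem is registering fluorescence traces (bulk
fiber photometry or single-cell miniscope recordings) onto a common per-trial
timebase before any population statistic can be computed.

`wmaze` provides, as a tested and reusable library plus CLI:

- **Synthetic sessions** (`wmaze.synthetic`) with the full trial grammar,
  lognormal phase-duration jitter, phase-tuned unit subpopulations, a planted
  delay-period sequence, mistake-trial degradation, and GCaMP-like traces
  (spikes ⊛ exponential kernel + noise) with a ground-truth deconvolved
  channel — so every downstream stage is testable without recorded data.
- **Event-anchored alignment** (`wmaze.align`): per-trial
  ΔF/F = (F − F₀)/F₀ and z-score (F − F₀)/σ using a 1-s pre-maintenance
  baseline, then segment-wise linear resampling of each phase onto
  `round(median duration × rate)` bins so phase boundaries coincide across
  trials.
- **Phase preference** (`wmaze.phasepref`): per unit and time window, a
  one-sided Wilcoxon rank-sum test of that window's per-trial mean activity
  against all other windows pooled, reported as −log₁₀(p), binarized at
  p ≤ 0.01, summarized as symmetric co-activity matrices, with binomial
  enrichment tests and Fisher combination across animals.
- **Time-resolved ROC decoding** (`wmaze.roc`): per-bin AUC between trial
  types from repeated 100-trial subsamples, compared against label-shuffled
  draws with Benjamini–Yekutieli FDR across bins.
- **Orderability** (`wmaze.orderability`): the Binary Directed Orderability
  index. Per trial, each unit's activity is reduced to the center of mass
  μ = Σ t·p(t) of its normalized signal p(t) = x(t)/Σx(t); for a pair (i, j),
  f_ij is the fraction of trials with μ_j > μ_i and

  &nbsp;&nbsp;&nbsp;&nbsp;BDO_ij = 2·f_ij − 1 ∈ [−1, 1],&nbsp;&nbsp;
  ABDO = mean |BDO| over off-diagonal pairs,

  tested against a null that shuffles unit labels independently within every
  trial.
- **Sequence validation** (`wmaze.sequence`): split correct trials into
  train/test halves, order units by training peak times, and measure per-unit
  peak shifts on held-out and mistake trials (median, 75th percentile, paired
  Wilcoxon signed-rank).
- **Population decoding** (`wmaze.decoding`): per-bin Euclidean (L2) distance
  between condition-averaged population vectors with a label-permutation
  null, and per-unit predictive counts with a binomial significance model.

## Worked example

```python
import numpy as np
from wmaze import align, orderability, phasepref
from wmaze.synthetic import SessionConfig, simulate_session
from wmaze.task import PERIOD_NAMES

cfg = SessionConfig(n_trials=60, n_units=30, fractions=(0.2, 0.6, 0.2), seed=1)
events, traces, truth = simulate_session(cfg)

# which task period does each unit prefer?
means = phasepref.window_mean_activity(events, truth.deconv, "periods")
table = phasepref.phase_significance(means, window_kind="periods")
counts = {p: int((table.preferred_window == i).sum())
          for i, p in enumerate(PERIOD_NAMES)}
print("preferred-period counts:", counts)
print("M-enrichment p:",
      phasepref.period_preference_test(counts, cfg.n_units)["per_period"]["M"])

# is delay activity sequentially ordered?
deconv = align.build_aligned_tensor(events, truth.deconv, "deconvolved")
sl = deconv.period_slice("M")
centers = orderability.trial_centers(deconv.values[deconv.is_correct][:, :, sl])
res = orderability.abdo_permutation_test(centers, np.random.default_rng(0),
                                         n_perm=300)
print(f"ABDO = {res.abdo:.3f}, permutation p = {res.perm_p:.4f}")
```

prints

```
preferred-period counts: {'E': 6, 'M': 18, 'R': 6}
M-enrichment p: 0.0024578342775849553
ABDO = 0.629, permutation p = 0.0033
```

The session planted 20/60/20% of units tuned to encoding/maintenance/
retrieval; the rank-sum preference map recovers those fractions exactly, the
binomial test confirms maintenance enrichment, and the delay sequence yields
an ABDO far above every label-shuffle draw (the permutation p is at its
add-one floor of 1/301).

The same stages run from the shell:

```bash
wmaze simulate --seed 1 --out session/
wmaze align --events session/events.csv --traces session/traces.h5 \
      --signal deconvolved --dataset deconv --out session/aligned.h5
wmaze bdo --aligned session/aligned.h5 --span M --nperm 1000 --seed 0 --out bdo/
wmaze run --config run.yaml --seed 1 --out results/   # full pipeline
```

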