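"""Transient population decoding of behavioral conditions.

Two complementary views of condition encoding: (1) the per-bin Euclidean (L2)
distance between condition-averaged population vectors, tested against a
condition-label permutation null and reported as -log10(p) over resampled
time; (2) per-unit predictive counts — units whose window means separate the
two conditions by rank-sum test — with a window-level binomial significance
model in which each unit is independently significant with probability alpha
under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats


@dataclass
class DecodingTrace:
    """Per-bin L2 condition separation with its permutation p-values."""

    t: np.ndarray
    l2: np.ndarray
    p: np.ndarray
    neg_log10_p: np.ndarray
    null_l2: np.ndarray = field(repr=False, default=None)


def condition_mean(values: np.ndarray, labels: np.ndarray, condition) -> np.ndarray:
    """Units x bins mean over a condition's trials."""
    labels = np.asarray(labels)
    mask = labels == condition
    if not mask.any():
        raise ValueError(f"no trial with condition {condition!r}")
    return np.asarray(values, dtype=float)[mask].mean(axis=0)


def l2_trace(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    """Per-bin Euclidean norm over units of the condition-mean difference."""
    mean_a = np.atleast_2d(np.asarray(mean_a, dtype=float))
    mean_b = np.atleast_2d(np.asarray(mean_b, dtype=float))
    if mean_a.shape != mean_b.shape:
        raise ValueError("condition means must have matching shapes")
    return np.sqrt(((mean_a - mean_b) ** 2).sum(axis=0))


def l2_permutation_test(values: np.ndarray, labels: np.ndarray,
                        rng: np.random.Generator, n_perm: int = 1000,
                        rate: float = 20.0, t_offset: float = 0.0,
                        standardize: bool = False,
                        chunk: int = 100) -> DecodingTrace:
    """L2 condition separation per bin against a label-permutation null.

    ``values`` is trials x units x bins. Permutations preserve class sizes;
    per-bin p uses the add-one estimator. ``standardize`` optionally z-scores
    each unit (over all trials and bins) before differencing. No multiple-
    testing correction is applied — the trace is reported as raw -log10(p).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes!r}")
    if standardize:
        mean = values.mean(axis=(0, 2), keepdims=True)
        sd = values.std(axis=(0, 2), keepdims=True)
        values = (values - mean) / np.where(sd == 0, 1.0, sd)

    n_trials, n_units, n_bins = values.shape
    mask_a = labels == classes[0]
    na = int(mask_a.sum())
    flat = values.reshape(n_trials, -1)

    def _l2_for(mask: np.ndarray) -> np.ndarray:
        diff = flat[mask].mean(axis=0) - flat[~mask].mean(axis=0)
        return np.sqrt((diff.reshape(n_units, n_bins) ** 2).sum(axis=0))

    obs = _l2_for(mask_a)
    exceed = np.zeros(n_bins)
    null = np.empty((n_perm, n_bins))
    for start in range(0, n_perm, chunk):
        for p in range(start, min(start + chunk, n_perm)):
            perm_mask = np.zeros(n_trials, dtype=bool)
            perm_mask[rng.choice(n_trials, size=na, replace=False)] = True
            null[p] = _l2_for(perm_mask)
    exceed = (null >= obs).sum(axis=0)
    pvals = (1 + exceed) / (1 + n_perm)
    return DecodingTrace(t=t_offset + np.arange(n_bins) / rate, l2=obs, p=pvals,
                         neg_log10_p=-np.log10(pvals), null_l2=null)


def predictive_unit_fraction(window_means: np.ndarray, labels: np.ndarray,
                             alpha: float = 0.01) -> dict:
    """Fraction of units predictive of a two-class contrast, per window.

    ``window_means`` is units x windows x trials (NaN for missing windows).
    Per unit and window, a two-sided rank-sum test compares the two classes'
    per-trial means; units with p <= alpha count as predictive. The
    window-level p is the exact binomial tail P(X >= count | n_units, alpha).
    """
    window_means = np.asarray(window_means, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes!r}")
    mask_a = labels == classes[0]
    if mask_a.sum() < 2 or (~mask_a).sum() < 2:
        raise ValueError("need at least 2 trials per class")
    n_units, n_win, _ = window_means.shape
    p_unit = np.ones((n_units, n_win))
    for u in range(n_units):
        for w in range(n_win):
            x = window_means[u, w, mask_a]
            y = window_means[u, w, ~mask_a]
            x = x[np.isfinite(x)]
            y = y[np.isfinite(y)]
            if x.size < 2 or y.size < 2:
                continue
            pooled = np.concatenate([x, y])
            if np.all(pooled == pooled[0]):  # fully tied, no evidence
                continue
            p_unit[u, w] = scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided").pvalue
    predictive = p_unit <= alpha
    counts = predictive.sum(axis=0)
    p_window = np.array([scipy.stats.binomtest(int(c), n_units, alpha,
                                               alternative="greater").pvalue
                         for c in counts])
    return {"fraction": counts / n_units, "count": counts,
            "p_window": p_window, "p_unit": p_unit}
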