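"""Train/test validation of delay-period activity sequences.

Correct trials are split into random halves; units are ordered by the peak
times of their trial-averaged, max-normalized signal on the training half, and
the same order is applied to held-out correct trials and to mistake trials.
The per-unit absolute peak-time shift relative to training quantifies how well
the sequence generalizes; test and mistake shift distributions are compared
with a paired two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from wmaze.align import AlignedTensor


@dataclass
class SequenceResult:
    """Train/test/mistake sequence comparison for one analysis span."""

    order: np.ndarray
    peak_train: np.ndarray
    peak_test: np.ndarray
    peak_mistake: np.ndarray | None
    shift_test: np.ndarray
    shift_mistake: np.ndarray | None
    median_shift_test: float
    p75_shift_test: float
    median_shift_mistake: float | None
    p75_shift_mistake: float | None
    p_compare: float | None
    unit_ok: np.ndarray = field(repr=False, default=None)


def split_trials(trial_idx: np.ndarray, rng: np.random.Generator):
    """Random disjoint halves of the given trials; train takes the odd extra."""
    trial_idx = np.asarray(trial_idx)
    if trial_idx.size < 2:
        raise ValueError("need at least 2 trials to split")
    perm = rng.permutation(trial_idx)
    n_train = (trial_idx.size + 1) // 2
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def peak_times(values: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit peak time (s) of the trial-averaged, max-normalized signal.

    ``values`` is trials x units x bins over the analysis span. Units whose
    mean trace is identically zero are flagged invalid (NaN peak). Ties in the
    maximum resolve to the earliest bin.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[2] == 0:
        raise ValueError("empty analysis span")
    mean = values.mean(axis=0)  # units x bins
    peak_val = mean.max(axis=1)
    ok = peak_val != 0
    # max-normalization does not move the argmax; kept for parity with how
    # the sorted sequence matrices are displayed/exported
    peaks = np.where(ok, mean.argmax(axis=1) / rate, np.nan)
    return peaks, ok


def shift_statistics(peaks_train: np.ndarray, peaks_other: np.ndarray):
    """Per-unit |peak - peak_train| in seconds with median and 75th percentile.

    Quantiles use linear interpolation between order statistics. Units invalid
    (NaN) in either condition are excluded.
    """
    peaks_train = np.asarray(peaks_train, dtype=float)
    peaks_other = np.asarray(peaks_other, dtype=float)
    if peaks_train.shape != peaks_other.shape:
        raise ValueError("unit sets must match")
    shifts = np.abs(peaks_other - peaks_train)
    finite = shifts[np.isfinite(shifts)]
    if finite.size == 0:
        raise ValueError("no unit valid in both conditions")
    return shifts, float(np.percentile(finite, 50)), float(np.percentile(finite, 75))


def compare_shift_distributions(shift_test: np.ndarray,
                                shift_mistake: np.ndarray) -> float:
    """Paired two-sided Wilcoxon signed-rank p on per-unit shifts.

    Zero differences are dropped (standard convention); all-zero differences
    give p = 1 by definition.
    """
    shift_test = np.asarray(shift_test, dtype=float)
    shift_mistake = np.asarray(shift_mistake, dtype=float)
    ok = np.isfinite(shift_test) & np.isfinite(shift_mistake)
    d = shift_mistake[ok] - shift_test[ok]
    if np.all(d == 0):
        return 1.0
    return float(scipy.stats.wilcoxon(d, zero_method="wilcox",
                                      alternative="two-sided").pvalue)


def sequence_analysis(tensor: AlignedTensor, rng: np.random.Generator,
                      span="M") -> SequenceResult:
    """Full train/test(/mistake) peak-shift analysis on an aligned tensor.

    ``span`` is a period name, 1-based phase, or (lo, hi) phase pair; the
    maintenance period is the default. Mistake statistics are None when the
    session has no mistake trials.
    """
    sl = tensor.span_slice(span)
    correct = np.flatnonzero(tensor.is_correct)
    train, test = split_trials(correct, rng)
    vals = tensor.values[:, :, sl]

    peaks_train, ok_train = peak_times(vals[train], tensor.rate)
    peaks_test, ok_test = peak_times(vals[test], tensor.rate)
    shift_test, med_t, p75_t = shift_statistics(peaks_train, peaks_test)

    mistakes = np.flatnonzero(~tensor.is_correct)
    if mistakes.size:
        peaks_mis, ok_mis = peak_times(vals[mistakes], tensor.rate)
        shift_mis, med_m, p75_m = shift_statistics(peaks_train, peaks_mis)
        p_cmp = compare_shift_distributions(shift_test, shift_mis)
        unit_ok = ok_train & ok_test & ok_mis
    else:
        peaks_mis = shift_mis = med_m = p75_m = p_cmp = None
        unit_ok = ok_train & ok_test

    order = np.argsort(np.where(np.isfinite(peaks_train), peaks_train, np.inf),
                       kind="stable")
    return SequenceResult(order=order, peak_train=peaks_train,
                          peak_test=peaks_test, peak_mistake=peaks_mis,
                          shift_test=shift_test, shift_mistake=shift_mis,
                          median_shift_test=med_t, p75_shift_test=p75_t,
                          median_shift_mistake=med_m, p75_shift_mistake=p75_m,
                          p_compare=p_cmp, unit_ok=unit_ok)
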