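"""Per-unit task-phase preference statistics and their aggregation.

For every unit, the mean deconvolved activity in each time window (the 10
trial phases or the 3 task periods) is compared, across correct trials,
against the pooled means of all other windows with a one-sided Wilcoxon
rank-sum test. Significance maps are reported as -log10(p), binarized at
p <= 0.01 into preference calls, summarized as symmetric co-activity fraction
matrices, and combined across animals with Fisher's method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import scipy.stats

from wmaze.align import TraceBlock
from wmaze.task import (
    N_PHASES,
    PERIOD_EVENTS,
    PERIOD_NAMES,
    TrialEventTable,
)

WINDOW_KINDS = ("phases", "periods")


@dataclass
class PhaseSignificanceTable:
    """Units x windows map of -log10(p) phase-preference values.

    ``sig`` holds -log10 of the one-sided rank-sum p-values; ``binary`` the
    preference calls at threshold ``alpha`` (inclusive, p <= alpha);
    ``preferred_window`` the window of maximal significance per unit (ties
    broken toward the earlier window).
    """

    sig: np.ndarray = field(repr=False)
    binary: np.ndarray = field(repr=False)
    preferred_window: np.ndarray
    alpha: float = 0.01
    window_kind: str = "phases"


def window_spans(event_row: np.ndarray, kind: str) -> list[tuple[float, float]]:
    """Time spans of the requested windows for one trial; NaN bounds if absent."""
    if kind == "phases":
        return [(event_row[k], event_row[k + 1]) for k in range(N_PHASES)]
    if kind == "periods":
        return [(event_row[PERIOD_EVENTS[p][0] - 1], event_row[PERIOD_EVENTS[p][1] - 1])
                for p in PERIOD_NAMES]
    raise ValueError(f"kind must be one of {WINDOW_KINDS}")


def window_mean_activity(events: TrialEventTable, traces: TraceBlock,
                         windows: str = "phases",
                         trials: np.ndarray | None = None) -> np.ndarray:
    """Mean activity per unit, window and trial over original time spans.

    Operates on the deconvolved (non-resampled) signal; windows absent in a
    trial (phases 8-10 on mistakes) are NaN. ``trials`` is a boolean mask or
    index array selecting trials (default: correct trials only, matching how
    the preference statistics are defined).
    """
    if traces.kind != "deconvolved":
        raise ValueError("window means are defined on deconvolved traces")
    ev = events.event_array()
    if trials is None:
        trials = events.is_correct
    idx = np.flatnonzero(trials) if np.asarray(trials).dtype == bool \
        else np.asarray(trials, dtype=int)
    n_win = N_PHASES if windows == "phases" else len(PERIOD_NAMES)
    out = np.full((traces.n_units, n_win, len(idx)), np.nan)
    for col, k in enumerate(idx):
        for w, (lo, hi) in enumerate(window_spans(ev[k], windows)):
            if np.isnan(lo) or np.isnan(hi):
                continue
            sl = traces.window_slice(lo, hi)
            if sl.stop > sl.start:
                out[:, w, col] = traces.values[:, sl].mean(axis=1)
    return out


def rank_sum_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided (greater) Wilcoxon rank-sum p-value of x against y."""
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        return 1.0
    if np.all(x == x[0]) and np.all(y == x[0]):  # fully tied, no evidence
        return 1.0
    return float(scipy.stats.mannwhitneyu(x, y, alternative="greater").pvalue)


def phase_significance(means: np.ndarray, alpha: float = 0.01,
                       window_kind: str = "phases") -> PhaseSignificanceTable:
    """Rank-sum preference map from a units x windows x trials mean table.

    Each window's per-trial means are tested (one-sided, greater) against the
    pooled per-trial means of all other windows. Missing per-trial windows are
    dropped pairwise, not imputed.
    """
    n_units, n_win, _ = means.shape
    if means.shape[2] < 2:
        raise ValueError("need at least 2 trials")
    sig = np.zeros((n_units, n_win))
    for u in range(n_units):
        for w in range(n_win):
            others = np.delete(np.arange(n_win), w)
            p = rank_sum_greater(means[u, w], means[u, others].ravel())
            sig[u, w] = -np.log10(max(p, np.finfo(float).tiny))
    binary = binarize(sig, alpha)
    preferred = np.argmax(sig, axis=1)  # argmax takes the earliest tie
    return PhaseSignificanceTable(sig=sig, binary=binary, preferred_window=preferred,
                                  alpha=alpha, window_kind=window_kind)


def binarize(sig: np.ndarray, alpha: float = 0.01) -> np.ndarray:
    """Threshold a -log10(p) map at p <= alpha (inclusive)."""
    return sig >= -np.log10(alpha) - 1e-12


def coactivity_matrix(binary: np.ndarray) -> np.ndarray:
    """Symmetric windows x windows matrix of co-active unit fractions.

    Entry (a, b) is the fraction of units significant in both windows a and b;
    the diagonal is the fraction significant in each window alone.
    """
    binary = np.asarray(binary, dtype=float)
    n_units = binary.shape[0]
    if n_units == 0:
        raise ValueError("co-activity undefined for zero units")
    return binary.T @ binary / n_units


def period_preference_test(counts, n_units: int) -> dict:
    """Binomial tests of period-preference enrichment.

    ``counts`` maps period name -> number of units preferring it (must sum to
    ``n_units``). Returns per-period one-sided p-values against the null that
    each of the three periods is equally likely (P(X >= count | n, 1/3)), and
    per-pair two-sided p-values restricted to each pair's units
    (Binomial(count_a + count_b, 1/2)).
    """
    if n_units <= 0:
        raise ValueError("n_units must be positive")
    counts = dict(counts)
    if sum(counts.values()) != n_units:
        raise ValueError("counts must sum to n_units")
    per_period = {
        p: scipy.stats.binomtest(counts[p], n_units, 1 / 3,
                                 alternative="greater").pvalue
        for p in counts
    }
    per_pair = {}
    names = list(counts)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            n_pair = counts[a] + counts[b]
            if n_pair == 0:
                per_pair[(a, b)] = 1.0
            else:
                per_pair[(a, b)] = scipy.stats.binomtest(
                    counts[a], n_pair, 0.5, alternative="two-sided").pvalue
    return {"per_period": per_period, "per_pair": per_pair}


def binomial_tail(count: int, n: int, p: float) -> float:
    """Exact upper binomial tail P(X >= count | n, p) by direct summation."""
    return float(sum(comb(n, k) * p**k * (1 - p) ** (n - k)
                     for k in range(count, n + 1)))


def fisher_combine(pvals) -> float:
    """Fisher's method: X2 = -2 sum(ln p) against chi-square with 2k d.o.f."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any(pvals <= 0) or np.any(pvals > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, p = scipy.stats.combine_pvalues(pvals, method="fisher")
    return float(p)


def bulk_activity_ratio(fractions: dict, mean_activities: dict,
                        numerator: str = "M", denominator: str = "E") -> float:
    """Fold change in population ('bulk') activity between two periods.

    The bulk signal contributed by a period scales with (fraction of units
    preferring it) x (their mean per-unit activity); the ratio of these
    products estimates e.g. how much larger the summed maintenance signal is
    than the encoding signal.
    """
    num = fractions[numerator] * mean_activities[numerator]
    den = fractions[denominator] * mean_activities[denominator]
    return num / den
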