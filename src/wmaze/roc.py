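"""Time-resolved ROC/AUC discrimination of trial types with a shuffle null.

For a two-class contrast (correct vs. mistake, drug vs. vehicle, left vs.
right), trials of each class are repeatedly subsampled, traces smoothed with a
centered 3-bin moving window, and a per-bin AUC computed via the Mann-Whitney
identity. The same procedure on label-shuffled trials gives the null trace;
real and shuffled AUC draws are compared per bin with a two-sided rank-sum
test under Benjamini-Yekutieli FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests


@dataclass
class AUCTrace:
    """Per-bin AUC of a trial-type classification and its shuffle null."""

    t: np.ndarray
    auc_mean: np.ndarray
    auc_sem: np.ndarray
    shuffle_mean: np.ndarray
    shuffle_sem: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    sig_mask: np.ndarray
    auc_draws: np.ndarray = field(repr=False, default=None)
    shuffle_draws: np.ndarray = field(repr=False, default=None)
    alpha: float = 0.01


def auc(a: np.ndarray, b: np.ndarray) -> float:
    """Probability that a random member of ``b`` exceeds one of ``a``.

    Ties count one half (Mann-Whitney identity); 0.5 means chance-level
    separation, 1.0 perfect ``b > a`` separation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ranks = scipy.stats.rankdata(np.concatenate([a, b]))
    u_b = ranks[a.size:].sum() - b.size * (b.size + 1) / 2
    return float(u_b / (a.size * b.size))


def _auc_per_bin(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized per-column AUC for (trials x bins) groups ``a`` and ``b``."""
    na, nb = a.shape[0], b.shape[0]
    pooled = np.concatenate([a, b], axis=0)
    ranks = scipy.stats.rankdata(pooled, axis=0)
    u_b = ranks[na:].sum(axis=0) - nb * (nb + 1) / 2
    return u_b / (na * nb)


def moving_average(x: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered boxcar along the last axis with truncated edge windows."""
    if window <= 1:
        return np.asarray(x, dtype=float)
    x = np.asarray(x, dtype=float)
    half = window // 2
    c = np.cumsum(np.concatenate([np.zeros(x.shape[:-1] + (1,)), x], axis=-1), axis=-1)
    n = x.shape[-1]
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (c[..., hi] - c[..., lo]) / (hi - lo)


def _draw(rng: np.random.Generator, idx: np.ndarray, n_draw: int) -> np.ndarray:
    """Subsample class trials; with replacement only when the class is scarce."""
    return rng.choice(idx, size=n_draw, replace=idx.size < n_draw)


def time_resolved_auc(signals: np.ndarray, labels: np.ndarray,
                      rng: np.random.Generator, n_draw: int = 100,
                      n_rep: int = 20, window: int = 3, alpha: float = 0.01,
                      rate: float = 20.0, t_offset: float = 0.0) -> AUCTrace:
    """Per-bin ROC classification of two trial types on an aligned signal.

    ``signals`` is trials x bins (bulk or population-summed activity on the
    common timebase); ``labels`` names each trial's class. Per repetition,
    ``n_draw`` trials per class are drawn (with replacement only when a class
    has fewer trials), smoothed with a centered ``window``-bin boxcar, and the
    per-bin AUC computed; label-shuffled repetitions give the null trace. Raw
    and adjusted p-values come from :func:`compare_to_shuffle` over the bins
    supplied, so restrict ``signals`` to the analyzed period beforehand.
    """
    signals = np.asarray(signals, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes!r}")
    idx_a = np.flatnonzero(labels == classes[0])
    idx_b = np.flatnonzero(labels == classes[1])
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("each class needs at least one trial")

    smooth = moving_average(signals, window)
    n_bins = smooth.shape[1]
    real = np.empty((n_rep, n_bins))
    null = np.empty((n_rep, n_bins))
    for r in range(n_rep):
        a = smooth[_draw(rng, idx_a, n_draw)]
        b = smooth[_draw(rng, idx_b, n_draw)]
        real[r] = _auc_per_bin(a, b)
        # fresh label permutation per repetition, class sizes preserved
        perm = rng.permutation(labels.size)
        pa = perm[:idx_a.size]
        pb = perm[idx_a.size:]
        null[r] = _auc_per_bin(smooth[_draw(rng, pa, n_draw)],
                               smooth[_draw(rng, pb, n_draw)])

    p_raw, p_adj, sig = compare_to_shuffle(real, null, alpha)
    sem = lambda x: x.std(axis=0, ddof=1) / np.sqrt(x.shape[0]) if x.shape[0] > 1 \
        else np.zeros(x.shape[1])
    return AUCTrace(t=t_offset + np.arange(n_bins) / rate,
                    auc_mean=real.mean(axis=0), auc_sem=sem(real),
                    shuffle_mean=null.mean(axis=0), shuffle_sem=sem(null),
                    p_raw=p_raw, p_adj=p_adj, sig_mask=sig,
                    auc_draws=real, shuffle_draws=null, alpha=alpha)


def compare_to_shuffle(real_draws: np.ndarray, shuffle_draws: np.ndarray,
                       alpha: float = 0.01):
    """Per-bin two-sided rank-sum of real vs. shuffled AUC draws, BY-adjusted.

    Returns ``(p_raw, p_adj, sig_mask)``; the Benjamini-Yekutieli step-up is
    applied across all bins passed in, and the mask is ``p_adj <= alpha``.
    """
    real_draws = np.asarray(real_draws, dtype=float)
    shuffle_draws = np.asarray(shuffle_draws, dtype=float)
    if real_draws.shape != shuffle_draws.shape:
        raise ValueError("draw matrices must have equal shapes")
    if real_draws.shape[0] < 2:
        raise ValueError("need at least 2 draws per bin")
    p_raw = scipy.stats.ranksums(real_draws, shuffle_draws, axis=0).pvalue
    p_raw = np.atleast_1d(np.asarray(p_raw, dtype=float))
    _, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_by")
    return p_raw, p_adj, p_adj <= alpha


def benjamini_yekutieli(p_raw: np.ndarray) -> np.ndarray:
    """BY-adjusted p-values (step-up with harmonic-sum factor), clipped at 1."""
    _, p_adj, _, _ = multipletests(np.asarray(p_raw, dtype=float), method="fdr_by")
    return p_adj
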