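"""Binary Directed Orderability (BDO) of neuronal pairs across trials.

Sequential activation is scored without assuming fixed latencies: per trial,
each unit's activity is reduced to the center of mass of its normalized
(baseline-subtracted) signal; for a pair (i, j), ``f_ij`` is the fraction of
trials in which unit j's center falls later than unit i's, and
``BDO_ij = 2 f_ij - 1`` is +1 when j consistently follows i, -1 when it leads,
and 0 when no consistent order exists. The population summary ABDO (mean
absolute off-diagonal BDO) is tested against a null that shuffles unit labels
independently within every trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TrialCenterMatrix:
    """Trials x units center-of-mass times on the analyzed span (bin units).

    ``valid`` marks units with nonzero signal in a given trial; silent units
    are invalid for that trial only and are skipped pair-wise downstream.
    """

    mu: np.ndarray = field(repr=False)
    valid: np.ndarray = field(repr=False)

    @property
    def n_trials(self) -> int:
        return self.mu.shape[0]

    @property
    def n_units(self) -> int:
        return self.mu.shape[1]


@dataclass
class BDOMatrix:
    """Antisymmetric units x units orderability matrix and its summary.

    ``bdo[i, j] = -bdo[j, i]`` with zero diagonal; pairs with no co-valid,
    tie-free trial are unorderable (``orderable`` False, bdo stored as 0 and
    excluded from ABDO). ``order`` sorts units by descending mean BDO, i.e.
    earliest units first.
    """

    bdo: np.ndarray = field(repr=False)
    orderable: np.ndarray = field(repr=False)
    abdo: float
    order: np.ndarray
    perm_p: float | None = None
    null_abdo: np.ndarray = field(repr=False, default=None)


def activity_probability(x: np.ndarray) -> np.ndarray | None:
    """Normalize a nonnegative signal to a per-bin activity probability.

    Returns ``x / sum(x)``, or ``None`` for an all-zero (silent) signal —
    silence is a validity flag, not an error.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("signal must be nonnegative after baseline subtraction")
    total = x.sum()
    if total <= 0:
        return None
    return x / total


def center_of_mass(p: np.ndarray) -> float:
    """Center of mass sum_t t*p(t) with 1-based bin coordinates."""
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("p must sum to 1")
    return float(np.sum(np.arange(1, p.size + 1) * p))


def trial_centers(values: np.ndarray, baseline: str = "min",
                  percentile: float = 10.0) -> TrialCenterMatrix:
    """Per-trial activity centers of mass from a trials x units x bins array.

    ``baseline`` is subtracted per unit and trial before normalizing:
    ``'min'`` (default, guarantees nonnegativity), ``'percentile'`` (clipped
    at zero), or ``'none'`` for already-nonnegative deconvolved signals.
    """
    values = np.asarray(values, dtype=float)
    if baseline == "min":
        x = values - values.min(axis=2, keepdims=True)
    elif baseline == "percentile":
        x = np.clip(values - np.percentile(values, percentile, axis=2, keepdims=True),
                    0.0, None)
    elif baseline == "none":
        if np.any(values < 0):
            raise ValueError("baseline='none' requires nonnegative signals")
        x = values
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    total = x.sum(axis=2)
    valid = total > 0
    t = np.arange(1, values.shape[2] + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = (x * t).sum(axis=2) / total
    mu[~valid] = np.nan
    return TrialCenterMatrix(mu=mu, valid=valid)


def pairwise_fraction(centers: TrialCenterMatrix, i: int, j: int) -> float:
    """Fraction of co-valid, tie-free trials in which unit j is later than i."""
    both = centers.valid[:, i] & centers.valid[:, j]
    mi = centers.mu[both, i]
    mj = centers.mu[both, j]
    untied = mi != mj
    if untied.sum() == 0:
        return np.nan
    return float(np.mean(mj[untied] > mi[untied]))


def _bdo_arrays(mu: np.ndarray, valid: np.ndarray):
    """Vectorized BDO over all pairs; returns (bdo, orderable)."""
    covalid = valid[:, :, None] & valid[:, None, :]
    with np.errstate(invalid="ignore"):
        later = (mu[:, None, :] > mu[:, :, None]) & covalid  # [k, i, j]
        tied = (mu[:, None, :] == mu[:, :, None]) & covalid
    n_later = later.sum(axis=0)
    n_valid = covalid.sum(axis=0) - tied.sum(axis=0)
    orderable = n_valid > 0
    np.fill_diagonal(orderable, False)
    bdo = np.zeros(orderable.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = n_later / n_valid
    bdo[orderable] = 2 * f[orderable] - 1
    return bdo, orderable


def bdo_matrix(centers: TrialCenterMatrix) -> BDOMatrix:
    """Full BDO matrix, ABDO summary, and the BDO-sorted unit order.

    Ties in per-trial centers are excluded from a pair's trial count, which
    preserves ``f_ij + f_ji = 1`` over the counted trials.
    """
    if centers.n_units < 2:
        raise ValueError("need at least 2 units")
    bdo, orderable = _bdo_arrays(centers.mu, centers.valid)
    ab = abdo(bdo, orderable)
    n_orderable = orderable.sum(axis=1)
    row_mean = np.divide((bdo * orderable).sum(axis=1),
                         np.maximum(n_orderable, 1))
    order = np.argsort(-row_mean, kind="stable")
    return BDOMatrix(bdo=bdo, orderable=orderable, abdo=ab, order=order)


def abdo(bdo: np.ndarray, orderable: np.ndarray | None = None) -> float:
    """Mean absolute off-diagonal BDO over orderable pairs."""
    bdo = np.asarray(bdo, dtype=float)
    if orderable is None:
        orderable = ~np.eye(bdo.shape[0], dtype=bool)
    if not orderable.any():
        return 0.0
    return float(np.abs(bdo[orderable]).mean())


def abdo_permutation_test(centers: TrialCenterMatrix,
                          rng: np.random.Generator,
                          n_perm: int = 1000,
                          chunk: int = 50) -> BDOMatrix:
    """ABDO significance against a per-trial unit-label shuffle null.

    Each permutation independently shuffles unit labels within every trial
    (centers and their validity move together), recomputes ABDO, and the
    p-value uses the add-one estimator ``(1 + #{null >= observed}) /
    (1 + n_perm)`` so it is never zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if centers.n_units < 2 or centers.n_trials < 2:
        raise ValueError("need at least 2 units and 2 trials")
    result = bdo_matrix(centers)
    null = np.empty(n_perm)
    n_trials, n_units = centers.mu.shape
    base = np.tile(np.arange(n_units), (n_trials, 1))
    for start in range(0, n_perm, chunk):
        for p in range(start, min(start + chunk, n_perm)):
            idx = rng.permuted(base, axis=1)
            mu_p = np.take_along_axis(centers.mu, idx, axis=1)
            valid_p = np.take_along_axis(centers.valid, idx, axis=1)
            b, o = _bdo_arrays(mu_p, valid_p)
            null[p] = abdo(b, o)
    result.perm_p = float((1 + np.sum(null >= result.abdo)) / (1 + n_perm))
    result.null_abdo = null
    return result
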