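"""Event-anchored preprocessing and segment-wise temporal resampling.

Freely moving behavior makes every trial phase a different length, so traces
from different trials cannot be averaged directly. The registration used here
interpolates each inter-event segment of a (dF/F- or z-transformed) trace onto
a fixed number of bins — ``round(median phase duration * rate)`` — so that
phase boundaries land on identical bin indices in every trial and activity can
be averaged and compared across trials, sessions and animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from wmaze.errors import (
    ConstantBaselineError,
    DegenerateBaselineError,
    MissingPhaseError,
    RateMismatchError,
    ShortSegmentError,
)
from wmaze.task import N_EVENTS, N_PHASES, PERIOD_PHASES, TrialEventTable

TRACE_KINDS = ("raw", "dff", "zscore", "deconvolved")


@dataclass
class TraceBlock:
    """Units x time activity matrix at a fixed sampling rate.

    ``values`` may be raw fluorescence, dF/F (percent), per-trial z-scores or
    deconvolved activity, as recorded in ``kind``. Bulk photometry is a single
    unit (``modality='photometry'``); miniscope data are
    ``modality='cellular'``. Sample ``i`` covers time
    ``[t0 + i/rate, t0 + (i+1)/rate)``.
    """

    values: np.ndarray = field(repr=False)
    rate: float
    t0: float = 0.0
    modality: str = "cellular"
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.kind not in TRACE_KINDS:
            raise ValueError(f"kind must be one of {TRACE_KINDS}")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Left edge of every sample bin, in seconds."""
        return self.t0 + np.arange(self.values.shape[1]) / self.rate

    def sample_index(self, t: float) -> int:
        """Index of the bin containing time ``t``."""
        return int(np.floor((t - self.t0) * self.rate))

    def window_slice(self, t_lo: float, t_hi: float) -> slice:
        """Slice of samples whose bin start lies in ``[t_lo, t_hi)``."""
        lo = int(np.ceil((t_lo - self.t0) * self.rate - 1e-9))
        hi = int(np.ceil((t_hi - self.t0) * self.rate - 1e-9))
        return slice(max(lo, 0), max(hi, 0))


@dataclass
class Baseline:
    """Per-trial baseline statistics from the pre-maintenance window.

    ``F0`` and ``sigma`` are per-unit arrays (length 1 for photometry):
    the mean and sample standard deviation (ddof=1) of the fluorescence in the
    ``window``-second span immediately before event 5.
    """

    F0: np.ndarray
    sigma: np.ndarray
    window: float = 1.0

    def __post_init__(self) -> None:
        self.F0 = np.atleast_1d(np.asarray(self.F0, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if self.window <= 0:
            raise ValueError("baseline window must be positive")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be nonnegative")


@dataclass
class AlignedTensor:
    """Trials x units x common-timebase activity after segment-wise resampling.

    ``boundaries`` holds the 11 event positions as bin indices on the common
    timebase (identical for every trial); phase ``k`` (1-based) occupies bins
    ``[boundaries[k-1], boundaries[k])``. ``phase_valid`` marks, per trial,
    the phases whose bounding events exist (phases 8-10 are invalid on
    mistake trials; their bins contain the retrieval tail stretched from
    events 8->11).
    """

    values: np.ndarray = field(repr=False)
    boundaries: np.ndarray
    median_durations: np.ndarray
    rate: float
    sides: np.ndarray
    outcomes: np.ndarray
    phase_valid: np.ndarray = field(repr=False)
    signal_kind: str = "zscore"

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    @property
    def is_correct(self) -> np.ndarray:
        return self.outcomes == "correct"

    def phase_slice(self, phase: int) -> slice:
        """Bin slice of a 1-based phase index."""
        if not 1 <= phase <= N_PHASES:
            raise ValueError(f"phase must be in 1..{N_PHASES}")
        return slice(int(self.boundaries[phase - 1]), int(self.boundaries[phase]))

    def period_slice(self, period: str) -> slice:
        """Bin slice of a task period ('E', 'M' or 'R')."""
        phases = PERIOD_PHASES[period]
        return slice(int(self.boundaries[phases[0] - 1]),
                     int(self.boundaries[phases[-1]]))

    def span_slice(self, span) -> slice:
        """Resolve a span argument (period name, phase int, or (lo, hi) phases)."""
        if isinstance(span, str):
            return self.period_slice(span)
        if isinstance(span, int):
            return self.phase_slice(span)
        lo, hi = span
        return slice(int(self.boundaries[lo - 1]), int(self.boundaries[hi]))


def compute_dff(trace: TraceBlock, event_times: np.ndarray,
                baseline_window: float = 1.0) -> TraceBlock:
    """Percent fluorescence change (F - F0) / F0 * 100 for one trial.

    ``F0`` is the per-unit mean over the ``baseline_window`` seconds before
    event 5 of this trial. The whole block is transformed with that trial's
    baseline; downstream resampling only reads the event 1 -> 11 span.
    """
    base = trial_baseline(trace, event_times, baseline_window)
    if np.any(base.F0 == 0):
        raise DegenerateBaselineError("baseline F0 is zero")
    values = (trace.values - base.F0[:, None]) / base.F0[:, None] * 100.0
    return replace(trace, values=values, kind="dff")


def zscore_trial(trace: TraceBlock, baseline: Baseline) -> TraceBlock:
    """Per-trial z-score (F - F0) / sigma using the trial's baseline statistics."""
    if np.any(baseline.sigma == 0):
        raise ConstantBaselineError("baseline standard deviation is zero")
    values = (trace.values - baseline.F0[:, None]) / baseline.sigma[:, None]
    return replace(trace, values=values, kind="zscore")


def trial_baseline(trace: TraceBlock, event_times: np.ndarray,
                   window: float = 1.0) -> Baseline:
    """Baseline mean and sample s.d. in the ``window`` s before event 5."""
    e5 = float(event_times[4])
    sl = trace.window_slice(e5 - window, e5)
    seg = trace.values[:, sl]
    if seg.shape[1] < 2:
        raise DegenerateBaselineError("baseline window outside recording")
    return Baseline(F0=seg.mean(axis=1), sigma=seg.std(axis=1, ddof=1),
                    window=window)


def median_phase_durations(events: TrialEventTable) -> np.ndarray:
    """Median duration of each of the 10 phases over trials possessing it."""
    dur = events.phase_durations()
    out = np.empty(N_PHASES)
    for k in range(N_PHASES):
        col = dur[:, k]
        col = col[np.isfinite(col)]
        if col.size == 0:
            raise MissingPhaseError(f"no trial has phase {k + 1}")
        out[k] = np.median(col)
    return out


def phase_bin_counts(targets: np.ndarray, rate: float) -> np.ndarray:
    """Bins per phase on the common timebase: round(target * rate), min 2."""
    targets = np.asarray(targets, dtype=float)
    if np.any(targets <= 0):
        raise ValueError("target durations must be positive")
    return np.maximum(2, np.round(targets * rate).astype(int))


def phase_boundaries(targets: np.ndarray, rate: float) -> np.ndarray:
    """Event positions (11 bin indices) on the common timebase."""
    nb = phase_bin_counts(targets, rate)
    return np.concatenate([[0], np.cumsum(nb)])


def _segment_grid(t_lo: float, t_hi: float, n_bins: int) -> np.ndarray:
    """Endpoints-inclusive interpolation grid for one phase segment."""
    return np.linspace(t_lo, t_hi, n_bins)


def resample_trial(trace: TraceBlock, event_times: np.ndarray,
                   targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Warp one trial onto the common timebase by segment-wise resampling.

    Each phase segment is linearly interpolated onto an endpoints-inclusive
    grid of ``round(target * rate)`` points, so the mapping within a phase is
    affine and monotone and constants are preserved exactly. Mistake trials
    (events 9/10 absent) have the retrieval tail from event 8 to event 11
    stretched over the bins of phases 8-10.

    Returns ``(resampled, boundaries)`` where ``resampled`` is
    ``units x total_bins`` and ``boundaries`` are the shared event bin indices.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.shape[0] != N_EVENTS:
        raise ValueError(f"expected {N_EVENTS} event times")
    bounds = phase_boundaries(targets, trace.rate)
    total = int(bounds[-1])
    out = np.empty((trace.n_units, total))

    # split into maximal runs of present events; a run of missing events
    # collapses its phases into one stretched segment
    segs: list[tuple[float, float, int, int]] = []  # (t_lo, t_hi, bin_lo, bin_hi)
    k = 0
    while k < N_PHASES:
        lo_ev = event_times[k]
        if np.isnan(lo_ev):
            raise ValueError(f"event {k + 1} missing; cannot anchor phase {k + 1}")
        j = k + 1
        while j < N_EVENTS - 1 and np.isnan(event_times[j]):
            j += 1
        hi_ev = event_times[j]
        if np.isnan(hi_ev):
            raise ValueError("event 11 missing; trial has no end anchor")
        segs.append((lo_ev, hi_ev, int(bounds[k]), int(bounds[j])))
        k = j

    n_samples = trace.values.shape[1]
    for t_lo, t_hi, b_lo, b_hi in segs:
        n_src = int(np.floor((t_hi - trace.t0) * trace.rate)) \
            - int(np.ceil((t_lo - trace.t0) * trace.rate)) + 1
        if n_src < 2:
            raise ShortSegmentError(
                f"phase segment [{t_lo:.3f}, {t_hi:.3f}] s covers fewer than 2 samples")
        grid = _segment_grid(t_lo, t_hi, b_hi - b_lo)
        # linear interpolation with weights shared across units
        pos = (grid - trace.t0) * trace.rate
        idx = np.clip(np.floor(pos).astype(int), 0, n_samples - 2)
        w = np.clip(pos - idx, 0.0, 1.0)
        v = trace.values
        out[:, b_lo:b_hi] = v[:, idx] * (1.0 - w) + v[:, idx + 1] * w
    return out, bounds


def build_aligned_tensor(events: TrialEventTable, trace: TraceBlock,
                         signal_kind: str = "zscore",
                         baseline_window: float = 1.0,
                         targets: np.ndarray | None = None) -> AlignedTensor:
    """Stack per-trial resampled traces into a trials x units x bins tensor.

    ``signal_kind`` selects the per-trial transform applied before warping:
    ``'zscore'`` and ``'dff'`` use the 1-s (by default) pre-maintenance
    baseline of each trial; ``'raw'`` / ``'deconvolved'`` use the trace as-is
    (the given ``trace.kind`` must match). Median phase durations are pooled
    over all trials unless explicit ``targets`` are given.
    """
    if signal_kind in ("raw", "deconvolved") and trace.kind != signal_kind:
        raise RateMismatchError(
            f"trace kind {trace.kind!r} does not match requested {signal_kind!r}")
    if targets is None:
        targets = median_phase_durations(events)
    targets = np.asarray(targets, dtype=float)
    bounds = phase_boundaries(targets, trace.rate)

    ev = events.event_array()
    tensors = []
    for row in ev:
        if signal_kind == "dff":
            block = compute_dff(trace, row, baseline_window)
        elif signal_kind == "zscore":
            block = zscore_trial(trace, trial_baseline(trace, row, baseline_window))
        else:
            block = trace
        resampled, b = resample_trial(block, row, targets)
        assert np.array_equal(b, bounds)
        tensors.append(resampled)

    phase_valid = np.isfinite(ev[:, :-1]) & np.isfinite(ev[:, 1:])
    return AlignedTensor(values=np.stack(tensors), boundaries=bounds,
                         median_durations=targets, rate=trace.rate,
                         sides=events.sides, outcomes=events.outcomes,
                         phase_valid=phase_valid, signal_kind=signal_kind)
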