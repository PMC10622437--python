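"""Synthetic T-maze sessions with planted task structure.

The generator emulates the statistical structure the downstream analyses
assume: the 11-event trial grammar with variable (lognormal-jittered) phase
durations, pseudo-randomized sample sides with no more than three consecutive
runs to the same arm, correct/mistake outcomes, subpopulations of units tuned
to encoding/maintenance/retrieval phases, a delay-period sequence tiling the
maintenance span, and GCaMP-like fluorescence (spikes convolved with an
exponential kernel plus Gaussian noise). A noiseless binned spike-count
channel stands in for deconvolved activity, so spike inference itself stays
out of scope while every analysis that consumes deconvolved traces remains
testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.signal

from wmaze.align import TraceBlock
from wmaze.errors import ConfigError
from wmaze.task import EVENT_COLUMNS, N_PHASES, PERIOD_PHASES, TrialEventTable

# Default median phase durations (s): sample run to T-junction, turn-to-reward,
# licking, end-of-licking to turn-back, return to start box, delay wait in the
# start box (>= 5 s enforced by the task), choice run, turn-to-reward, licking,
# end of choice run.
DEFAULT_MEDIAN_DURATIONS = (3.0, 1.5, 2.0, 1.0, 2.5, 5.0, 3.0, 1.5, 2.0, 2.0)


@dataclass
class SessionConfig:
    """Parameters of one synthetic session.

    The defaults mirror the recorded sessions the analyses were designed for:
    20 Hz sampling, tens of units per field of view, ~25% mistake trials, and
    an enforced delay of at least 5 s.
    """

    n_trials: int = 150
    n_units: int = 60
    rate: float = 20.0
    median_phase_durations: tuple = DEFAULT_MEDIAN_DURATIONS
    #: coefficient of variation of the multiplicative lognormal duration jitter
    duration_jitter: float = 0.25
    #: fractions of units tuned to the E / M / R periods (rest untuned)
    fractions: tuple = (0.2, 0.6, 0.2)
    #: seconds of the maintenance period covered by the planted sequence
    sequence_span: float = 7.5
    #: transient amplitude / noise s.d. ratio (np.inf for noiseless traces)
    snr: float = 5.0
    p_mistake: float = 0.25
    p_left_sample: float = 0.5
    #: fluorescence decay time constant of the exponential kernel (s)
    kinetics_tau: float = 0.5
    seed: int = 0
    #: fixed inter-trial interval (s)
    inter_trial_interval: float = 10.0
    #: homogeneous background spike rate for every unit (Hz)
    background_rate: float = 0.05
    #: mean number of spikes per tuned burst (Poisson)
    burst_spikes: float = 3.0
    #: s.d. of sequence-unit spike times around their planted center (s)
    sequence_width: float = 0.2
    #: mistake-trial timing jitter for maintenance units, fraction of sequence_span
    mistake_jitter_frac: float = 0.25

    def validate(self) -> None:
        if self.n_trials < 1 or self.n_units < 1:
            raise ConfigError("n_trials and n_units must be positive")
        if self.rate <= 0:
            raise ConfigError("rate must be positive")
        if len(self.median_phase_durations) != N_PHASES:
            raise ConfigError(f"median_phase_durations must have {N_PHASES} entries")
        if any(d <= 0 for d in self.median_phase_durations):
            raise ConfigError("all phase durations must be positive")
        if self.duration_jitter < 0:
            raise ConfigError("duration_jitter must be >= 0")
        if len(self.fractions) != 3 or any(f < 0 for f in self.fractions):
            raise ConfigError("fractions must be three nonnegative proportions")
        if sum(self.fractions) > 1 + 1e-12:
            raise ConfigError("fractions must sum to <= 1")
        if not 0 <= self.p_mistake <= 1 or not 0 <= self.p_left_sample <= 1:
            raise ConfigError("probabilities must lie in [0, 1]")
        if self.sequence_span <= 0 or self.kinetics_tau <= 0:
            raise ConfigError("sequence_span and kinetics_tau must be positive")
        if self.snr <= 0:
            raise ConfigError("snr must be positive (np.inf for noiseless)")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic session, for parameter-recovery tests.

    Attributes
    ----------
    unit_class : array of {'E', 'M', 'R', 'untuned'} per unit.
    planted_peak_phase : 1-based phase index per unit (-1 for untuned).
    planted_sequence_rank : ordinal position of each maintenance unit within
        the planted delay sequence (-1 for non-maintenance units).
    spikes : DataFrame with columns ``unit``, ``trial``, ``time`` (s).
    deconv : noiseless binned spike counts, the stand-in for spike inference.
    """

    unit_class: np.ndarray
    planted_peak_phase: np.ndarray
    planted_sequence_rank: np.ndarray
    spikes: pd.DataFrame = field(repr=False)
    deconv: TraceBlock = field(repr=False)


def generate_events(cfg: SessionConfig, rng: np.random.Generator) -> TrialEventTable:
    """Draw a trial event table under the task grammar.

    Phase durations are ``median * lognormal`` with unit median, so the
    configured medians are the population medians regardless of jitter.
    Sample sides are pseudo-randomized with runs capped at three, mistakes are
    Bernoulli(``p_mistake``), and events 9/10 are omitted on mistakes (the
    trial still ends at event 11 after the unrewarded choice run).
    """
    cfg.validate()
    medians = np.asarray(cfg.median_phase_durations, dtype=float)
    sigma = np.sqrt(np.log1p(cfg.duration_jitter**2))

    sides: list[str] = []
    for _ in range(cfg.n_trials):
        cand = "left" if rng.random() < cfg.p_left_sample else "right"
        if len(sides) >= 3 and sides[-1] == sides[-2] == sides[-3] == cand:
            cand = "right" if cand == "left" else "left"
        sides.append(cand)

    outcomes = np.where(rng.random(cfg.n_trials) < cfg.p_mistake, "mistake", "correct")

    rows = []
    t = 1.0  # leave room for a pre-trial baseline window
    for k in range(cfg.n_trials):
        if cfg.duration_jitter == 0:
            durations = medians.copy()
        else:
            durations = medians * rng.lognormal(mean=0.0, sigma=sigma, size=N_PHASES)
        ev = np.empty(len(EVENT_COLUMNS))
        ev[0] = t
        ev[1:] = t + np.cumsum(durations)
        end = ev[-1]
        if outcomes[k] == "mistake":
            ev[8] = np.nan
            ev[9] = np.nan
        rows.append({"trial_id": k, "side": sides[k], "outcome": outcomes[k],
                     **dict(zip(EVENT_COLUMNS, ev))})
        t = end + cfg.inter_trial_interval
    return TrialEventTable(pd.DataFrame(rows))


def _assign_units(cfg: SessionConfig, rng: np.random.Generator):
    """Unit classes, planted phases and sequence ranks."""
    n = cfg.n_units
    n_e, n_m, n_r = (int(round(f * n)) for f in cfg.fractions)
    while n_e + n_m + n_r > n:  # rounding overshoot
        n_m -= 1
    classes = np.array(["E"] * n_e + ["M"] * n_m + ["R"] * n_r
                       + ["untuned"] * (n - n_e - n_m - n_r))
    rng.shuffle(classes)

    peak_phase = np.full(n, -1, dtype=int)
    seq_rank = np.full(n, -1, dtype=int)
    m_units = np.flatnonzero(classes == "M")
    seq_rank[m_units] = rng.permutation(len(m_units))

    medians = np.asarray(cfg.median_phase_durations, dtype=float)
    d5, d6 = medians[4], medians[5]
    maint = d5 + d6
    for u in np.flatnonzero(classes == "E"):
        peak_phase[u] = rng.choice(PERIOD_PHASES["E"])
    for u in np.flatnonzero(classes == "R"):
        peak_phase[u] = rng.choice(PERIOD_PHASES["R"])
    for u in m_units:
        frac = _sequence_fraction(seq_rank[u], len(m_units), cfg.sequence_span, maint)
        peak_phase[u] = 5 if frac * maint < d5 else 6
    return classes, peak_phase, seq_rank


def _sequence_fraction(rank: int, n_seq: int, span: float, maint_total: float) -> float:
    """Fractional position of a sequence unit's center within the maintenance period."""
    return min(1.0, (rank + 0.5) / n_seq * span / maint_total)


def generate_traces(events: TrialEventTable, cfg: SessionConfig,
                    rng: np.random.Generator) -> tuple[TraceBlock, GroundTruth]:
    """Emit GCaMP-like traces with planted phase tuning and delay sequences.

    Tuned E/R units fire a Poisson burst uniformly within their planted phase
    on every trial where that phase exists. Maintenance units fire around a
    center placed at a fixed fraction of each trial's actual maintenance span,
    ordered by their planted sequence rank; on mistake trials those spike
    times receive extra Gaussian jitter (s.d. ``mistake_jitter_frac *
    sequence_span``), degrading the sequence. All units also carry a low
    homogeneous background rate. Spikes are binned at ``cfg.rate``, convolved
    with a causal exponential kernel of time constant ``kinetics_tau`` (unit
    amplitude at the spike bin) and corrupted with Gaussian noise of s.d.
    ``1 / snr``.
    """
    cfg.validate()
    classes, peak_phase, seq_rank = _assign_units(cfg, rng)
    ev = events.event_array()
    n_trials = len(events)
    medians = np.asarray(cfg.median_phase_durations, dtype=float)
    maint_total = medians[4] + medians[5]
    n_seq = max(1, int((classes == "M").sum()))
    mistake_sd = cfg.mistake_jitter_frac * cfg.sequence_span

    session_end = np.nanmax(ev) + 2.0
    t1, t11 = ev[:, 0], ev[:, 10]
    parts: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []

    def _expand(counts: np.ndarray, units: np.ndarray):
        """Flatten a (len(units), n_trials) count matrix to spike indices."""
        flat = counts.ravel()
        total = int(flat.sum())
        u_idx = np.repeat(np.repeat(units, n_trials), flat)
        k_idx = np.repeat(np.tile(np.arange(n_trials), len(units)), flat)
        return total, u_idx, k_idx

    # background activity across every trial, every unit
    n_bg = rng.poisson(cfg.background_rate * (t11 - t1),
                       size=(cfg.n_units, n_trials))
    total, u_idx, k_idx = _expand(n_bg, np.arange(cfg.n_units))
    times = t1[k_idx] + rng.random(total) * (t11 - t1)[k_idx]
    parts.append((u_idx, k_idx, times))

    # phase-tuned bursts, uniform within each unit's planted phase
    er_units = np.flatnonzero((classes == "E") | (classes == "R"))
    if er_units.size:
        ph = peak_phase[er_units]  # 1-based; phase ph spans events ph..ph+1
        lo = ev[:, ph - 1].T  # (n_er, n_trials)
        hi = ev[:, ph].T
        ok = np.isfinite(lo) & np.isfinite(hi)
        n_burst = rng.poisson(cfg.burst_spikes, size=lo.shape) * ok
        total, u_idx, k_idx = _expand(n_burst, er_units)
        lo_f = np.repeat(lo.ravel(), n_burst.ravel())
        hi_f = np.repeat(hi.ravel(), n_burst.ravel())
        parts.append((u_idx, k_idx, lo_f + rng.random(total) * (hi_f - lo_f)))

    # maintenance sequence: centers at fixed fractions of each trial's delay
    m_units = np.flatnonzero(classes == "M")
    if m_units.size:
        fracs = np.array([_sequence_fraction(seq_rank[u], n_seq,
                                             cfg.sequence_span, maint_total)
                          for u in m_units])
        e5, e7 = ev[:, 4], ev[:, 6]
        centers = e5[None, :] + fracs[:, None] * (e7 - e5)[None, :]
        n_burst = rng.poisson(cfg.burst_spikes, size=centers.shape)
        total, u_idx, k_idx = _expand(n_burst, m_units)
        c_f = np.repeat(centers.ravel(), n_burst.ravel())
        burst = rng.normal(c_f, cfg.sequence_width)
        bad = events.outcomes[k_idx] == "mistake"
        burst[bad] += rng.normal(0.0, mistake_sd, size=int(bad.sum()))
        parts.append((u_idx, k_idx, np.clip(burst, t1[k_idx], t11[k_idx])))

    spikes = pd.DataFrame({
        "unit": np.concatenate([p[0] for p in parts]).astype(int),
        "trial": np.concatenate([p[1] for p in parts]).astype(int),
        "time": np.concatenate([p[2] for p in parts]).astype(float),
    })

    n_bins = int(np.ceil(session_end * cfg.rate))
    counts = np.zeros((cfg.n_units, n_bins))
    bins = np.floor(spikes["time"].to_numpy() * cfg.rate).astype(int)
    np.add.at(counts, (spikes["unit"].to_numpy(), np.clip(bins, 0, n_bins - 1)), 1.0)

    # exponential kernel as an exact IIR filter: y[t] = x[t] + decay * y[t-1]
    decay = np.exp(-1.0 / (cfg.kinetics_tau * cfg.rate))
    clean = scipy.signal.lfilter([1.0], [1.0, -decay], counts, axis=1)
    noise_sd = 0.0 if np.isinf(cfg.snr) else 1.0 / cfg.snr
    values = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd else clean

    traces = TraceBlock(values=values, rate=cfg.rate, t0=0.0,
                        modality="cellular", kind="raw")
    deconv = TraceBlock(values=counts, rate=cfg.rate, t0=0.0,
                        modality="cellular", kind="deconvolved")
    truth = GroundTruth(unit_class=classes, planted_peak_phase=peak_phase,
                        planted_sequence_rank=seq_rank, spikes=spikes, deconv=deconv)
    return traces, truth


def bulk_from_cells(traces: TraceBlock) -> TraceBlock:
    """Sum cellular traces into a single photometry-like bulk signal."""
    if traces.values.shape[0] == 0:
        raise ValueError("cannot sum an empty unit set")
    return replace(traces, values=traces.values.sum(axis=0, keepdims=True),
                   modality="photometry")


def simulate_session(cfg: SessionConfig) -> tuple[TrialEventTable, TraceBlock, GroundTruth]:
    """Generate one full session from a single seed.

    The seed is split into independent child streams for the event and trace
    stages, so either stage is reproducible on its own.
    """
    ss = np.random.SeedSequence(cfg.seed)
    ev_rng, tr_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    events = generate_events(cfg, ev_rng)
    traces, truth = generate_traces(events, cfg, tr_rng)
    return events, traces, truth
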