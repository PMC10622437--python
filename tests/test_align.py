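"""Preprocessing and segment-wise resampling contracts."""

import numpy as np
import pytest

from wmaze import align
from wmaze.align import (
    AlignedTensor,
    Baseline,
    TraceBlock,
    build_aligned_tensor,
    compute_dff,
    median_phase_durations,
    phase_boundaries,
    resample_trial,
    trial_baseline,
    zscore_trial,
)
from wmaze.errors import (
    ConstantBaselineError,
    DegenerateBaselineError,
    MissingPhaseError,
    ShortSegmentError,
)
from wmaze.synthetic import SessionConfig, generate_events, simulate_session


def _toy_events(durations, t1=2.0):
    """Event-time row from 10 phase durations."""
    ev = np.empty(11)
    ev[0] = t1
    ev[1:] = t1 + np.cumsum(durations)
    return ev


def _toy_trace(values, rate=10.0):
    return TraceBlock(values=values, rate=rate)


class TestDff:
    def test_constant_trace_is_zero(self):
        ev = _toy_events([1.0] * 10)
        trace = _toy_trace(np.full((1, 200), 3.0))
        out = compute_dff(trace, ev)
        np.testing.assert_allclose(out.values, 0.0)
        assert out.kind == "dff"

    def test_fifty_percent_change(self):
        # baseline samples equal 2, the rest 3 -> dF/F = 50%
        ev = _toy_events([1.0] * 10, t1=2.0)
        vals = np.full((1, 200), 3.0)
        e5 = ev[4]
        trace = _toy_trace(vals)
        sl = trace.window_slice(e5 - 1.0, e5)
        vals[0, sl] = 2.0
        out = compute_dff(trace, ev)
        assert out.values[0, -1] == pytest.approx(50.0)

    def test_matches_elementwise_formula_oracle(self, rng):
        ev = _toy_events([1.0] * 10)
        vals = rng.uniform(1.0, 2.0, size=(2, 200))
        trace = _toy_trace(vals)
        base = trial_baseline(trace, ev, 1.0)
        out = compute_dff(trace, ev)
        oracle = (vals - base.F0[:, None]) / base.F0[:, None] * 100.0
        np.testing.assert_array_equal(out.values, oracle)

    def test_zero_baseline_rejected(self):
        ev = _toy_events([1.0] * 10)
        vals = np.ones((1, 200))
        trace = _toy_trace(vals)
        sl = trace.window_slice(ev[4] - 1.0, ev[4])
        vals[0, sl] = 0.0
        with pytest.raises(DegenerateBaselineError):
            compute_dff(_toy_trace(vals), ev)

    def test_baseline_outside_recording_rejected(self):
        ev = _toy_events([1.0] * 10, t1=0.0)  # event 5 at t=4, but trace starts at 30
        trace = TraceBlock(values=np.ones((1, 100)), rate=10.0, t0=30.0)
        with pytest.raises(DegenerateBaselineError):
            compute_dff(trace, ev)


class TestZscore:
    def test_trace_at_baseline_is_zero(self):
        base = Baseline(F0=[2.0], sigma=[0.7])
        out = zscore_trial(_toy_trace(np.full((1, 50), 2.0)), base)
        np.testing.assert_allclose(out.values, 0.0)

    def test_hand_computed_value(self):
        # baseline samples {1, 3}: F0 = 2, sample s.d. (ddof=1) = sqrt(2)
        base = Baseline(F0=[2.0], sigma=[np.sqrt(2.0)])
        out = zscore_trial(_toy_trace(np.full((1, 4), 4.0)), base)
        np.testing.assert_allclose(out.values, np.sqrt(2.0))

    def test_baseline_uses_sample_std(self):
        ev = _toy_events([1.0] * 10, t1=2.0)
        vals = np.ones((1, 200))
        trace = _toy_trace(vals)
        sl = trace.window_slice(ev[4] - 1.0, ev[4])
        assert sl.stop - sl.start == 10
        vals[0, sl.start:sl.start + 2] = [1.0, 3.0]
        base = trial_baseline(_toy_trace(vals), ev, 1.0)
        seg = vals[0, sl]
        assert base.sigma[0] == pytest.approx(np.std(seg, ddof=1))

    def test_affine_invariance(self, rng):
        ev = _toy_events([1.0] * 10)
        vals = rng.normal(size=(1, 200))
        t1 = _toy_trace(vals)
        t2 = _toy_trace(3.5 * vals + 7.0)
        z1 = zscore_trial(t1, trial_baseline(t1, ev))
        z2 = zscore_trial(t2, trial_baseline(t2, ev))
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-9)

    def test_zero_sigma_rejected(self):
        with pytest.raises(ConstantBaselineError):
            zscore_trial(_toy_trace(np.ones((1, 10))), Baseline(F0=[1.0], sigma=[0.0]))


class TestMedianDurations:
    def test_identical_trials(self, rng):
        cfg = SessionConfig(n_trials=5, n_units=1, duration_jitter=0.0,
                            p_mistake=0.0, seed=0)
        events = generate_events(cfg, rng)
        np.testing.assert_allclose(median_phase_durations(events),
                                    cfg.median_phase_durations)

    def test_matches_sort_and_pick_oracle(self, rng):
        cfg = SessionConfig(n_trials=31, n_units=1, duration_jitter=0.5, seed=0)
        events = generate_events(cfg, rng)
        med = median_phase_durations(events)
        dur = events.phase_durations()
        for k in range(10):
            col = np.sort(dur[~np.isnan(dur[:, k]), k])
            assert med[k] == pytest.approx(col[(len(col) - 1) // 2]
                                           if len(col) % 2 else
                                           0.5 * (col[len(col) // 2 - 1]
                                                  + col[len(col) // 2]))

    def test_median_of_1_2_9_is_2(self):
        import pandas as pd

        from wmaze.task import EVENT_COLUMNS, TrialEventTable
        rows = []
        for i, d in enumerate([1.0, 2.0, 9.0]):
            ev = _toy_events([d] + [1.0] * 9, t1=2.0)
            rows.append({"trial_id": i, "side": "left", "outcome": "correct",
                         **dict(zip(EVENT_COLUMNS, ev))})
        med = median_phase_durations(TrialEventTable(pd.DataFrame(rows)))
        assert med[0] == 2.0


class TestResample:
    def test_five_samples_to_three_bins(self):
        # one 'phase': samples [0,1,2,3,4] at 1 Hz resampled to 3 bins
        trace = TraceBlock(values=np.arange(5.0), rate=1.0)
        ev = np.concatenate([[0.0, 4.0], np.full(9, np.nan)])
        # use a single-phase call via the grid helper invariants instead:
        grid_vals, bounds = None, None
        # emulate through resample_trial with 10 phases is clumsy; check the
        # documented endpoint-inclusive linear rule directly on phase 1
        from wmaze.align import _segment_grid
        grid = _segment_grid(0.0, 4.0, 3)
        out = np.interp(grid, trace.times, trace.values[0])
        np.testing.assert_allclose(out, [0.0, 2.0, 4.0])

    def test_identity_warp_and_constants(self):
        cfg = SessionConfig(n_trials=1, n_units=1, duration_jitter=0.0,
                            p_mistake=0.0, seed=0)
        events = generate_events(cfg, np.random.default_rng(0))
        ev = events.event_array()[0]
        targets = np.asarray(cfg.median_phase_durations)
        rate = cfg.rate
        n = int(np.ceil((ev[-1] + 2) * rate))
        const = TraceBlock(values=np.full((1, n), 4.2), rate=rate)
        out, bounds = resample_trial(const, ev, targets)
        np.testing.assert_array_equal(out, 4.2)  # constants preserved exactly
        np.testing.assert_array_equal(bounds, phase_boundaries(targets, rate))

        # a ramp is reproduced up to interpolation at identical sample points
        ramp = TraceBlock(values=np.arange(n, dtype=float)[None, :], rate=rate)
        out, bounds = resample_trial(ramp, ev, targets)
        for k in range(10):
            seg = out[0, bounds[k]:bounds[k + 1]]
            assert np.all(np.diff(seg) > 0)  # monotone warp never reorders

    def test_boundary_exactness_across_trials(self):
        cfg = SessionConfig(n_trials=8, n_units=2, duration_jitter=0.4,
                            p_mistake=0.0, seed=1)
        events, traces, truth = simulate_session(cfg)
        targets = median_phase_durations(events)
        all_bounds = []
        for row in events.event_array():
            _, bounds = resample_trial(traces, row, targets)
            all_bounds.append(bounds)
        assert all(np.array_equal(b, all_bounds[0]) for b in all_bounds)
        np.testing.assert_array_equal(
            all_bounds[0], phase_boundaries(targets, cfg.rate))

    def test_mean_preservation_on_ramp(self):
        # time-average of a constant-plus-ramp segment survives the warp
        rate = 10.0
        n = 400
        a, b = 0.3, 1.7
        vals = (b + a * np.arange(n) / rate)[None, :]
        trace = TraceBlock(values=vals, rate=rate)
        ev = _toy_events([2.0] * 10, t1=4.0)
        out, bounds = resample_trial(trace, ev, np.full(10, 3.0))
        for k in range(10):
            seg = out[0, bounds[k]:bounds[k + 1]]
            lo, hi = ev[k], ev[k + 1]
            true_mean = b + a * (lo + hi) / 2  # midpoint of an affine ramp
            assert seg.mean() == pytest.approx(true_mean, abs=1e-9)

    def test_round_trip_on_bandlimited_signal(self):
        rate = 20.0
        t = np.arange(0, 40, 1 / rate)
        vals = np.sin(2 * np.pi * 0.3 * t)[None, :]
        trace = TraceBlock(values=vals, rate=rate)
        durations = [2.0, 1.5, 2.5, 1.0, 2.0, 3.0, 2.0, 1.5, 2.0, 2.0]
        ev = _toy_events(durations, t1=3.0)
        targets = np.full(10, 2.0)
        out, bounds = resample_trial(trace, ev, targets)
        # map back: treat the warped signal as a trace on the common timebase
        warped = TraceBlock(values=out, rate=rate)
        back, bounds2 = resample_trial(warped, bounds / rate, durations)
        # the endpoints-inclusive grid over half-open bin spans skews each
        # phase by up to one source sample, i.e. d_orig/(d_target*rate - 1)
        # seconds; bound the round-trip error by |f'|max times that skew plus
        # a small interpolation term
        fprime = 2 * np.pi * 0.3
        for k in range(10):
            seg = back[0, bounds2[k]:bounds2[k + 1]]
            t_orig = np.linspace(ev[k], ev[k + 1], len(seg))
            truth_vals = np.sin(2 * np.pi * 0.3 * t_orig)
            skew = durations[k] / (targets[k] * rate - 1)
            assert np.abs(seg - truth_vals).max() < fprime * skew + 0.02

    def test_short_segment_rejected(self):
        trace = TraceBlock(values=np.ones((1, 100)), rate=10.0)
        ev = _toy_events([0.05] + [1.0] * 9, t1=1.0)
        with pytest.raises(ShortSegmentError):
            resample_trial(trace, ev, np.full(10, 1.0))


class TestBuildTensor:
    def test_single_trial_matches_resample(self):
        cfg = SessionConfig(n_trials=1, n_units=3, p_mistake=0.0, seed=2)
        events, traces, truth = simulate_session(cfg)
        tensor = build_aligned_tensor(events, truth.deconv, "deconvolved")
        out, bounds = resample_trial(truth.deconv, events.event_array()[0],
                                     tensor.median_durations)
        np.testing.assert_array_equal(tensor.values[0], out)
        np.testing.assert_array_equal(tensor.boundaries, bounds)

    def test_two_identical_trials_average_to_either(self):
        cfg = SessionConfig(n_trials=2, n_units=2, duration_jitter=0.0,
                            p_mistake=0.0, background_rate=0.0, seed=3)
        events, traces, truth = simulate_session(cfg)
        tensor = build_aligned_tensor(events, traces, "raw")
        # phase durations identical; planted spikes differ, so compare warps
        # of the same underlying trace instead: trial-mean equals trial 0
        same = AlignedTensor(values=np.repeat(tensor.values[:1], 2, axis=0),
                             boundaries=tensor.boundaries,
                             median_durations=tensor.median_durations,
                             rate=tensor.rate, sides=tensor.sides,
                             outcomes=tensor.outcomes,
                             phase_valid=tensor.phase_valid)
        np.testing.assert_array_equal(same.values.mean(axis=0), tensor.values[0])

    def test_mistake_trials_marked_invalid_in_retrieval_tail(self):
        cfg = SessionConfig(n_trials=40, n_units=2, p_mistake=0.5, seed=4)
        events, traces, truth = simulate_session(cfg)
        tensor = build_aligned_tensor(events, traces, "zscore")
        mistakes = ~events.is_correct
        assert mistakes.any()
        assert not tensor.phase_valid[mistakes][:, 7:].any()
        assert tensor.phase_valid[mistakes][:, :7].all()
        assert tensor.phase_valid[~mistakes].all()
        assert np.isfinite(tensor.values).all()

    def test_planted_boundary_transition_lands_on_tensor_boundary(self):
        """A unit active only in phase 3 is confined to phase-3 bins after
        alignment, for every trial despite duration jitter."""
        cfg = SessionConfig(n_trials=25, n_units=6, snr=np.inf,
                            fractions=(1.0, 0.0, 0.0), background_rate=0.0,
                            duration_jitter=0.35, p_mistake=0.0,
                            kinetics_tau=0.025, seed=6)
        events, traces, truth = simulate_session(cfg)
        tensor = build_aligned_tensor(events, truth.deconv, "deconvolved")
        for u in range(cfg.n_units):
            ph = truth.planted_peak_phase[u]
            sl = tensor.phase_slice(int(ph))
            # binning + linear interpolation can smear a couple of bins
            # across a boundary (more when a short phase is stretched)
            sl_pad = slice(max(sl.start - 2, 0), sl.stop + 2)
            total = tensor.values[:, u, :].sum()
            assert tensor.values[:, u, sl_pad].sum() == pytest.approx(total, rel=1e-6)
            assert tensor.values[:, u, sl].sum() > 0.9 * total

    def test_phase_slices_partition_timebase(self, planted_tensors):
        tensor, _ = planted_tensors
        stops = [tensor.phase_slice(k).stop for k in range(1, 11)]
        starts = [tensor.phase_slice(k).start for k in range(1, 11)]
        assert starts[0] == 0 and stops[-1] == tensor.n_bins
        assert stops[:-1] == starts[1:]
        m = tensor.period_slice("M")
        assert (m.start, m.stop) == (tensor.phase_slice(5).start,
                                     tensor.phase_slice(6).stop)


def test_missing_phase_error():
    import pandas as pd

    from wmaze.task import EVENT_COLUMNS, TrialEventTable
    ev = _toy_events([1.0] * 10)
    row = {"trial_id": 0, "side": "left", "outcome": "mistake",
           **dict(zip(EVENT_COLUMNS, ev))}
    row["t_event_09"] = np.nan
    row["t_event_10"] = np.nan
    events = TrialEventTable(pd.DataFrame([row]))
    with pytest.raises(MissingPhaseError):
        median_phase_durations(events)
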