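"""End-to-end orchestration: simulate -> align -> analyses -> report.

A run is described by a strict-schema configuration (YAML on disk). Every
random stage derives its stream from the single run seed, so re-running an
identical configuration byte-reproduces all outputs. The summary JSON always
carries a provenance block (package version, UTC timestamp, config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import wmaze
from wmaze import align, decoding, io, orderability, phasepref, roc, sequence, synthetic
from wmaze.errors import ConfigError
from wmaze.task import PERIOD_NAMES, TrialEventTable, validate_events

log = logging.getLogger("wmaze")

DEFAULT_STAGES = ("simulate", "align", "phasepref", "roc", "bdo", "sequence", "decode")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run (strict schema)."""

    out_dir: str = "wmaze_run"
    seed: int = 0
    stages: tuple = DEFAULT_STAGES
    # inputs; ignored when the simulate stage is enabled
    events_path: str | None = None
    traces_path: str | None = None
    # stage parameters (defaults mirror the analyses' published settings)
    session: dict = field(default_factory=dict)
    signal_kind: str = "zscore"
    baseline_window: float = 1.0
    alpha: float = 0.01
    n_draw: int = 100
    n_rep: int = 20
    roc_window: int = 3
    roc_contrast: str = "outcome"
    roc_period: str = "M"
    n_perm: int = 1000
    bdo_span: str = "M"
    decode_contrast: str = "side"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if not set(cfg.stages) <= set(DEFAULT_STAGES):
            raise ConfigError(f"stages must be a subset of {DEFAULT_STAGES}")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(cfg: RunConfig) -> dict:
    return {"package_version": wmaze.__version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the toggled stages and write a machine-readable summary.

    Returns the summary dict; also writes ``summary.json`` and a short human
    report to ``cfg.out_dir``. Raises on any stage error (the CLI converts
    this to a nonzero exit).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"provenance": _provenance(cfg), "stages": {}}
    rng = np.random.default_rng(cfg.seed)

    events = traces = truth = None
    t_start = time.perf_counter()

    def _stage_done(name: str, payload: dict) -> None:
        summary["stages"][name] = payload
        log.info("stage %-9s done in %.2f s", name, time.perf_counter() - t0)

    if "simulate" in cfg.stages:
        t0 = time.perf_counter()
        scfg = synthetic.SessionConfig(**{"seed": cfg.seed, **cfg.session})
        events, traces, truth = synthetic.simulate_session(scfg)
        io.save_session(out, events, traces, truth)
        _stage_done("simulate", {"n_trials": len(events),
                                 "n_units": traces.n_units,
                                 "n_mistakes": int((~events.is_correct).sum())})
    elif cfg.events_path and cfg.traces_path:
        t0 = time.perf_counter()
        events = TrialEventTable.from_csv(cfg.events_path)
        traces = io.load_traces(cfg.traces_path)
        _stage_done("load", {"n_trials": len(events), "n_units": traces.n_units})
    else:
        raise ConfigError("either enable the simulate stage or give input paths")

    report = validate_events(events)
    if len(report):
        report.to_csv(out / "event_violations.csv", index=False)
        raise ConfigError(f"{len(report)} event-grammar violations; see "
                          f"{out / 'event_violations.csv'}")

    tensor = deconv_tensor = None
    if "align" in cfg.stages:
        t0 = time.perf_counter()
        tensor = align.build_aligned_tensor(events, traces, cfg.signal_kind,
                                            cfg.baseline_window)
        io.save_aligned(out / "aligned.h5", tensor)
        deconv = truth.deconv if truth is not None else None
        if deconv is None and cfg.traces_path:
            try:
                deconv = io.load_traces(cfg.traces_path, "deconv")
            except KeyError:
                deconv = None
        if deconv is not None:
            deconv_tensor = align.build_aligned_tensor(
                events, deconv, "deconvolved",
                targets=tensor.median_durations)
        _stage_done("align", {"n_bins": tensor.n_bins,
                              "boundaries": tensor.boundaries.tolist()})

    def _need(dep: str, obj) -> None:
        if obj is None:
            raise ConfigError(f"stage requires '{dep}' output; enable that stage")

    if "phasepref" in cfg.stages:
        t0 = time.perf_counter()
        _need("align", tensor)
        src = truth.deconv if truth is not None else traces
        means = phasepref.window_mean_activity(events, src, "periods")
        table = phasepref.phase_significance(means, cfg.alpha, "periods")
        counts = {p: int((table.preferred_window == i).sum())
                  for i, p in enumerate(PERIOD_NAMES)}
        tests = phasepref.period_preference_test(counts, src.n_units)
        coact = phasepref.coactivity_matrix(table.binary)
        pd.DataFrame(table.sig, columns=list(PERIOD_NAMES)).to_csv(
            out / "period_significance.csv", index_label="unit")
        pd.DataFrame(coact, index=list(PERIOD_NAMES),
                     columns=list(PERIOD_NAMES)).to_csv(out / "coactivity.csv")
        _stage_done("phasepref", {
            "preferred_fractions": {p: counts[p] / src.n_units for p in counts},
            "p_per_period": {k: float(v) for k, v in tests["per_period"].items()},
            "p_per_pair": {f"{a}|{b}": float(v)
                           for (a, b), v in tests["per_pair"].items()}})

    if "roc" in cfg.stages:
        t0 = time.perf_counter()
        _need("align", tensor)
        sl = tensor.span_slice(cfg.roc_period)
        bulk = tensor.values.sum(axis=1)[:, sl]
        labels = tensor.outcomes if cfg.roc_contrast == "outcome" else tensor.sides
        if np.unique(labels).size == 2:
            trace = roc.time_resolved_auc(bulk, labels, rng, cfg.n_draw,
                                          cfg.n_rep, cfg.roc_window, cfg.alpha,
                                          tensor.rate, sl.start / tensor.rate)
            pd.DataFrame({"t": trace.t, "auc_mean": trace.auc_mean,
                          "auc_sem": trace.auc_sem,
                          "shuffle_mean": trace.shuffle_mean,
                          "shuffle_sem": trace.shuffle_sem,
                          "p_raw": trace.p_raw, "p_adj": trace.p_adj,
                          "sig": trace.sig_mask}).to_csv(out / "roc.csv", index=False)
            _stage_done("roc", {"n_sig_bins": int(trace.sig_mask.sum()),
                                "n_bins": int(trace.sig_mask.size)})
        else:
            _stage_done("roc", {"skipped": "contrast has a single class"})

    if "bdo" in cfg.stages:
        t0 = time.perf_counter()
        source = deconv_tensor if deconv_tensor is not None else tensor
        _need("align", source)
        sl = source.span_slice(cfg.bdo_span)
        vals = source.values[source.is_correct][:, :, sl]
        centers = orderability.trial_centers(vals)
        result = orderability.abdo_permutation_test(centers, rng, cfg.n_perm)
        pd.DataFrame(result.bdo).to_csv(out / "bdo.csv", index_label="unit")
        _stage_done("bdo", {"abdo": result.abdo, "perm_p": result.perm_p,
                            "n_perm": cfg.n_perm, "span": cfg.bdo_span})

    if "sequence" in cfg.stages:
        t0 = time.perf_counter()
        source = deconv_tensor if deconv_tensor is not None else tensor
        _need("align", source)
        res = sequence.sequence_analysis(source, rng, cfg.bdo_span)
        _stage_done("sequence", {
            "median_shift_test": res.median_shift_test,
            "p75_shift_test": res.p75_shift_test,
            "median_shift_mistake": res.median_shift_mistake,
            "p75_shift_mistake": res.p75_shift_mistake,
            "p_compare": res.p_compare})

    if "decode" in cfg.stages:
        t0 = time.perf_counter()
        source = deconv_tensor if deconv_tensor is not None else tensor
        _need("align", source)
        labels = source.sides if cfg.decode_contrast == "side" else source.outcomes
        if np.unique(labels).size == 2:
            trace = decoding.l2_permutation_test(source.values, labels, rng,
                                                 cfg.n_perm, source.rate)
            pd.DataFrame({"t": trace.t, "l2": trace.l2, "p": trace.p,
                          "neg_log10_p": trace.neg_log10_p}).to_csv(
                out / "decode.csv", index=False)
            _stage_done("decode", {"n_sig_bins": int((trace.p <= cfg.alpha).sum()),
                                   "n_bins": int(trace.p.size)})
        else:
            _stage_done("decode", {"skipped": "contrast has a single class"})

    summary["wall_clock_s"] = time.perf_counter() - t_start
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    lines = [f"wmaze run {summary['provenance']['config_hash']}"]
    for name, payload in summary["stages"].items():
        lines.append(f"  {name}: {json.dumps(payload, default=float)}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return summary
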