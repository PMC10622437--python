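"""On-disk formats: events as CSV, traces and aligned tensors as HDF5."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from wmaze.align import AlignedTensor, TraceBlock
from wmaze.synthetic import GroundTruth
from wmaze.task import TrialEventTable


def save_traces(path, traces: TraceBlock, truth: GroundTruth | None = None) -> None:
    """Write /traces (+ /deconv, /spikes and planted metadata if available)."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("traces", data=traces.values)
        d.attrs["rate"] = traces.rate
        d.attrs["t0"] = traces.t0
        d.attrs["modality"] = traces.modality
        d.attrs["kind"] = traces.kind
        if truth is not None:
            dd = f.create_dataset("deconv", data=truth.deconv.values)
            dd.attrs["rate"] = truth.deconv.rate
            dd.attrs["t0"] = truth.deconv.t0
            dd.attrs["modality"] = truth.deconv.modality
            dd.attrs["kind"] = "deconvolved"
            f.create_dataset("spikes", data=truth.spikes[["unit", "trial", "time"]]
                             .to_numpy(dtype=float))
            g = f.create_group("ground_truth")
            g.create_dataset("unit_class",
                             data=np.char.encode(truth.unit_class.astype(str)))
            g.create_dataset("planted_peak_phase", data=truth.planted_peak_phase)
            g.create_dataset("planted_sequence_rank", data=truth.planted_sequence_rank)


def load_traces(path, dataset: str = "traces") -> TraceBlock:
    """Read /traces or /deconv back into a TraceBlock."""
    with h5py.File(path, "r") as f:
        d = f[dataset]
        return TraceBlock(values=d[()], rate=float(d.attrs["rate"]),
                          t0=float(d.attrs.get("t0", 0.0)),
                          modality=str(d.attrs.get("modality", "cellular")),
                          kind=str(d.attrs.get("kind", "raw")))


def save_aligned(path, tensor: AlignedTensor) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("aligned", data=tensor.values)
        d.attrs["rate"] = tensor.rate
        d.attrs["signal_kind"] = tensor.signal_kind
        f.create_dataset("boundaries", data=tensor.boundaries)
        f.create_dataset("median_durations", data=tensor.median_durations)
        f.create_dataset("phase_valid", data=tensor.phase_valid)
        g = f.create_group("labels")
        g.create_dataset("side", data=np.char.encode(tensor.sides.astype(str)))
        g.create_dataset("outcome", data=np.char.encode(tensor.outcomes.astype(str)))


def load_aligned(path) -> AlignedTensor:
    with h5py.File(path, "r") as f:
        d = f["aligned"]
        return AlignedTensor(
            values=d[()],
            boundaries=f["boundaries"][()],
            median_durations=f["median_durations"][()],
            rate=float(d.attrs["rate"]),
            sides=np.char.decode(f["labels/side"][()]),
            outcomes=np.char.decode(f["labels/outcome"][()]),
            phase_valid=f["phase_valid"][()].astype(bool),
            signal_kind=str(d.attrs.get("signal_kind", "zscore")),
        )


def save_session(out_dir, events: TrialEventTable, traces: TraceBlock,
                 truth: GroundTruth | None = None) -> dict:
    """Write a session as events.csv + traces.h5; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events_path = out / "events.csv"
    traces_path = out / "traces.h5"
    events.to_csv(events_path)
    save_traces(traces_path, traces, truth)
    return {"events": str(events_path), "traces": str(traces_path)}
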