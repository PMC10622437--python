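"""Trial grammar of the T-maze delayed non-match-to-place task.

Each trial is anchored by 11 salient events (start of sample run, T-junction
turn, first reward, end of licking, turn back, reaching the start box, start of
choice run, T-junction turn, second reward, end of licking, end of choice run).
Consecutive events bound 10 trial phases; events 1-5, 5-7 and 7-11 delimit the
encoding (E), maintenance (M) and retrieval (R) periods. Mistake trials earn no
second reward, so events 9 and 10 are absent and phases 8-10 are undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_EVENTS = 11
N_PHASES = 10
N_PERIODS = 3

PERIOD_NAMES = ("E", "M", "R")
#: 1-based phase indices belonging to each task period.
PERIOD_PHASES = {"E": (1, 2, 3, 4), "M": (5, 6), "R": (7, 8, 9, 10)}
#: (first event, last event), 1-based, bounding each period.
PERIOD_EVENTS = {"E": (1, 5), "M": (5, 7), "R": (7, 11)}

EVENT_COLUMNS = [f"t_event_{k:02d}" for k in range(1, N_EVENTS + 1)]


@dataclass
class TrialEventTable:
    """Per-trial metadata and the 11 salient event timestamps.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per trial with columns ``trial_id``, ``side`` (``left`` /
        ``right`` sample-run direction), ``outcome`` (``correct`` /
        ``mistake``) and ``t_event_01`` .. ``t_event_11`` in seconds from
        session start. Events 9 and 10 are NaN for mistake trials.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ["trial_id", "side", "outcome", *EVENT_COLUMNS]
                   if c not in self.table.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sides(self) -> np.ndarray:
        return self.table["side"].to_numpy()

    @property
    def outcomes(self) -> np.ndarray:
        return self.table["outcome"].to_numpy()

    @property
    def is_correct(self) -> np.ndarray:
        return self.outcomes == "correct"

    def event_array(self) -> np.ndarray:
        """Event times as a (n_trials, 11) float array, NaN where absent."""
        return self.table[EVENT_COLUMNS].to_numpy(dtype=float)

    def phase_durations(self) -> np.ndarray:
        """Per-trial phase durations, (n_trials, 10), NaN for missing phases."""
        ev = self.event_array()
        return np.diff(ev, axis=1)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialEventTable":
        return cls(pd.read_csv(path))


def period_of_phase(phase: int) -> str:
    """Task period (E/M/R) containing a 1-based phase index."""
    for name, phases in PERIOD_PHASES.items():
        if phase in phases:
            return name
    raise ValueError(f"phase must be in 1..{N_PHASES}, got {phase}")


def validate_events(events: TrialEventTable) -> pd.DataFrame:
    """Check every trial against the task grammar.

    Returns a report DataFrame with one row per violation (columns
    ``trial_id``, ``problem``); an empty frame means the table is clean.
    Checked: strictly increasing present event times, mandatory events
    (1-8 and 11) present, and absence of events 9/10 in mistake trials.
    """
    problems: list[dict] = []
    ev = events.event_array()
    mandatory = [0, 1, 2, 3, 4, 5, 6, 7, 10]  # 0-based: events 1-8, 11
    for row, trial_id, outcome in zip(ev, events.table["trial_id"], events.outcomes):
        present = ~np.isnan(row)
        if not present[mandatory].all():
            problems.append({"trial_id": trial_id, "problem": "missing mandatory event"})
        t = row[present]
        if np.any(np.diff(t) <= 0):
            problems.append({"trial_id": trial_id, "problem": "event times not strictly increasing"})
        if outcome == "mistake" and (present[8] or present[9]):
            problems.append({"trial_id": trial_id, "problem": "mistake trial contains event 9 or 10"})
        if outcome == "correct" and not present.all():
            problems.append({"trial_id": trial_id, "problem": "correct trial with missing events"})
    return pd.DataFrame(problems, columns=["trial_id", "problem"])
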