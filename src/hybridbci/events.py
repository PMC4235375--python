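"""Stimulus event schedules.

A schedule is an ordered list of stimulus events, each with an onset (s from
session start), a duration (s), a label from {AUD, VIS, MIX, IDLE}, a block
number, and a kind: ``"trial"`` for the stimulus-locked events of blocks 2-5
or ``"continuous"`` for the three fixed 60 s clips of block 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LABELS = ("AUD", "VIS", "MIX", "IDLE")

_COLUMNS = ["onset_s", "duration_s", "label", "block", "kind"]


class ScheduleError(ValueError):
    """Raised when a schedule violates its invariants."""


@dataclass
class EventSchedule:
    """Time-sorted, non-overlapping stimulus events.

    Invariants (checked on construction): events sorted by onset and
    non-overlapping; labels drawn from `LABELS`; within the trial blocks no
    two consecutive events share a label.
    """

    events: pd.DataFrame

    def __post_init__(self) -> None:
        ev = self.events
        missing = [c for c in _COLUMNS if c not in ev.columns]
        if missing:
            raise ScheduleError(f"schedule missing columns {missing}")
        ev = ev[_COLUMNS].reset_index(drop=True)
        bad = set(ev["label"]) - set(LABELS)
        if bad:
            raise ScheduleError(f"unknown labels {sorted(bad)}")
        if (ev["duration_s"] <= 0).any():
            raise ScheduleError("event durations must be positive")
        onset = ev["onset_s"].to_numpy(float)
        if len(ev) > 1:
            if (np.diff(onset) < 0).any():
                raise ScheduleError("events must be time-sorted")
            end = onset + ev["duration_s"].to_numpy(float)
            if (onset[1:] < end[:-1] - 1e-9).any():
                raise ScheduleError("events overlap")
        trials = ev[ev["kind"] == "trial"]
        lab = trials["label"].to_numpy()
        if len(lab) > 1 and (lab[1:] == lab[:-1]).any():
            raise ScheduleError("consecutive trial events share a label")
        self.events = ev

    def __len__(self) -> int:
        return len(self.events)

    @property
    def end_time(self) -> float:
        """Time at which the last event ends (s)."""
        if not len(self.events):
            return 0.0
        ev = self.events
        return float((ev["onset_s"] + ev["duration_s"]).max())

    def trials(self) -> pd.DataFrame:
        """The stimulus-locked events of blocks 2-5."""
        return self.events[self.events["kind"] == "trial"].reset_index(drop=True)

    def continuous_segments(self) -> pd.DataFrame:
        """The continuous clips of block 1."""
        return self.events[self.events["kind"] == "continuous"].reset_index(drop=True)

    def label_counts(self) -> dict[str, int]:
        t = self.trials()
        return {lab: int((t["label"] == lab).sum()) for lab in LABELS}

    def shifted(self, dt: float) -> "EventSchedule":
        """Schedule with all onsets translated by `dt` seconds."""
        ev = self.events.copy()
        ev["onset_s"] = ev["onset_s"] + dt
        return EventSchedule(ev)

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path_or_buf) -> None:
        self.events.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "EventSchedule":
        ev = pd.read_csv(path_or_buf)
        if "kind" not in ev.columns:
            ev["kind"] = "trial"
        return cls(ev)

    @classmethod
    def from_records(cls, records: list[dict]) -> "EventSchedule":
        return cls(pd.DataFrame.from_records(records, columns=_COLUMNS))

    @classmethod
    def empty(cls) -> "EventSchedule":
        return cls(pd.DataFrame(columns=_COLUMNS))

    def __eq__(self, other) -> bool:  # value equality, used by container round-trip
        if not isinstance(other, EventSchedule):
            return NotImplemented
        return self.events.equals(other.events)
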