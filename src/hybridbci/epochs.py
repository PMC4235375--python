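"""Stimulus-locked epoching and 50 %-overlap windowing.

Conventions: time is seconds from session start, sample indices are 0-based,
and epoch windows are half-open ``[onset + t_start, onset + t_stop)``.
Events whose epoch would overflow a recording are dropped (not clipped) so
that all epochs in a TrialSet have equal length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EventSchedule

logger = logging.getLogger(__name__)

#: Default epoch windows (t_start, t_stop) relative to stimulus onset, per
#: signal type.  fNIRS haemoglobin epochs run 0-10 s at 1 Hz with a 2 s
#: prestimulus baseline; EEG band-power epochs cover the full 10 s stimulus
#: window; ERP epochs cover the first second plus 100 ms of prestimulus
#: context for baseline correction.
DEFAULT_POLICIES: dict[str, tuple[float, float]] = {
    "hbo": (-2.0, 10.0),
    "hbr": (-2.0, 10.0),
    "pow": (0.0, 10.0),
    "erp": (-0.1, 1.0),
}


@dataclass
class EpochBlock:
    """Equal-length epochs of one signal type.

    ``data`` has shape (n_trials, n_series, n_samples) covering
    ``[t_start, t_stop)`` around each onset at sampling rate ``fs``.
    """

    data: np.ndarray
    fs: float
    t_start: float
    t_stop: float

    @property
    def n_pre(self) -> int:
        """Number of prestimulus samples."""
        return int(round(-self.t_start * self.fs)) if self.t_start < 0 else 0

    def post_onset(self) -> np.ndarray:
        """The portion of each epoch from the onset forward."""
        return self.data[..., self.n_pre:]

    def prestimulus(self) -> np.ndarray:
        return self.data[..., : self.n_pre]

    def select(self, idx) -> "EpochBlock":
        return EpochBlock(self.data[idx], self.fs, self.t_start, self.t_stop)


@dataclass
class TrialSet:
    """Stimulus-locked epochs with labels, one row of `meta` per trial."""

    subject_id: str
    meta: pd.DataFrame  # columns: label, onset_s, duration_s, block
    blocks: dict[str, EpochBlock] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.meta)
        for name, blk in self.blocks.items():
            if blk.data.shape[0] != n:
                raise ValueError(f"block {name!r} trial count mismatch")

    def __len__(self) -> int:
        return len(self.meta)

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy()

    def select(self, idx) -> "TrialSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return TrialSet(
            subject_id=self.subject_id,
            meta=self.meta.iloc[idx].reset_index(drop=True),
            blocks={k: b.select(idx) for k, b in self.blocks.items()},
        )


def extract_epochs(
    data: np.ndarray,
    fs: float,
    onsets: np.ndarray,
    t_start: float,
    t_stop: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut half-open windows ``[onset+t_start, onset+t_stop)`` out of `data`.

    Returns ``(epochs, kept)`` where `kept` marks the events whose window fits
    entirely inside the recording; overflowing events are dropped with a
    logged warning.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_t = data.shape[-1]
    n_samp = int(round((t_stop - t_start) * fs))
    starts = np.round((np.asarray(onsets, float) + t_start) * fs).astype(int)
    kept = (starts >= 0) & (starts + n_samp <= n_t)
    if not kept.all():
        logger.warning(
            "dropping %d event(s) whose epoch extends past the recording",
            int((~kept).sum()),
        )
    epochs = np.stack(
        [data[:, s : s + n_samp] for s in starts[kept]], axis=0
    ) if kept.any() else np.empty((0, data.shape[0], n_samp))
    return epochs, kept


def epoch_trials(
    schedule: EventSchedule,
    signals: dict[str, tuple[np.ndarray, float]],
    policies: dict[str, tuple[float, float]] | None = None,
    subject_id: str = "",
) -> TrialSet:
    """Epoch every stimulus-locked event of `schedule` in each signal.

    Parameters
    ----------
    signals
        Mapping from block name to ``(data, fs)``, where data has shape
        (n_series, n_samples).  Typically hbo/hbr at 1 Hz (post-preprocessing)
        and pow/erp views of the cleaned EEG at 256 Hz.
    policies
        Epoch windows per block name; defaults to `DEFAULT_POLICIES`.

    An event is kept only if its epoch fits in *every* requested signal, so
    all blocks stay aligned trial-for-trial.  A schedule with zero events
    yields an empty TrialSet.
    """
    policies = dict(DEFAULT_POLICIES if policies is None else policies)
    trials = schedule.trials()
    onsets = trials["onset_s"].to_numpy(float)
    kept_all = np.ones(len(trials), dtype=bool)
    raw = {}
    for name, (data, fs) in signals.items():
        if name not in policies:
            raise KeyError(f"no epoch policy for signal {name!r}")
        t0, t1 = policies[name]
        _, kept = extract_epochs(data, fs, onsets, t0, t1)
        kept_all &= kept
    blocks = {}
    for name, (data, fs) in signals.items():
        t0, t1 = policies[name]
        epochs, _ = extract_epochs(data, fs, onsets[kept_all], t0, t1)
        blocks[name] = EpochBlock(epochs, fs, t0, t1)
    return TrialSet(
        subject_id=subject_id,
        meta=trials.loc[kept_all, ["label", "onset_s", "duration_s", "block"]]
        .reset_index(drop=True),
        blocks=blocks,
    )


# ------------------------------------------------------------------ windows


@dataclass
class WindowSet:
    """50 %-overlapping windows over one continuous labelled segment.

    Starts sit at consecutive multiples of ``w_len / 2`` relative to the
    segment start; the count is ``ceil(duration / (w_len / 2))`` and final
    windows are truncated at the segment end.
    """

    segment_id: str
    label: str
    w_len: float
    duration: float
    starts: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def stops(self) -> np.ndarray:
        """Window end times, truncated at the segment end."""
        return np.minimum(self.starts + self.w_len, self.duration)


def segment_windows(
    duration: float,
    w_len: float,
    label: str = "",
    segment_id: str = "",
) -> WindowSet:
    """Segment a `duration`-second recording into 50 %-overlap windows.

    A 60 s segment yields 120/60/30/15/8 windows for w_len of 1/2/4/8/16 s.
    """
    if w_len <= 0:
        raise ValueError("window length must be positive")
    if duration < w_len / 2:
        raise ValueError("segment shorter than half a window")
    hop = w_len / 2.0
    count = int(np.ceil(duration / hop - 1e-9))
    starts = np.arange(count) * hop
    return WindowSet(segment_id=segment_id, label=label, w_len=float(w_len),
                     duration=float(duration), starts=starts)
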