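"""Grand averages, correlation-based feature rankings and Friedman tests.

Rankings follow the correlation-analysis recipe: for every subject each
item (electrode, frequency component, time window, or fNIRS probe) is
scored by the highest absolute Pearson correlation between any of its
features and the binary condition labels; items are ranked 1 = best and
ranks are averaged across subjects.  A Friedman test on the per-subject
rank rows asks whether the ordering is consistent across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .epochs import TrialSet
from .features import PowFeatureParams, pow_feature, pow_frequencies


@dataclass
class RankingTable:
    """Per-subject item ranks (each row a permutation of 1..k)."""

    items: list
    ranks: np.ndarray  # (n_subjects, k)

    def __post_init__(self) -> None:
        self.ranks = np.atleast_2d(np.asarray(self.ranks, float))
        k = len(self.items)
        if self.ranks.shape[1] != k:
            raise ValueError("rank matrix width must equal item count")
        for row in self.ranks:
            if sorted(row) != list(range(1, k + 1)):
                raise ValueError("each subject's ranks must be a permutation of 1..k")

    @property
    def mean_rank(self) -> np.ndarray:
        return self.ranks.mean(axis=0)

    @property
    def sd_rank(self) -> np.ndarray:
        return self.ranks.std(axis=0, ddof=1) if len(self.ranks) > 1 else \
            np.zeros(self.ranks.shape[1])

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(self.mean_rank, kind="stable")
        return pd.DataFrame({
            "rank": np.arange(1, len(self.items) + 1),
            "item": [self.items[i] for i in order],
            "mean_rank": self.mean_rank[order],
            "sd": self.sd_rank[order],
        })


def label_correlation_scores(X: np.ndarray, y: np.ndarray,
                             groups: np.ndarray) -> dict:
    """Max |Pearson r(feature, label)| per feature group for one subject.

    Constant features contribute a correlation of 0 (so degenerate groups
    rank last); `y` is the binary 0/1 condition label.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    yc = y - y.mean()
    denom_y = np.sqrt((yc**2).sum())
    Xc = X - X.mean(axis=0)
    denom_x = np.sqrt((Xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(Xc.T @ yc) / np.where(denom_x > 0, denom_x * denom_y, np.inf)
    r = np.nan_to_num(r)
    return {g: float(r[groups == g].max()) for g in pd.unique(groups)}


def rank_features(
    subject_data: list[tuple[np.ndarray, np.ndarray]],
    groups: np.ndarray,
) -> RankingTable:
    """Rank feature groups by label correlation, averaged across subjects.

    `subject_data` holds per-subject (feature matrix, binary labels); the
    feature-to-group assignment `groups` is shared.  Ranks are ordinal
    (1 = highest score), ties broken by group order.
    """
    if len(subject_data) < 2:
        raise ValueError("ranking requires >= 2 subjects")
    items = list(pd.unique(np.asarray(groups)))
    rows = []
    for X, y in subject_data:
        scores = label_correlation_scores(X, y, np.asarray(groups))
        vals = np.array([scores[g] for g in items])
        order = np.lexsort((np.arange(len(items)), -vals))
        ranks = np.empty(len(items))
        ranks[order] = np.arange(1, len(items) + 1)
        rows.append(ranks)
    return RankingTable(items, np.vstack(rows))


def friedman_rank_test(table: RankingTable) -> tuple[float, float]:
    """Friedman chi-square over the rank matrix (k - 1 degrees of freedom).

    Identical rankings across n subjects of k items give the maximum
    statistic n*(k - 1).
    """
    n, k = table.ranks.shape
    if n < 2:
        raise ValueError("Friedman test requires >= 2 subjects")
    if k < 3:
        raise ValueError("Friedman test requires >= 3 items")
    stat, p = stats.friedmanchisquare(*[table.ranks[:, j] for j in range(k)])
    return float(stat), float(p)


# ------------------------------------------------------------ grand averages


def grand_average_hrf(
    trials: TrialSet,
    channels: np.ndarray | None = None,
    block: str = "hbo",
    baseline_s: float = 2.0,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-label mean haemoglobin curve (channel-averaged) with a standard
    error band, after subtracting the prestimulus baseline per channel."""
    blk = trials.blocks[block]
    n_base = int(round(baseline_s * blk.fs))
    if blk.n_pre < n_base:
        raise ValueError(f"epochs lack a {baseline_s} s prestimulus baseline")
    data = blk.data
    if channels is not None:
        data = data[:, np.asarray(channels), :]
    base = data[..., blk.n_pre - n_base: blk.n_pre].mean(axis=-1, keepdims=True)
    corrected = (data - base).mean(axis=1)  # average channel group
    out = {}
    for lab in np.unique(trials.labels):
        sel = corrected[trials.labels == lab]
        sem = (sel.std(axis=0, ddof=1) / np.sqrt(len(sel))
               if len(sel) > 1 else np.zeros(sel.shape[1]))
        out[lab] = {"mean": sel.mean(axis=0), "sem": sem, "n": len(sel),
                    "t": blk.t_start + np.arange(sel.shape[1]) / blk.fs}
    return out


def grand_average_erp(
    trials: TrialSet,
    electrodes: np.ndarray | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-label mean ERP waveform over the first second, per electrode."""
    blk = trials.blocks["erp"]
    data = blk.post_onset()
    if electrodes is not None:
        data = data[:, np.asarray(electrodes), :]
    out = {}
    for lab in np.unique(trials.labels):
        sel = data[trials.labels == lab]
        out[lab] = {"mean": sel.mean(axis=0), "n": len(sel),
                    "t": np.arange(sel.shape[-1]) / blk.fs}
    return out


def average_psd(
    trials: TrialSet,
    electrodes: np.ndarray | None = None,
    fs: float = 256.0,
    params: PowFeatureParams = PowFeatureParams(band_low=1.0, band_high=45.0),
) -> dict[str, dict[str, np.ndarray]]:
    """Per-label log10 Welch PSD of the 10 s stimulus epochs."""
    data = trials.blocks["pow"].post_onset()
    if electrodes is not None:
        data = data[:, np.asarray(electrodes), :]
    psd = pow_feature(data, fs=fs, params=params)
    freqs = pow_frequencies(params)
    out = {}
    for lab in np.unique(trials.labels):
        sel = psd[trials.labels == lab]
        mean = sel.mean(axis=0)
        if (mean <= 0).any():
            raise ValueError("degenerate (zero-power) spectrum")
        out[lab] = {"log_psd": np.log10(mean), "freqs": freqs, "n": len(sel)}
    return out


def probe_best_channel_rate(
    subject_scores: list[np.ndarray],
    channel_probe: np.ndarray,
    probe_index: int,
) -> float:
    """Fraction of subjects whose best-correlated fNIRS channel lies on the
    given probe (scores are per-channel max |r| values per subject)."""
    hits = [int(channel_probe[int(np.argmax(s))] == probe_index)
            for s in subject_scores]
    return float(np.mean(hits))
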