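"""EEG preprocessing: zero-phase FIR band-pass, ICA blink rejection, and
prestimulus baseline correction.

The band-pass uses a linear-phase FIR whose length is 3 x (sampling rate /
low cutoff) taps (1536 at 256 Hz and 0.5 Hz), applied forward and backward.
Blink rejection decomposes the channels into as many independent components,
removes exactly the one whose time course correlates most with a frontal
low-frequency blink proxy, and reconstructs from the remainder; a maximum
correlation below threshold leaves the data untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA

from .epochs import EpochBlock, TrialSet
from .montage import FRONTAL_ELECTRODE

logger = logging.getLogger(__name__)

DEFAULT_BAND = (0.5, 48.0)
BLINK_CORR_THRESHOLD = 0.3


def fir_bandpass_taps(low: float, high: float, fs: float) -> np.ndarray:
    """Design the band-pass FIR; length 3*(fs/low) rounded up to odd."""
    if not 0 < low < high < fs / 2:
        raise ValueError(f"invalid band ({low}, {high}) Hz at fs={fs}")
    numtaps = int(round(3 * fs / low))
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(numtaps, [low, high], pass_zero=False, fs=fs)


def bandpass_filter(
    x: np.ndarray, fs: float = 256.0, low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
) -> np.ndarray:
    """Zero-phase band-pass of (n_electrodes, n_samples) voltages."""
    x = np.asarray(x, float)
    taps = fir_bandpass_taps(low, high, fs)
    padlen = min(x.shape[-1] - 1, 3 * len(taps))
    return signal.filtfilt(taps, [1.0], x, axis=-1, padlen=padlen)


def blink_proxy(x: np.ndarray, fs: float, frontal_index: int) -> np.ndarray:
    """Blink proxy: thresholded low-frequency envelope of the frontal
    electrode.

    Blinks are large, slow, frontally dominant deflections; keeping only
    excursions beyond 4 robust standard deviations makes the proxy specific
    to blink events, so blink-free data correlates with no component.
    """
    b, a = signal.butter(4, 5.0, btype="low", fs=fs)
    low = signal.filtfilt(b, a, x[frontal_index])
    center = np.median(low)
    mad = np.median(np.abs(low - center)) * 1.4826
    dev = low - center
    return np.where(np.abs(dev) > 4.0 * max(mad, 1e-12), dev, 0.0)


def remove_blink_ica(
    x: np.ndarray,
    fs: float,
    electrode_names: tuple[str, ...],
    seed: int = 0,
    corr_threshold: float = BLINK_CORR_THRESHOLD,
) -> tuple[np.ndarray, int | None]:
    """Remove the single blink-dominated independent component.

    Returns ``(cleaned, removed_component)``; `removed_component` is None
    when no component correlates with the blink proxy above
    `corr_threshold`, in which case the data passes through unchanged.
    """
    x = np.asarray(x, float)
    n_el = x.shape[0]
    if n_el < 2:
        raise ValueError("ICA blink removal needs >= 2 electrodes")
    if x.shape[1] / fs < 60:
        raise ValueError("need >= 60 s of data for a stable unmixing")
    frontal = electrode_names.index(FRONTAL_ELECTRODE)
    proxy = blink_proxy(x, fs, frontal)
    ica = FastICA(
        n_components=n_el, random_state=seed, whiten="unit-variance",
        max_iter=500, tol=1e-4,
    )
    # estimate the unmixing on a decimated copy (blinks are low-frequency;
    # ~64 Hz is ample), then unmix the full-rate data with it
    step = max(1, int(round(fs / 64.0)))
    ica.fit(x[:, ::step].T)
    sources = (x.T - ica.mean_) @ ica.components_.T  # (n_samples, n_components)
    proxy_c = proxy - proxy.mean()
    src_c = sources - sources.mean(axis=0)
    denom = np.sqrt((src_c**2).sum(axis=0) * (proxy_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(src_c.T @ proxy_c) / np.where(denom > 0, denom, np.inf)
    best = int(np.argmax(corr))
    if corr[best] < corr_threshold:
        logger.warning(
            "no blink component found (max |r| = %.2f < %.2f); skipping removal",
            corr[best], corr_threshold,
        )
        return x.copy(), None
    sources[:, best] = 0.0
    cleaned = (sources @ ica.mixing_.T + ica.mean_).T
    return cleaned, best


def baseline_correct_block(block: EpochBlock, baseline_s: float = 0.1) -> EpochBlock:
    """Subtract each epoch's mean over the `baseline_s` prestimulus window.

    The corrected prestimulus window has zero mean per electrode; applying
    the correction twice equals applying it once.
    """
    n_base = int(round(baseline_s * block.fs))
    if block.n_pre < n_base:
        raise ValueError(
            f"epochs carry only {block.n_pre} prestimulus samples; "
            f"{n_base} needed for a {baseline_s * 1e3:.0f} ms baseline"
        )
    base = block.data[..., block.n_pre - n_base : block.n_pre]
    corrected = block.data - base.mean(axis=-1, keepdims=True)
    return EpochBlock(corrected, block.fs, block.t_start, block.t_stop)


def baseline_correct(trials: TrialSet, blocks: tuple[str, ...] = ("erp",),
                     baseline_s: float = 0.1) -> TrialSet:
    """Baseline-correct the named epoch blocks of a TrialSet."""
    new = dict(trials.blocks)
    for name in blocks:
        new[name] = baseline_correct_block(trials.blocks[name], baseline_s)
    return TrialSet(subject_id=trials.subject_id, meta=trials.meta, blocks=new)


def preprocess_eeg(
    eeg: np.ndarray,
    fs: float,
    electrode_names: tuple[str, ...],
    seed: int = 0,
    band: tuple[float, float] = DEFAULT_BAND,
    ica: bool = True,
) -> tuple[np.ndarray, dict]:
    """Band-pass then (optionally) ICA blink removal; returns (data, log)."""
    filtered = bandpass_filter(eeg, fs, *band)
    log: dict = {"band_hz": band, "fir_taps": int(round(3 * fs / band[0])) | 1}
    if ica:
        cleaned, removed = remove_blink_ica(filtered, fs, electrode_names, seed=seed)
        log["ica_removed_component"] = removed
        return cleaned, log
    log["ica_removed_component"] = None
    return filtered, log
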