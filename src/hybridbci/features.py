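"""Per-trial feature extraction: haemoglobin slope features, Welch band
power, downsampled ERP waveforms, z-normalization, and the continuous-mode
fNIRS feature.

All extractors are deterministic functions of their inputs and parameters.
The extractor classes follow the sklearn transformer protocol (fit /
transform on (n_trials, ...) arrays); the module-level functions are thin
wrappers used by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from sklearn.base import BaseEstimator, TransformerMixin


# ----------------------------------------------------------- feature matrix


@dataclass
class FeatureMatrix:
    """Trials x features values of one feature type, with provenance.

    ``provenance`` carries one row per feature (channel/electrode plus the
    frequency or time index it came from).
    """

    values: np.ndarray
    feature_type: str  # HbO | HbR | POW | ERP
    provenance: pd.DataFrame | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")
        if self.provenance is not None and len(self.provenance) != self.values.shape[1]:
            raise ValueError("provenance length must equal feature dimension")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


# ------------------------------------------------------------ slope feature


@dataclass(frozen=True)
class SlopeFeatureParams:
    """Centre `t_opt` and total span `w` (s) of the haemoglobin slope feature."""

    t_opt: float
    w: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.w / 2 != int(self.w / 2):
            raise ValueError("w must be a positive even number of 1 Hz samples")
        if self.t_opt - self.w / 2 < 0:
            raise ValueError("window extends before stimulus onset")


#: search grids for the nested parameter selection
DEFAULT_TOPT_GRID = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
DEFAULT_W_GRID = (2.0, 4.0, 6.0, 8.0)


def slope_grid(
    epoch_len_s: float = 10.0,
    t_opt_grid=DEFAULT_TOPT_GRID,
    w_grid=DEFAULT_W_GRID,
) -> list[SlopeFeatureParams]:
    """All grid points whose window fits inside the epoch."""
    grid = []
    for t_opt in t_opt_grid:
        for w in w_grid:
            if t_opt - w / 2 >= 0 and t_opt + w / 2 <= epoch_len_s - 1:
                grid.append(SlopeFeatureParams(t_opt, w))
    if not grid:
        raise ValueError("empty slope parameter grid")
    return grid


def slope_feature(epochs: np.ndarray, params: SlopeFeatureParams) -> np.ndarray:
    """Mean haemoglobin rise around `t_opt`:

        f_c = (2/w) * ( sum_{t=t_opt}^{t_opt+w/2} x_c(t)
                        - sum_{t=t_opt-w/2}^{t_opt} x_c(t) )

    with sums over integer 1 Hz samples, both endpoints inclusive.  `epochs`
    has shape (n_trials, n_channels, n_samples) at 1 Hz relative to onset.
    """
    epochs = np.asarray(epochs, float)
    n_samp = epochs.shape[-1]
    t0 = int(round(params.t_opt))
    h = int(round(params.w / 2))
    if t0 - h < 0 or t0 + h > n_samp - 1:
        raise ValueError(
            f"slope window [{t0 - h}, {t0 + h}] exceeds the {n_samp}-sample epoch"
        )
    upper = epochs[..., t0 : t0 + h + 1].sum(axis=-1)
    lower = epochs[..., t0 - h : t0 + 1].sum(axis=-1)
    return (2.0 / params.w) * (upper - lower)


class SlopeFeature(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper: (n_trials, n_channels, n_samples) -> (n_trials, n_channels)."""

    def __init__(self, t_opt: float = 5.0, w: float = 4.0):
        self.t_opt = t_opt
        self.w = w

    def fit(self, X, y=None):
        self.params_ = SlopeFeatureParams(self.t_opt, self.w)
        return self

    def transform(self, X):
        return slope_feature(X, SlopeFeatureParams(self.t_opt, self.w))


# -------------------------------------------------------------- POW feature


@dataclass(frozen=True)
class PowFeatureParams:
    """Welch band-power configuration.

    2 s Hann segments with 50 % overlap give a 0.5 Hz grid; every other
    component (i.e. integer frequencies) in [band_low, band_high] is kept,
    yielding 38 values per electrode for the default 3-40 Hz band.
    """

    band_low: float = 3.0
    band_high: float = 40.0
    segment_s: float = 2.0
    overlap: float = 0.5
    step_hz: float = 1.0


def pow_frequencies(params: PowFeatureParams) -> np.ndarray:
    """The selected frequency components, band_low to band_high inclusive."""
    return np.arange(params.band_low, params.band_high + params.step_hz / 2,
                     params.step_hz)


def pow_feature(
    epochs: np.ndarray, fs: float = 256.0,
    params: PowFeatureParams = PowFeatureParams(),
) -> np.ndarray:
    """Welch PSD features: (n_trials, n_electrodes, n_samples) ->
    (n_trials, n_electrodes, n_selected).  Linear power scale (any log
    scaling is deferred to the z-normalizer)."""
    epochs = np.asarray(epochs, float)
    nper = min(int(round(params.segment_s * fs)), epochs.shape[-1])
    nover = int(round(nper * params.overlap))
    # zero-pad short (truncated-window) segments so the frequency grid always
    # contains the integer-Hz selection
    nfft = max(nper, int(round(fs)))
    f, psd = signal.welch(epochs, fs=fs, window="hann", nperseg=nper,
                          noverlap=nover, nfft=nfft, axis=-1)
    want = pow_frequencies(params)
    if want[0] < f[0] or want[-1] > f[-1]:
        raise ValueError("requested band outside the resolvable range")
    idx = []
    for fw in want:
        j = int(np.argmin(np.abs(f - fw)))
        if abs(f[j] - fw) > 1e-6:
            raise ValueError(
                f"frequency {fw} Hz not on the Welch grid (resolution {f[1]-f[0]:.3g} Hz)"
            )
        idx.append(j)
    return psd[..., idx]


# -------------------------------------------------------------- ERP feature


@dataclass(frozen=True)
class ErpFeatureParams:
    """Median filter length, moving-average length, and downsampling step
    (in samples at 256 Hz)."""

    k_med: int = 5
    k_avg: int = 13
    k_down: int = 13

    def __post_init__(self) -> None:
        if self.k_med % 2 == 0 or self.k_med < 1:
            raise ValueError("k_med must be odd and positive")
        if self.k_down < 1:
            raise ValueError("k_down must be >= 1")


def erp_feature(
    epochs: np.ndarray, params: ErpFeatureParams = ErpFeatureParams(),
    expected_len: int = 256,
) -> np.ndarray:
    """Smoothed, downsampled ERP waveform: median filter (5) -> moving
    average (13) -> keep every 13th sample starting at the first, giving 20
    values per electrode for a 1 s epoch at 256 Hz.

    Edge samples are replicated so constant epochs are preserved exactly.
    """
    epochs = np.asarray(epochs, float)
    if expected_len is not None and epochs.shape[-1] != expected_len:
        raise ValueError(
            f"ERP epoch must have {expected_len} samples, got {epochs.shape[-1]}"
        )
    med = ndimage.median_filter(epochs, size=(1,) * (epochs.ndim - 1) + (params.k_med,),
                                mode="nearest")
    pad = params.k_avg // 2
    padded = np.pad(med, [(0, 0)] * (med.ndim - 1) + [(pad, params.k_avg - 1 - pad)],
                    mode="edge")
    kernel = np.ones(params.k_avg) / params.k_avg
    smooth = np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="valid"), -1, padded
    )
    return smooth[..., :: params.k_down]


class ErpFeature(TransformerMixin, BaseEstimator):
    def __init__(self, k_med: int = 5, k_avg: int = 13, k_down: int = 13):
        self.k_med = k_med
        self.k_avg = k_avg
        self.k_down = k_down

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return erp_feature(X, ErpFeatureParams(self.k_med, self.k_avg, self.k_down))


# ------------------------------------------------------------- z-normalizer


class FeatureStandardizer(TransformerMixin, BaseEstimator):
    """Z-normalization with training-fold statistics.

    Zero-variance (degenerate) features are centered only: their scale is
    set to 1 and flagged in ``degenerate_mask_``.
    """

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] < 2:
            raise ValueError("need >= 2 training trials to standardize")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.degenerate_mask_ = sd <= 1e-12 * max(np.abs(X).max(), 1.0)
        self.scale_ = np.where(self.degenerate_mask_, 1.0, sd)
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        return (X - self.mean_) / self.scale_


def fit_normalizer(train: FeatureMatrix) -> FeatureStandardizer:
    return FeatureStandardizer().fit(train.values)


def apply_normalizer(nz: FeatureStandardizer, fm: FeatureMatrix) -> FeatureMatrix:
    return FeatureMatrix(nz.transform(fm.values), fm.feature_type,
                         fm.provenance, fm.labels)


# ------------------------------------------------- continuous fNIRS feature


def continuous_fnirs_feature(
    window: np.ndarray, elapsed: np.ndarray | None
) -> np.ndarray:
    """Mean of the window minus the mean of the already-elapsed data.

    `window` has shape (n_channels, n_window_samples); `elapsed` holds all
    samples from the segment start up to the window start.  The first window
    of a segment (empty `elapsed`) returns 0 by convention.
    """
    window = np.atleast_2d(np.asarray(window, float))
    if window.shape[-1] == 0:
        raise ValueError("empty window")
    if elapsed is None or np.size(elapsed) == 0:
        return np.zeros(window.shape[0])
    elapsed = np.atleast_2d(np.asarray(elapsed, float))
    return window.mean(axis=-1) - elapsed.mean(axis=-1)


# ------------------------------------------------------ parameter selection


def select_slope_params(
    feature_by_params: dict[SlopeFeatureParams, np.ndarray],
    y: np.ndarray,
    splits: list[tuple[np.ndarray, np.ndarray]],
    classifier_factory,
) -> tuple[SlopeFeatureParams, float]:
    """Pick the grid point maximizing mean split accuracy.

    ``feature_by_params`` maps each grid point to its (n_trials, n_channels)
    feature matrix; `splits` is a list of (train_idx, eval_idx) pairs.  Ties
    are broken by smaller t_opt, then smaller w.  Returns (params, accuracy).
    """
    if not feature_by_params:
        raise ValueError("empty parameter grid")
    best = None
    order = sorted(feature_by_params, key=lambda p: (p.t_opt, p.w))
    for p in order:
        X = feature_by_params[p]
        accs = []
        for tr, ev in splits:
            nz = FeatureStandardizer().fit(X[tr])
            clf = classifier_factory().fit(nz.transform(X[tr]), y[tr])
            accs.append(float((clf.predict(nz.transform(X[ev])) == y[ev]).mean()))
        acc = float(np.mean(accs))
        if best is None or acc > best[1] + 1e-12:
            best = (p, acc)
    return best
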