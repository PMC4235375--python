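"""fNIRS optical preprocessing chain.

Order of operations (fixed): per-channel AC normalization -> cardiac pulse
correction -> 8 s median filter with downsampling to 1 Hz -> optical density
-> modified Beer-Lambert law conversion to HbO/HbR concentration changes ->
common average referencing.  The forward Beer-Lambert map used by the
simulator lives here too, so the inverse pair can be tested against each
other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .montage import MontageSpec

logger = logging.getLogger(__name__)

#: Molar extinction coefficients in 1/(mM*cm) from the Prahl compilation,
#: columns (HbO, HbR), rows (690 nm, 830 nm).  The two wavelengths straddle
#: the isosbestic point, making the system well conditioned.
EXTINCTION_690_830 = np.array(
    [
        [0.27600, 2.05196],  # 690 nm
        [0.97400, 0.69304],  # 830 nm
    ]
)

#: Default differential path-length factor (dimensionless), both wavelengths.
DEFAULT_DPF = (6.0, 6.0)


@dataclass
class MbllParams:
    """Parameters of the (modified) Beer-Lambert relation per channel.

    The relation per wavelength lambda and channel c is

        dOD_lambda = (eps_HbO,lambda * dHbO + eps_HbR,lambda * dHbR) * d_c * DPF_lambda

    with concentrations in mM, distances in cm and eps in 1/(mM*cm).
    """

    distances_cm: np.ndarray
    extinction: np.ndarray = field(default_factory=lambda: EXTINCTION_690_830.copy())
    dpf: tuple[float, float] = DEFAULT_DPF

    def __post_init__(self) -> None:
        self.distances_cm = np.atleast_1d(np.asarray(self.distances_cm, float))
        self.extinction = np.asarray(self.extinction, float)
        if self.extinction.shape != (2, 2) or (self.extinction <= 0).any():
            raise ValueError("extinction must be a positive 2x2 matrix")
        if abs(np.linalg.det(self.extinction)) < 1e-12:
            raise ValueError("extinction matrix is singular")
        if (self.distances_cm <= 0).any():
            raise ValueError("source-detector distances must be positive")

    @classmethod
    def from_montage(cls, montage: MontageSpec, **kw) -> "MbllParams":
        return cls(distances_cm=np.asarray(montage.distances_cm), **kw)


@dataclass
class HemoglobinSeries:
    """Concentration changes (mM) per channel at 1 Hz after preprocessing."""

    hbo: np.ndarray  # (n_channels, n_samples)
    hbr: np.ndarray
    fs: float = 1.0
    bad_channels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, float)
        self.hbr = np.asarray(self.hbr, float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must share a shape")
        if self.bad_channels is None:
            self.bad_channels = np.zeros(self.hbo.shape[0], dtype=bool)


# ----------------------------------------------------------------- stages


def normalize_ac(ac: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Divide each channel/wavelength trace by its temporal mean.

    Returns ``(normalized, bad_channels)``.  Channels whose mean intensity is
    (numerically) zero at either wavelength cannot be normalized; they are
    flagged bad, left as ones, and excluded downstream.
    """
    ac = np.asarray(ac, float)
    mean = ac.mean(axis=-1, keepdims=True)
    scale = np.abs(mean)
    tiny = scale <= 1e-12 * max(np.abs(ac).max(), 1.0)
    bad = tiny.any(axis=0).ravel() if ac.ndim == 3 else np.atleast_1d(tiny.ravel())
    if bad.any():
        logger.warning("flagging %d zero-mean channel(s) as bad", int(bad.sum()))
    safe = np.where(tiny, 1.0, mean)
    out = ac / safe
    if ac.ndim == 3:
        out[:, bad, :] = 1.0
    return out, bad


def detect_cardiac_peak(
    x: np.ndarray, fs: float, band: tuple[float, float] = (0.7, 2.0),
    min_ratio: float = 3.0,
) -> float | None:
    """Locate the dominant cardiac spectral peak of the channel-mean signal.

    Returns the peak frequency (Hz), or None if no point in the band rises
    `min_ratio`-fold above the band's median power.
    """
    mean_sig = x.reshape(-1, x.shape[-1]).mean(axis=0)
    nper = min(len(mean_sig), int(round(fs * 30)))
    f, p = signal.welch(mean_sig, fs=fs, nperseg=nper)
    sel = (f >= band[0]) & (f <= band[1])
    if not sel.any():
        return None
    pb = p[sel]
    med = np.median(pb)
    if med <= 0 or pb.max() < min_ratio * med:
        return None
    return float(f[sel][np.argmax(pb)])


def pulse_correct(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.7, 2.0),
    stop_halfwidth: float = 0.15,
) -> np.ndarray:
    """Remove the cardiac pulsation with a zero-phase second-order band-stop.

    The cardiac frequency is detected on the mean over channels; every
    channel is then notch-filtered at that frequency (+-`stop_halfwidth` Hz,
    applied forward and backward).  Without a detectable cardiac peak the
    data passes through unchanged with a logged warning.
    """
    x = np.asarray(x, float)
    if fs <= 2 * band[1]:
        raise ValueError("sampling rate too low to resolve the cardiac band")
    f0 = detect_cardiac_peak(x, fs, band)
    if f0 is None:
        logger.warning("no cardiac peak detected in %s Hz; pulse correction skipped", band)
        return x.copy()
    q = f0 / (2 * stop_halfwidth)
    b, a = signal.iirnotch(f0, Q=q, fs=fs)
    return signal.filtfilt(b, a, x, axis=-1)


def median_downsample(
    x: np.ndarray,
    fs_in: float = 19.5,
    filter_len_s: float = 8.0,
    rate_out: float = 1.0,
) -> np.ndarray:
    """8 s median filter followed by decimation to `rate_out` Hz.

    The median window (rounded to an odd sample count; 157 samples at
    19.5 Hz) is evaluated at the input sample nearest each output time, with
    edge samples replicated, which is equivalent to filtering the full
    series and then decimating.
    """
    x = np.asarray(x, float)
    n_t = x.shape[-1]
    k = int(round(filter_len_s * fs_in))
    if k % 2 == 0:
        k += 1
    if n_t < k:
        raise ValueError(
            f"input of {n_t} samples is shorter than the {k}-sample median window"
        )
    n_out = int(np.floor(n_t / fs_in * rate_out))
    centers = np.round(np.arange(n_out) / rate_out * fs_in).astype(int)
    half = k // 2
    idx = np.clip(centers[:, None] + np.arange(-half, half + 1)[None, :], 0, n_t - 1)
    return np.median(x[..., idx], axis=-1)


def intensity_to_od(x: np.ndarray) -> np.ndarray:
    """Optical density change of a mean-normalized intensity: -log10(I/I0)."""
    x = np.asarray(x, float)
    return -np.log10(np.clip(x, 1e-12, None))


def mbll_forward(
    hbo: np.ndarray, hbr: np.ndarray, params: MbllParams
) -> np.ndarray:
    """Concentration changes -> optical density changes, shape (2, n_ch, n_t)."""
    hbo = np.atleast_2d(np.asarray(hbo, float))
    hbr = np.atleast_2d(np.asarray(hbr, float))
    e = params.extinction
    d = params.distances_cm[:, None]
    od = np.empty((2,) + hbo.shape)
    for w in range(2):
        od[w] = (e[w, 0] * hbo + e[w, 1] * hbr) * d * params.dpf[w]
    return od


def mbll_convert(od: np.ndarray, params: MbllParams) -> tuple[np.ndarray, np.ndarray]:
    """Optical density changes -> (dHbO, dHbR); exact inverse of `mbll_forward`."""
    od = np.asarray(od, float)
    if od.ndim != 3 or od.shape[0] != 2:
        raise ValueError("od must have shape (2, n_channels, n_samples)")
    einv = np.linalg.inv(params.extinction)
    d = params.distances_cm[:, None]
    scaled = np.stack([od[w] / (d * params.dpf[w]) for w in range(2)])
    hbo = einv[0, 0] * scaled[0] + einv[0, 1] * scaled[1]
    hbr = einv[1, 0] * scaled[0] + einv[1, 1] * scaled[1]
    return hbo, hbr


def common_average_reference(x: np.ndarray, channel_mask: np.ndarray | None = None) -> np.ndarray:
    """Subtract the across-channel mean from each channel at every time point.

    `channel_mask` optionally restricts which channels enter the mean (bad
    channels are excluded); the subtraction is still applied to all rows.
    """
    x = np.asarray(x, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("common average referencing needs >= 2 channels")
    rows = x if channel_mask is None else x[np.asarray(channel_mask, bool)]
    if rows.shape[0] < 2:
        raise ValueError("fewer than 2 usable channels for referencing")
    return x - rows.mean(axis=0, keepdims=True)


def preprocess_fnirs(
    fnirs_ac: np.ndarray,
    params: MbllParams,
    fs_in: float = 19.5,
    pulse_correction: bool = True,
) -> HemoglobinSeries:
    """Run the full optical chain on raw AC intensities (2, n_ch, n_samples)."""
    x, bad = normalize_ac(fnirs_ac)
    if pulse_correction:
        x = pulse_correct(x, fs_in)
    x = median_downsample(x, fs_in=fs_in)
    od = intensity_to_od(x)
    hbo, hbr = mbll_convert(od, params)
    good = ~bad
    hbo = common_average_reference(hbo, good)
    hbr = common_average_reference(hbr, good)
    return HemoglobinSeries(hbo=hbo, hbr=hbr, fs=1.0, bad_channels=bad)
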