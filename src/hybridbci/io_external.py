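"""Import of externally recorded data: SNIRF (fNIRS), EDF (EEG), CSV events.

The SNIRF reader is a focused h5py-based reader of the subset of the SNIRF
HDF5 schema needed here (``/nirs/data1/dataTimeSeries``, ``time`` and the
per-column ``measurementList``); EDF files are read through MNE.  Imported
signals are aligned and resampled onto the session grid (19.5 Hz fNIRS,
256 Hz EEG) and channels are mapped onto the montage.
"""

from __future__ import annotations

import logging

import h5py
import numpy as np

from .events import EventSchedule
from .montage import MontageSpec, default_montage
from .session import EEG_FS, FNIRS_FS, Session

logger = logging.getLogger(__name__)


class MontageError(ValueError):
    """Raised when imported channels cannot be mapped onto the montage."""


def read_snirf(path, montage: MontageSpec) -> tuple[np.ndarray, float]:
    """Read two-wavelength AC intensities from a SNIRF file.

    Measurement columns are grouped by wavelength index and ordered by
    (source, detector); each wavelength must supply at least the montage's
    channel count.  Surplus channels are dropped with a warning.
    Returns ``(ac, fs)`` with ac shaped (2, n_channels, n_samples).
    """
    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise MontageError(f"{path}: no /nirs group (not a SNIRF file?)")
        nirs = f["nirs"]
        data = nirs["data1"]
        ts = np.asarray(data["dataTimeSeries"][()], float)  # (n_t, n_meas)
        time = np.asarray(data["time"][()], float).ravel()
        cols: dict[int, list[tuple[int, int, int]]] = {}
        for key in sorted(k for k in data.keys() if k.startswith("measurementList")):
            ml = data[key]
            idx = int(key[len("measurementList"):]) - 1
            w = int(np.asarray(ml["wavelengthIndex"][()]).ravel()[0])
            s = int(np.asarray(ml["sourceIndex"][()]).ravel()[0])
            d = int(np.asarray(ml["detectorIndex"][()]).ravel()[0])
            cols.setdefault(w, []).append((s, d, idx))
    if len(time) > 1:
        dt = np.diff(time)
        fs = float(1.0 / np.median(dt))
    else:
        fs = FNIRS_FS
    n_c = montage.n_channels
    if sorted(cols) != [1, 2]:
        raise MontageError(f"expected wavelength indices 1 and 2, got {sorted(cols)}")
    ac = []
    for w in (1, 2):
        chans = sorted(cols[w])
        if len(chans) < n_c:
            raise MontageError(
                f"wavelength {w} supplies {len(chans)} channels; montage needs {n_c}"
            )
        if len(chans) > n_c:
            logger.warning("dropping %d unmapped channels at wavelength %d",
                           len(chans) - n_c, w)
        ac.append(ts[:, [c[2] for c in chans[:n_c]]].T)
    return np.stack(ac), fs


def read_edf(path, montage: MontageSpec) -> tuple[np.ndarray, float]:
    """Read EEG voltages (uV) for the montage electrodes from an EDF file.

    Raises MontageError naming every missing required electrode.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    have = {name.strip(): i for i, name in enumerate(raw.ch_names)}
    missing = [e for e in montage.eeg_electrodes if e not in have]
    if missing:
        raise MontageError(f"EDF is missing required electrodes: {missing}")
    data = raw.get_data(picks=[have[e] for e in montage.eeg_electrodes])
    return data * 1e6, float(raw.info["sfreq"])  # MNE loads volts


def _resample_linear(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Linear-interpolation resampling onto the target uniform grid."""
    if abs(fs_in - fs_out) < 1e-6:
        return x
    n_out = int(np.floor(x.shape[-1] / fs_in * fs_out))
    t_out = np.arange(n_out) / fs_out
    t_in = np.arange(x.shape[-1]) / fs_in
    flat = x.reshape(-1, x.shape[-1])
    out = np.stack([np.interp(t_out, t_in, row) for row in flat])
    return out.reshape(x.shape[:-1] + (n_out,))


def import_external(
    fnirs_path,
    eeg_path,
    schedule_path,
    montage: MontageSpec | None = None,
    subject_id: str = "imported",
) -> Session:
    """Build a Session from SNIRF + EDF + CSV event files.

    Signals are resampled to the 19.5 Hz / 256 Hz session grids; schedule
    validation errors (overlaps, unknown labels) propagate from the CSV
    parser.
    """
    montage = montage or default_montage()
    schedule = EventSchedule.from_csv(schedule_path)
    ac, fs_f = read_snirf(fnirs_path, montage)
    eeg, fs_e = read_edf(eeg_path, montage)
    ac = _resample_linear(ac, fs_f, FNIRS_FS)
    eeg = _resample_linear(eeg, fs_e, EEG_FS)
    return Session(
        subject_id=subject_id,
        fnirs_ac=ac,
        eeg=eeg,
        schedule=schedule,
        montage=montage,
        provenance={"import_fnirs": str(fnirs_path), "import_eeg": str(eeg_path)},
    )


def write_minimal_snirf(path, ac: np.ndarray, fs: float = FNIRS_FS) -> None:
    """Write a minimal, synthetic SNIRF file (the subset `read_snirf` reads).

    Intended for fixtures and round-trip checks, not as a complete SNIRF
    exporter: only dataTimeSeries, time and the per-column measurementList
    entries are emitted.
    """
    ac = np.asarray(ac, float)
    n_w, n_c, n_t = ac.shape
    ts = np.concatenate([ac[w].T for w in range(n_w)], axis=1)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        data = f.create_group("nirs/data1")
        data.create_dataset("dataTimeSeries", data=ts)
        data.create_dataset("time", data=np.arange(n_t) / fs)
        col = 1
        for w in range(n_w):
            for c in range(n_c):
                ml = data.create_group(f"measurementList{col}")
                ml.create_dataset("sourceIndex", data=c + 1)
                ml.create_dataset("detectorIndex", data=1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                col += 1
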