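"""The multimodal Session container and its on-disk HDF5 format.

A Session bundles a synchronized pair of recordings (two-wavelength fNIRS AC
intensities at 19.5 Hz and EEG voltages at 256 Hz), the stimulus schedule,
the montage, and provenance.  On disk a session is a single HDF5 file:

    /fnirs/ac          float64 (2, n_channels, n_samples)   attrs: fs_hz
    /eeg/raw           float64 (n_electrodes, n_samples)    attrs: fs_hz
    /events/{onset_s,duration_s,label,block,kind}           parallel 1-D arrays
    /montage           attrs: channels_per_probe, probes, eeg_electrodes,
                       wavelengths_nm; dataset distances_cm
    /provenance        attrs: free-form scalar metadata (seed, version, ...)
    root attrs: schema_version, subject_id
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .events import EventSchedule, _COLUMNS
from .montage import MontageSpec

FNIRS_FS = 19.5
EEG_FS = 256.0

SCHEMA_VERSION = 1


class SessionFormatError(IOError):
    """Raised when an on-disk session cannot be read."""


@dataclass
class Session:
    """A synchronized multimodal recording for one subject.

    ``fnirs_ac`` has shape (2 wavelengths, n_channels, n_samples) at 19.5 Hz;
    ``eeg`` has shape (n_electrodes, n_samples) at 256 Hz.  Both signal blocks
    must cover the schedule's full time span.
    """

    subject_id: str
    fnirs_ac: np.ndarray
    eeg: np.ndarray
    schedule: EventSchedule
    montage: MontageSpec
    provenance: dict = field(default_factory=dict)
    fnirs_fs: float = FNIRS_FS
    eeg_fs: float = EEG_FS

    def __post_init__(self) -> None:
        self.fnirs_ac = np.asarray(self.fnirs_ac, dtype=float)
        self.eeg = np.asarray(self.eeg, dtype=float)
        if self.fnirs_ac.ndim != 3 or self.fnirs_ac.shape[0] != 2:
            raise ValueError("fnirs_ac must have shape (2, n_channels, n_samples)")
        if self.fnirs_ac.shape[1] != self.montage.n_channels:
            raise ValueError(
                f"fnirs_ac has {self.fnirs_ac.shape[1]} channels, montage expects "
                f"{self.montage.n_channels}"
            )
        if self.eeg.ndim != 2 or self.eeg.shape[0] != self.montage.n_electrodes:
            raise ValueError("eeg must have shape (n_electrodes, n_samples)")
        if not (np.isfinite(self.fnirs_ac).all() and np.isfinite(self.eeg).all()):
            raise ValueError("signals contain non-finite samples")
        end = self.schedule.end_time
        if self.fnirs_duration < end - 1e-9 or self.eeg_duration < end - 1e-9:
            raise ValueError("signals do not cover the schedule's time span")

    @property
    def fnirs_duration(self) -> float:
        return self.fnirs_ac.shape[2] / self.fnirs_fs

    @property
    def eeg_duration(self) -> float:
        return self.eeg.shape[1] / self.eeg_fs


# ---------------------------------------------------------------------- I/O


def save_session(session: Session, path) -> None:
    """Write a session to `path` (HDF5).  Round-trip is bit-exact."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["subject_id"] = session.subject_id
        g = f.create_group("fnirs")
        d = g.create_dataset("ac", data=session.fnirs_ac)
        d.attrs["fs_hz"] = session.fnirs_fs
        g = f.create_group("eeg")
        d = g.create_dataset("raw", data=session.eeg)
        d.attrs["fs_hz"] = session.eeg_fs
        g = f.create_group("events")
        ev = session.schedule.events
        for col in _COLUMNS:
            vals = ev[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind in "U":
                vals = np.asarray([str(v) for v in vals], dtype="S")
            g.create_dataset(col, data=vals)
        g = f.create_group("montage")
        m = session.montage
        g.attrs["channels_per_probe"] = np.asarray(m.channels_per_probe)
        g.attrs["probes"] = [p.encode() for p in m.probes]
        g.attrs["eeg_electrodes"] = [e.encode() for e in m.eeg_electrodes]
        g.attrs["wavelengths_nm"] = np.asarray(m.wavelengths_nm)
        g.create_dataset("distances_cm", data=np.asarray(m.distances_cm))
        g = f.create_group("provenance")
        for k, v in session.provenance.items():
            g.attrs[str(k)] = v


def load_session(path) -> Session:
    """Read a session written by `save_session`.

    Raises ``SessionFormatError`` on truncated files or unknown schema
    versions; never returns a partial object.
    """
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise SessionFormatError(f"cannot open session file {path}: {e}") from e
    with f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SessionFormatError(
                f"unknown session schema version {version!r} (expected {SCHEMA_VERSION})"
            )
        try:
            fnirs = f["fnirs/ac"][()]
            fnirs_fs = float(f["fnirs/ac"].attrs["fs_hz"])
            eeg = f["eeg/raw"][()]
            eeg_fs = float(f["eeg/raw"].attrs["fs_hz"])
            ev = {}
            for col in _COLUMNS:
                vals = f["events"][col][()]
                if vals.dtype.kind == "S":
                    vals = vals.astype("U")
                ev[col] = vals
            mg = f["montage"]
            montage = MontageSpec(
                channels_per_probe=tuple(int(n) for n in mg.attrs["channels_per_probe"]),
                probes=tuple(p.decode() if isinstance(p, bytes) else str(p) for p in mg.attrs["probes"]),
                distances_cm=tuple(float(d) for d in mg["distances_cm"][()]),
                eeg_electrodes=tuple(e.decode() if isinstance(e, bytes) else str(e) for e in mg.attrs["eeg_electrodes"]),
                wavelengths_nm=tuple(float(w) for w in mg.attrs["wavelengths_nm"]),
            )
            prov = {k: _plain(v) for k, v in f["provenance"].attrs.items()}
            subject_id = str(f.attrs["subject_id"])
        except KeyError as e:
            raise SessionFormatError(f"session file {path} is incomplete: {e}") from e
    schedule = EventSchedule(pd.DataFrame(ev))
    return Session(
        subject_id=subject_id,
        fnirs_ac=fnirs,
        eeg=eeg,
        schedule=schedule,
        montage=montage,
        provenance=prov,
        fnirs_fs=fnirs_fs,
        eeg_fs=eeg_fs,
    )


def _plain(v):
    """Convert h5py attribute values back to plain Python scalars/strings."""
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.generic):
        return v.item()
    return v
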