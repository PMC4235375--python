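"""Sensor montage description for the hybrid fNIRS-EEG recording setup.

The recording geometry consists of three rigid fNIRS probes (one over the
occipital cortex, one over each temporal lobe) built from overlapping
multi-distance source-detector channels, plus 10 analysis EEG electrodes
(after referencing to the mastoids M1/M2).  The montage is configured by
per-probe channel counts and per-channel source-detector distances; the
exact geometric enumeration of the overlapping channels is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Probe names in canonical order.
PROBES = ("occipital", "left_temporal", "right_temporal")

#: EEG electrodes available for analysis after M1/M2 referencing.
EEG_ELECTRODES = ("Fz", "Cz", "Pz", "Oz", "O1", "O2", "FT7", "FT8", "TP7", "TP8")

#: Electrodes over the visual cortex.
OCCIPITAL_ELECTRODES = ("Oz", "O1", "O2")

#: Frontal-most electrode, used as the blink proxy site.
FRONTAL_ELECTRODE = "Fz"

#: Valid source-detector distance range in cm.
DISTANCE_RANGE_CM = (1.7, 2.5)


@dataclass(frozen=True)
class MontageSpec:
    """Immutable description of the fNIRS probe layout and EEG electrode set.

    Parameters
    ----------
    channels_per_probe
        Number of fNIRS channels on each probe, ordered as `probes`.
        The study montage uses (60, 55, 55) for a total of 170 channels.
    distances_cm
        Source-detector distance of every channel (cm), concatenated in
        probe order.  Must lie within ``DISTANCE_RANGE_CM``.
    wavelengths_nm
        The two laser wavelengths; concentration conversion relies on one
        wavelength on each side of the haemoglobin isosbestic point.
    """

    channels_per_probe: tuple[int, ...] = (60, 55, 55)
    probes: tuple[str, ...] = PROBES
    distances_cm: tuple[float, ...] = ()
    eeg_electrodes: tuple[str, ...] = EEG_ELECTRODES
    wavelengths_nm: tuple[float, float] = (690.0, 830.0)

    def __post_init__(self) -> None:
        if len(self.channels_per_probe) != len(self.probes):
            raise ValueError("channels_per_probe must match probes")
        if any(n < 1 for n in self.channels_per_probe):
            raise ValueError("each probe needs at least one channel")
        if not self.distances_cm:
            # deterministic default: sweep the allowed range within each probe
            d = []
            lo, hi = DISTANCE_RANGE_CM
            for n in self.channels_per_probe:
                d.extend(np.linspace(lo, hi, n).round(4).tolist())
            object.__setattr__(self, "distances_cm", tuple(d))
        if len(self.distances_cm) != self.n_channels:
            raise ValueError(
                f"distances_cm has {len(self.distances_cm)} entries, "
                f"expected {self.n_channels}"
            )
        lo, hi = DISTANCE_RANGE_CM
        dist = np.asarray(self.distances_cm)
        if dist.min() < lo - 1e-9 or dist.max() > hi + 1e-9:
            raise ValueError(f"source-detector distances must lie in [{lo}, {hi}] cm")
        if len(self.wavelengths_nm) != 2:
            raise ValueError("exactly two wavelengths required")

    @property
    def n_channels(self) -> int:
        """Total fNIRS channel count across all probes."""
        return int(sum(self.channels_per_probe))

    @property
    def n_electrodes(self) -> int:
        return len(self.eeg_electrodes)

    @property
    def channel_probe(self) -> np.ndarray:
        """Probe index of every fNIRS channel (each channel maps to one probe)."""
        return np.repeat(
            np.arange(len(self.probes)), np.asarray(self.channels_per_probe)
        )

    def probe_channels(self, probe: str) -> np.ndarray:
        """Indices of the channels belonging to `probe`."""
        if probe not in self.probes:
            raise KeyError(f"unknown probe {probe!r}")
        return np.flatnonzero(self.channel_probe == self.probes.index(probe))

    def electrode_index(self, name: str) -> int:
        try:
            return self.eeg_electrodes.index(name)
        except ValueError:
            raise KeyError(f"electrode {name!r} not in montage") from None


def default_montage() -> MontageSpec:
    """The full study montage: 60 + 55 + 55 = 170 fNIRS channels, 10 electrodes."""
    return MontageSpec()


def reduced_montage(channels_per_probe: tuple[int, int, int] = (6, 6, 6)) -> MontageSpec:
    """A small montage with the same probe structure, for fast experiments."""
    return MontageSpec(channels_per_probe=channels_per_probe)
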