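"""Shared fixtures: small synthetic cohorts, prepared (preprocessed) views,
and a minimal EDF writer for import tests.

Everything is generated programmatically at test time from fixed seeds.
"""

from __future__ import annotations

import struct
import warnings

import numpy as np
import pytest

from hybridbci.montage import MontageSpec
from hybridbci.pipeline import make_fixtures, prepare_session
from hybridbci.simulate import CohortModels, SimulationConfig, generate_cohort

warnings.filterwarnings("ignore", message=".*FastICA did not converge.*")


@pytest.fixture(scope="session")
def montage6() -> MontageSpec:
    return MontageSpec(channels_per_probe=(6, 6, 6))


@pytest.fixture(scope="session")
def fixture_cohort(montage6):
    """Two subjects, 8 trials per label, 6 channels per probe."""
    return make_fixtures(seed=7)


@pytest.fixture(scope="session")
def prepared_small(fixture_cohort):
    return [prepare_session(s, seed=i) for i, s in enumerate(fixture_cohort)]


@pytest.fixture(scope="session")
def cohort12(montage6):
    """The study-scale synthetic cohort at reduced channel count:
    12 subjects, 30 trials per label, 6 fNIRS channels per probe."""
    cfg = SimulationConfig(n_subjects=12, trials_per_label=30)
    return generate_cohort(cfg, CohortModels.default(montage6), montage6, seed=11)


@pytest.fixture(scope="session")
def prepared12(cohort12):
    return [prepare_session(s, seed=i) for i, s in enumerate(cohort12)]


def write_minimal_edf(path, data_uv: np.ndarray, fs: float, ch_names) -> None:
    """Write a tiny EDF file (synthetic; int16, 1 s records, uV units)."""
    n_ch, n_t = data_uv.shape
    spr = int(round(fs))
    n_rec = n_t // spr
    phys = 1000.0

    def pad(s, n):
        return s.encode("ascii")[:n].ljust(n)

    hdr = b"".join([
        pad("0", 8), pad("synthetic", 80), pad("synthetic", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 * (n_ch + 1)), 8), pad("", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(n_ch), 4),
    ])
    fields = [
        ("%s", [str(c) for c in ch_names], 16),
        ("%s", ["" for _ in ch_names], 80),
        ("%s", ["uV" for _ in ch_names], 8),
        ("%s", [str(-phys) for _ in ch_names], 8),
        ("%s", [str(phys) for _ in ch_names], 8),
        ("%s", ["-32768" for _ in ch_names], 8),
        ("%s", ["32767" for _ in ch_names], 8),
        ("%s", ["" for _ in ch_names], 80),
        ("%s", [str(spr) for _ in ch_names], 8),
        ("%s", ["" for _ in ch_names], 32),
    ]
    for _, vals, width in fields:
        hdr += b"".join(pad(v, width) for v in vals)
    scale = 32767 / phys
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for c in range(n_ch):
                seg = np.clip(data_uv[c, r * spr:(r + 1) * spr] * scale,
                              -32768, 32767).astype("<i2")
                fh.write(struct.pack(f"<{spr}h", *seg.tolist()))
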