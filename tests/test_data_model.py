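"""Containers, epoching, windowing, and the on-disk session format."""

import numpy as np
import pandas as pd
import pytest

from hybridbci.epochs import (
    DEFAULT_POLICIES,
    TrialSet,
    epoch_trials,
    extract_epochs,
    segment_windows,
)
from hybridbci.events import EventSchedule, ScheduleError
from hybridbci.montage import MontageSpec, default_montage
from hybridbci.session import SessionFormatError, load_session, save_session


# ------------------------------------------------------------------ montage


class TestMontage:
    def test_default_totals(self):
        m = default_montage()
        assert m.n_channels == 170
        assert m.channels_per_probe == (60, 55, 55)
        assert m.n_electrodes == 10

    def test_every_channel_maps_to_one_probe(self):
        m = default_montage()
        probes = m.channel_probe
        assert len(probes) == m.n_channels
        counts = np.bincount(probes, minlength=3)
        assert tuple(counts) == m.channels_per_probe

    def test_distances_within_range(self):
        m = default_montage()
        d = np.asarray(m.distances_cm)
        assert d.min() >= 1.7 and d.max() <= 2.5

    def test_out_of_range_distance_rejected(self):
        with pytest.raises(ValueError, match="distances"):
            MontageSpec(channels_per_probe=(2, 2, 2),
                        distances_cm=(1.0, 2.0, 2.0, 2.0, 2.0, 2.0))


# ------------------------------------------------------------------ windows


class TestWindowing:
    @pytest.mark.parametrize("w_len,expected", [(1, 120), (2, 60), (4, 30),
                                                (8, 15), (16, 8)])
    def test_reference_window_counts(self, w_len, expected):
        """A 60 s clip yields 120/60/30/15/8 windows for 1-16 s lengths."""
        assert len(segment_windows(60.0, w_len)) == expected

    @pytest.mark.parametrize("w_len", [1, 2, 4, 8, 16])
    def test_count_matches_enumeration_oracle(self, w_len):
        """Count equals placing starts at k*w_len/2 while start < duration."""
        for duration in range(max(1, int(np.ceil(w_len / 2))), 121):
            ws = segment_windows(float(duration), float(w_len))
            k, starts = 0, []
            while k * w_len / 2 < duration - 1e-9:
                starts.append(k * w_len / 2)
                k += 1
            assert len(ws) == len(starts)
            np.testing.assert_allclose(ws.starts, starts)

    def test_truncated_single_window(self):
        ws = segment_windows(10.0, 20.0)
        assert len(ws) == 1
        assert ws.stops[0] == 10.0

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            segment_windows(60.0, 0.0)
        with pytest.raises(ValueError):
            segment_windows(60.0, -1.0)


# ------------------------------------------------------------------ epochs


def _toy_schedule(onsets, labels, duration=12.0):
    recs = [dict(onset_s=o, duration_s=duration, label=l, block=2, kind="trial")
            for o, l in zip(onsets, labels)]
    return EventSchedule(pd.DataFrame.from_records(recs))


class TestEpoching:
    def test_sample_count_arithmetic(self):
        """10 s at 1 Hz -> 10 samples; 1 s ERP at 256 Hz -> 256 samples."""
        sched = _toy_schedule([10.0, 40.0], ["AUD", "VIS"])
        hemo = np.zeros((3, 80))
        eeg = np.zeros((2, 80 * 256))
        ts = epoch_trials(sched, {"hbo": (hemo, 1.0), "erp": (eeg, 256.0)},
                          policies={"hbo": (-2.0, 10.0), "erp": (-0.1, 1.0)})
        assert len(ts) == 2
        assert ts.blocks["hbo"].post_onset().shape[-1] == 10
        assert ts.blocks["erp"].post_onset().shape[-1] == 256

    def test_trial_count_matches_schedule(self, prepared_small):
        p = prepared_small[0]
        counts = pd.Series(p.trials.labels).value_counts()
        assert len(p.trials) == 32
        assert set(counts) == {8}

    def test_overflow_event_dropped_not_clipped(self):
        sched = _toy_schedule([5.0, 72.0], ["AUD", "VIS"])  # 2nd overruns
        hemo = np.zeros((3, 80))
        ts = epoch_trials(sched, {"hbo": (hemo, 1.0)},
                          policies={"hbo": (-2.0, 10.0)})
        assert len(ts) == 1
        assert ts.labels.tolist() == ["AUD"]

    def test_zero_events_empty_trialset(self):
        ts = epoch_trials(EventSchedule.empty(), {"hbo": (np.zeros((3, 50)), 1.0)},
                          policies={"hbo": (-2.0, 10.0)})
        assert len(ts) == 0

    def test_translation_equivariance(self):
        """Shifting schedule and signals by dt yields identical epochs."""
        rng = np.random.default_rng(0)
        sig = rng.standard_normal((4, 200))
        sched = _toy_schedule([20.0, 60.0], ["AUD", "VIS"])
        dt = 37.0
        shifted_sig = np.concatenate([np.zeros((4, int(dt))), sig], axis=1)
        a = epoch_trials(sched, {"hbo": (sig, 1.0)}, {"hbo": (-2.0, 10.0)})
        b = epoch_trials(sched.shifted(dt), {"hbo": (shifted_sig, 1.0)},
                         {"hbo": (-2.0, 10.0)})
        np.testing.assert_array_equal(a.blocks["hbo"].data, b.blocks["hbo"].data)

    def test_extract_epochs_half_open(self):
        data = np.arange(20.0)[None, :]
        ep, kept = extract_epochs(data, 1.0, np.array([3.0]), 0.0, 5.0)
        assert kept.all()
        np.testing.assert_array_equal(ep[0, 0], [3, 4, 5, 6, 7])


# ---------------------------------------------------------------- schedules


class TestScheduleValidation:
    def test_overlapping_events_rejected(self):
        with pytest.raises(ScheduleError, match="overlap"):
            _toy_schedule([0.0, 5.0], ["AUD", "VIS"], duration=10.0)

    def test_consecutive_same_label_rejected(self):
        with pytest.raises(ScheduleError, match="consecutive"):
            _toy_schedule([0.0, 20.0], ["AUD", "AUD"])

    def test_csv_round_trip(self, tmp_path):
        sched = _toy_schedule([0.0, 20.0, 40.0], ["AUD", "VIS", "IDLE"])
        path = tmp_path / "events.csv"
        sched.to_csv(path)
        again = EventSchedule.from_csv(path)
        assert again == sched


# ------------------------------------------------------------- session file


class TestSessionIO:
    def test_round_trip_bit_exact(self, fixture_cohort, tmp_path):
        s = fixture_cohort[0]
        path = tmp_path / "s.h5"
        save_session(s, path)
        again = load_session(path)
        np.testing.assert_array_equal(again.fnirs_ac, s.fnirs_ac)
        np.testing.assert_array_equal(again.eeg, s.eeg)
        assert again.schedule == s.schedule
        assert again.subject_id == s.subject_id
        assert again.montage.channels_per_probe == s.montage.channels_per_probe
        assert again.provenance["seed_entropy"] == s.provenance["seed_entropy"]

    def test_truncated_file_is_format_error(self, fixture_cohort, tmp_path):
        s = fixture_cohort[0]
        path = tmp_path / "s.h5"
        save_session(s, path)
        blob = path.read_bytes()
        (tmp_path / "t.h5").write_bytes(blob[: len(blob) // 3])
        with pytest.raises(SessionFormatError):
            load_session(tmp_path / "t.h5")

    def test_unknown_schema_version_rejected(self, fixture_cohort, tmp_path):
        import h5py

        s = fixture_cohort[0]
        path = tmp_path / "s.h5"
        save_session(s, path)
        with h5py.File(path, "a") as f:
            f.attrs["schema_version"] = 99
        with pytest.raises(SessionFormatError, match="schema"):
            load_session(path)

    def test_same_seed_equal_provenance(self, montage6):
        from hybridbci.pipeline import make_fixtures

        a = make_fixtures(seed=3, n_subjects=1, trials_per_label=2)[0]
        b = make_fixtures(seed=3, n_subjects=1, trials_per_label=2)[0]
        assert a.provenance == b.provenance


# ------------------------------------------------------------------ imports


class TestImportExternal:
    def test_snirf_import_maps_all_channels(self, tmp_path, montage6):
        from hybridbci.io_external import read_snirf, write_minimal_snirf

        rng = np.random.default_rng(0)
        ac = rng.uniform(500, 1500, size=(2, montage6.n_channels, 100))
        path = tmp_path / "x.snirf"
        write_minimal_snirf(path, ac, fs=19.5)
        got, fs = read_snirf(path, montage6)
        assert got.shape == ac.shape
        np.testing.assert_allclose(got, ac)
        assert fs == pytest.approx(19.5)

    def test_edf_missing_electrode_names_absence(self, tmp_path, montage6):
        from tests.conftest import write_minimal_edf
        from hybridbci.io_external import MontageError, read_edf

        rng = np.random.default_rng(0)
        names = [e for e in montage6.eeg_electrodes if e != "Oz"]
        data = rng.standard_normal((len(names), 512)) * 20
        path = tmp_path / "x.edf"
        write_minimal_edf(path, data, 256.0, names)
        with pytest.raises(MontageError, match="Oz"):
            read_edf(path, montage6)

    def test_full_import_round_trip(self, tmp_path, montage6):
        from tests.conftest import write_minimal_edf
        from hybridbci.io_external import import_external, write_minimal_snirf

        rng = np.random.default_rng(1)
        dur = 64
        ac = rng.uniform(500, 1500, size=(2, montage6.n_channels,
                                          int(dur * 19.5)))
        eeg = rng.standard_normal((10, dur * 256)) * 20
        sched = _toy_schedule([5.0, 30.0], ["AUD", "VIS"], duration=10.0)
        write_minimal_snirf(tmp_path / "x.snirf", ac, fs=19.5)
        write_minimal_edf(tmp_path / "x.edf", eeg, 256.0,
                          montage6.eeg_electrodes)
        sched.to_csv(tmp_path / "events.csv")
        sess = import_external(tmp_path / "x.snirf", tmp_path / "x.edf",
                               tmp_path / "events.csv", montage6)
        assert sess.fnirs_ac.shape[1] == montage6.n_channels
        assert sess.eeg.shape[0] == 10
        assert sess.schedule == sched

    def test_overlapping_schedule_csv_rejected(self, tmp_path):
        bad = pd.DataFrame({
            "onset_s": [0.0, 5.0], "duration_s": [10.0, 10.0],
            "label": ["AUD", "VIS"], "block": [2, 2],
            "kind": ["trial", "trial"],
        })
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(ScheduleError, match="overlap"):
            EventSchedule.from_csv(path)
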