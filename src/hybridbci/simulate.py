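"""Synthetic multimodal session generator.

Emulates the block design and signal phenomenology of the auditory/visual
perception experiment: five blocks (one with three fixed 60 s continuous
clips, four with randomized stimulus-locked trials), haemodynamic responses
driven per probe and label (VIS -> occipital probe, AUD -> temporal probes,
MIX -> both, IDLE -> none), modality-distinctive ERPs with a positive
deflection near 312 ms, occipital alpha suppressed by visual engagement,
cardiac pulsation in the optical signal and blink artifacts in the EEG.

All generation is a pure function of (config, models, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.stats import gamma as gamma_dist

from .events import LABELS, EventSchedule
from .fnirs import MbllParams, mbll_forward
from .montage import MontageSpec, OCCIPITAL_ELECTRODES, default_montage
from .session import EEG_FS, FNIRS_FS, Session

logger = logging.getLogger(__name__)


class SchedulingError(RuntimeError):
    """Raised when the no-repeat constraint cannot be satisfied."""


# ------------------------------------------------------------------ config


@dataclass
class SimulationConfig:
    """Experimental-design parameters of a synthetic cohort.

    Defaults reproduce the study conditions: 12 subjects, 30 trials per
    label in blocks 2-5, stimulus durations uniform on 12.5 +- 2.5 s, rest
    periods uniform on 20 +- 5 s, and a first block of three 60 s continuous
    clips (AUD, VIS, MIX) separated by 20 s gaps.
    """

    n_subjects: int = 12
    trials_per_label: int = 30
    stim_duration_s: tuple[float, float] = (10.0, 15.0)
    rest_duration_s: tuple[float, float] = (15.0, 25.0)
    continuous_clip_s: float = 60.0
    continuous_gap_s: float = 20.0
    inter_block_gap_s: float = 20.0
    n_trial_blocks: int = 4
    max_schedule_retries: int = 10_000

    def __post_init__(self) -> None:
        for pair in (self.stim_duration_s, self.rest_duration_s):
            if pair[0] <= 0 or pair[1] < pair[0]:
                raise ValueError("duration bounds must be positive and ordered")
        if self.trials_per_label < 1:
            raise ValueError("need at least one trial per label")


@dataclass
class HrfModel:
    """Haemodynamic forward model: double-gamma impulse response plus noise.

    ``hbo_amp_mM`` is the plateau HbO concentration change (mM) that a
    sustained stimulus evokes on a driven probe; HbR mirrors it with
    opposite sign and ``hbr_ratio`` magnitude.  VIS drives the occipital
    probe, AUD the two temporal probes, MIX both, IDLE none.
    """

    peak_s: float = 5.5
    undershoot_peak_s: float = 15.0
    undershoot_ratio: float = 1.0 / 6.0
    hbo_amp_mM: float = 1.0e-3
    hbr_ratio: float = -0.3
    drift_amp_mM: float = 1.0e-3
    drift_period_s: tuple[float, float] = (60.0, 180.0)
    noise_od: float = 4.0e-2
    pulse_freq_hz: tuple[float, float] = (1.0, 1.5)
    pulse_amp: float = 0.01
    subject_sigma: float = 0.3
    #: per-channel sensitivity range: overlapping multi-distance channels
    #: sample the activated cortex unevenly, so evoked amplitudes vary
    channel_gain_range: tuple[float, float] = (0.15, 1.0)
    #: per-label probe drive, amplitude multipliers per probe name
    label_drive: dict = field(default_factory=lambda: {
        "VIS": {"occipital": 1.0},
        "AUD": {"left_temporal": 1.0, "right_temporal": 1.0},
        "MIX": {"occipital": 1.0, "left_temporal": 1.0, "right_temporal": 1.0},
        "IDLE": {},
    })

    def kernel(self, fs: float, length_s: float = 32.0) -> np.ndarray:
        """Double-gamma impulse response, normalized to unit integral so a
        sustained boxcar drive plateaus at the configured amplitude."""
        t = np.arange(int(round(length_s * fs))) / fs
        a1 = 6.0
        g1 = gamma_dist.pdf(t, a1, scale=self.peak_s / (a1 - 1))
        a2 = 16.0
        g2 = gamma_dist.pdf(t, a2, scale=self.undershoot_peak_s / (a2 - 1))
        h = g1 / g1.max() - self.undershoot_ratio * g2 / g2.max()
        return h / (h.sum() / fs)

    def null(self) -> "HrfModel":
        """Copy with all evoked effects removed (noise structure retained)."""
        return replace(self, hbo_amp_mM=0.0)


@dataclass
class ErpTemplate:
    """Per-label, per-electrode event-related waveforms over the first second.

    Defaults plant an early negative deflection near 110 ms and a positive
    P300-like deflection near 330 ms, occipitally dominant for VIS and
    fronto-centrally dominant for AUD; MIX superposes both; IDLE is silent.
    """

    waveforms: dict  # label -> (n_electrodes, n_samples) at fs
    fs: float = EEG_FS
    latency_jitter_s: float = 0.02
    amp_jitter_sigma: float = 0.2

    def __post_init__(self) -> None:
        for lab, w in self.waveforms.items():
            if not np.isfinite(w).all():
                raise ValueError(f"non-finite template for {lab}")

    @property
    def n_samples(self) -> int:
        return next(iter(self.waveforms.values())).shape[1]

    @classmethod
    def default(cls, montage: MontageSpec, amp_uv: float = 12.0) -> "ErpTemplate":
        names = montage.eeg_electrodes
        n_el = len(names)
        n = int(EEG_FS)
        t = np.arange(n) / EEG_FS

        def bump(center, width, amp):
            return amp * np.exp(-0.5 * ((t - center) / width) ** 2)

        occ = np.array([1.0 if e in OCCIPITAL_ELECTRODES else
                        (0.5 if e == "Pz" else 0.15) for e in names])
        # auditory ERP is centro-parietal midline dominant (Pz/Cz, then Fz),
        # clearly distinct from the steeply frontal blink topography
        front_w = {
            "Pz": 1.0, "Cz": 0.95, "Fz": 0.4, "FT7": 0.25, "FT8": 0.25,
            "TP7": 0.3, "TP8": 0.3, "Oz": 0.15, "O1": 0.15, "O2": 0.15,
        }
        front = np.array([front_w.get(e, 0.2) for e in names])
        vis = (occ[:, None] * (bump(0.33, 0.045, amp_uv)
                               - bump(0.11, 0.03, 0.6 * amp_uv))[None, :])
        aud = (front[:, None] * (bump(0.33, 0.05, amp_uv)
                                 - bump(0.10, 0.03, 0.7 * amp_uv))[None, :])
        return cls(waveforms={
            "VIS": vis, "AUD": aud, "MIX": vis + aud,
            "IDLE": np.zeros((n_el, n)),
        })

    @classmethod
    def silent(cls, montage: MontageSpec) -> "ErpTemplate":
        n = int(EEG_FS)
        z = np.zeros((montage.n_electrodes, n))
        return cls(waveforms={lab: z.copy() for lab in LABELS},
                   latency_jitter_s=0.0, amp_jitter_sigma=0.0)


@dataclass
class OscillatoryModel:
    """Background rhythms: 1/f noise plus alpha (9.5 Hz) and beta (18.5 Hz)
    generators whose occipital gain is modulated by the stimulus label, and
    Poisson-timed, frontally weighted blink artifacts.

    The occipital alpha gain ordering AUD >= IDLE > VIS is enforced: visual
    engagement suppresses the idling rhythm while auditory-only stimulation
    leaves it elevated.
    """

    background_uv: float = 7.0
    alpha_freq_hz: float = 9.5
    alpha_amp_uv: float = 6.0
    beta_freq_hz: float = 18.5
    beta_amp_uv: float = 2.0
    alpha_gain: dict = field(default_factory=lambda: {
        "AUD": 1.3, "IDLE": 1.05, "VIS": 0.35, "MIX": 0.45,
    })
    beta_gain: dict = field(default_factory=lambda: {
        "AUD": 1.1, "IDLE": 1.0, "VIS": 0.9, "MIX": 0.95,
    })
    blink_rate_hz: float = 0.15
    blink_amp_uv: float = 100.0
    blink_width_s: float = 0.35

    def __post_init__(self) -> None:
        g = self.alpha_gain
        if not (g["AUD"] >= g["IDLE"] > g["VIS"]):
            raise ValueError("alpha gains must satisfy AUD >= IDLE > VIS")

    def null(self) -> "OscillatoryModel":
        """Copy with label-independent gains and no blinks (background kept)."""
        return replace(
            self,
            alpha_gain={"AUD": 1.0, "IDLE": 1.0, "VIS": 0.999, "MIX": 1.0},
            beta_gain={lab: 1.0 for lab in LABELS},
            blink_rate_hz=0.0,
        )


@dataclass
class CohortModels:
    """Bundle of the three signal models used to generate a cohort."""

    hrf: HrfModel
    erp: ErpTemplate
    osc: OscillatoryModel

    @classmethod
    def default(cls, montage: MontageSpec) -> "CohortModels":
        return cls(HrfModel(), ErpTemplate.default(montage), OscillatoryModel())

    @classmethod
    def null(cls, montage: MontageSpec) -> "CohortModels":
        """No label-dependent effects anywhere: for chance-level calibration."""
        return cls(HrfModel().null(), ErpTemplate.silent(montage),
                   OscillatoryModel().null())

    @classmethod
    def general_activity_only(cls, montage: MontageSpec) -> "CohortModels":
        """Confound construction: AUD, VIS and MIX evoke *identical* responses
        (same probes, same ERP, same alpha change), so nothing distinguishes
        the modalities — only activity vs. rest."""
        drive_all = {"occipital": 1.0, "left_temporal": 1.0, "right_temporal": 1.0}
        hrf = HrfModel(label_drive={
            "VIS": dict(drive_all), "AUD": dict(drive_all),
            "MIX": dict(drive_all), "IDLE": {},
        })
        base = ErpTemplate.default(montage)
        generic = 0.5 * (base.waveforms["AUD"] + base.waveforms["VIS"])
        erp = ErpTemplate(waveforms={
            "AUD": generic, "VIS": generic, "MIX": generic,
            "IDLE": np.zeros_like(generic),
        })
        # oscillations carry (numerically) no label information here; the
        # AUD/VIS gap below is nil but keeps the ordering check satisfied
        osc = OscillatoryModel(
            alpha_gain={"AUD": 1.05, "IDLE": 1.05, "VIS": 1.0499, "MIX": 1.0499},
            beta_gain={lab: 1.0 for lab in LABELS},
        )
        return cls(hrf, erp, osc)


# --------------------------------------------------------------- schedule


def _label_sequence(counts: dict[str, int], rng: np.random.Generator,
                    max_retries: int) -> list[str]:
    """Random label sequence with exact counts and no immediate repeats.

    Built by weighted sequential sampling excluding the previous label;
    dead ends trigger a restart (bounded by `max_retries`).
    """
    total = sum(counts.values())
    if max(counts.values()) > (total + 1) // 2:
        raise SchedulingError("no-repeat constraint unsatisfiable for these counts")
    labels = [lab for lab in counts if counts[lab] > 0]
    for _ in range(max_retries):
        remaining = dict(counts)
        seq: list[str] = []
        prev = None
        ok = True
        for _i in range(total):
            options = [lab for lab in labels if remaining[lab] > 0 and lab != prev]
            if not options:
                ok = False
                break
            weights = np.array([remaining[lab] for lab in options], float)
            lab = options[rng.choice(len(options), p=weights / weights.sum())]
            seq.append(lab)
            remaining[lab] -= 1
            prev = lab
        if ok:
            return seq
    raise SchedulingError(
        f"could not satisfy the no-repeat constraint in {max_retries} attempts"
    )


def generate_schedule(config: SimulationConfig, rng: np.random.Generator
                      ) -> EventSchedule:
    """Sample one session's schedule: block 1 continuous clips followed by
    four trial blocks with randomized order, durations and rests."""
    records = []
    t = 0.0
    for lab in ("AUD", "VIS", "MIX"):
        records.append(dict(onset_s=t, duration_s=config.continuous_clip_s,
                            label=lab, block=1, kind="continuous"))
        t += config.continuous_clip_s + config.continuous_gap_s
    t += config.inter_block_gap_s - config.continuous_gap_s

    counts = {lab: config.trials_per_label for lab in LABELS}
    seq = _label_sequence(counts, rng, config.max_schedule_retries)
    blocks = np.array_split(np.arange(len(seq)), config.n_trial_blocks)
    block_of = np.empty(len(seq), int)
    for bi, idx in enumerate(blocks):
        block_of[idx] = bi + 2
    lo_s, hi_s = config.stim_duration_s
    lo_r, hi_r = config.rest_duration_s
    prev_block = 2
    for i, lab in enumerate(seq):
        if block_of[i] != prev_block:
            t += config.inter_block_gap_s
            prev_block = block_of[i]
        dur = rng.uniform(lo_s, hi_s)
        records.append(dict(onset_s=t, duration_s=dur, label=lab,
                            block=int(block_of[i]), kind="trial"))
        t += dur
        if lab != "IDLE":  # no resting period after IDLE trials
            t += rng.uniform(lo_r, hi_r)
        else:
            t += 2.5  # short gap so prestimulus baselines stay usable
    return EventSchedule(pd.DataFrame.from_records(records))


# ------------------------------------------------------------------ fNIRS


def _label_boxcars(schedule: EventSchedule, fs: float, n_t: float) -> dict:
    t_idx = {}
    for lab in LABELS:
        box = np.zeros(n_t)
        ev = schedule.events[schedule.events["label"] == lab]
        for _, row in ev.iterrows():
            i0 = int(round(row["onset_s"] * fs))
            i1 = int(round((row["onset_s"] + row["duration_s"]) * fs))
            box[i0: min(i1, n_t)] = 1.0
        t_idx[lab] = box
    return t_idx


def simulate_fnirs(
    schedule: EventSchedule,
    hrf: HrfModel,
    montage: MontageSpec,
    rng: np.random.Generator,
    noise: bool = True,
    subject_scale: float = 1.0,
    pad_s: float = 10.0,
    return_truth: bool = False,
):
    """Simulate two-wavelength AC intensities for one session.

    Concentration time-courses are label-gated boxcars convolved with the
    double-gamma kernel plus slow drift, mapped to optical densities by the
    forward Beer-Lambert law and to intensities I = I0 * 10**(-dOD), with a
    multiplicative cardiac oscillation and white optical-density noise.
    """
    fs = FNIRS_FS
    n_t = int(np.ceil((schedule.end_time + pad_s) * fs))
    t = np.arange(n_t) / fs
    kern = hrf.kernel(fs)
    boxes = _label_boxcars(schedule, fs, n_t)
    responses = {
        lab: sp_signal.fftconvolve(box, kern, mode="full")[:n_t] / fs
        for lab, box in boxes.items()
    }
    n_ch = montage.n_channels
    probe_names = [montage.probes[p] for p in montage.channel_probe]
    channel_gain = rng.uniform(*hrf.channel_gain_range, size=n_ch)
    hbo = np.zeros((n_ch, n_t))
    for lab, drive in hrf.label_drive.items():
        if not drive:
            continue
        resp = responses[lab]
        gains = channel_gain * np.array([drive.get(p, 0.0) for p in probe_names])
        hbo += (hrf.hbo_amp_mM * subject_scale) * gains[:, None] * resp[None, :]
    hbr = hrf.hbr_ratio * hbo
    if noise and hrf.drift_amp_mM > 0:
        periods = rng.uniform(*hrf.drift_period_s, size=n_ch)
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        drift = hrf.drift_amp_mM * np.sin(
            2 * np.pi * t[None, :] / periods[:, None] + phases[:, None]
        )
        hbo = hbo + drift
        hbr = hbr + np.abs(hrf.hbr_ratio) * drift * rng.choice([-1.0, 1.0], size=(n_ch, 1))
    params = MbllParams.from_montage(montage)
    od = mbll_forward(hbo, hbr, params)
    if noise and hrf.noise_od > 0:
        od = od + rng.normal(0.0, hrf.noise_od, size=od.shape)
    i0 = rng.uniform(500.0, 2000.0, size=(2, n_ch, 1))
    intensity = i0 * 10.0 ** (-od)
    if hrf.pulse_amp > 0:
        f_pulse = rng.uniform(*hrf.pulse_freq_hz)
        # cardiac pulsation is largely coherent across channels
        phase = (rng.uniform(0, 2 * np.pi)
                 + rng.uniform(-0.3, 0.3, size=(2, n_ch, 1)))
        intensity = intensity * (
            1.0 + hrf.pulse_amp * np.sin(2 * np.pi * f_pulse * t[None, None, :] + phase)
        )
    n_neg = int((intensity <= 0).sum())
    if n_neg:
        logger.warning("clipping %d non-positive intensity sample(s)", n_neg)
        intensity = np.clip(intensity, 1e-9, None)
    if return_truth:
        return intensity, {"hbo": hbo, "hbr": hbr, "fs": fs,
                           "channel_gain": channel_gain}
    return intensity


# -------------------------------------------------------------------- EEG


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """1/f-amplitude noise per row, unit variance."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n=n, axis=1)
    out /= out.std(axis=1, keepdims=True)
    return out


def _narrowband(rng: np.random.Generator, n_t: int, fs: float, freq: float
                ) -> np.ndarray:
    """Unit-RMS narrowband oscillation: a sinusoid with a slowly wandering
    positive envelope and random phase."""
    t = np.arange(n_t) / fs
    phase = rng.uniform(0, 2 * np.pi)
    env = rng.standard_normal(n_t)
    b, a = sp_signal.butter(2, 0.2, fs=fs)
    env = sp_signal.filtfilt(b, a, env)
    env = 1.0 + 0.4 * env / max(env.std(), 1e-12)
    env = np.clip(env, 0.1, None)
    x = env * np.sin(2 * np.pi * freq * t + phase)
    return x / np.sqrt((x**2).mean())


#: relative alpha/beta source strength per electrode (occipitally dominant)
_ALPHA_WEIGHTS = {
    "Oz": 1.0, "O1": 0.95, "O2": 0.95, "Pz": 0.6, "Cz": 0.3,
    "Fz": 0.15, "FT7": 0.25, "FT8": 0.25, "TP7": 0.35, "TP8": 0.35,
}
#: blink topography (steep frontal falloff, as for ocular sources)
_BLINK_WEIGHTS = {
    "Fz": 1.0, "Cz": 0.2, "Pz": 0.08, "Oz": 0.02, "O1": 0.02, "O2": 0.02,
    "FT7": 0.45, "FT8": 0.45, "TP7": 0.06, "TP8": 0.06,
}


def simulate_eeg(
    schedule: EventSchedule,
    erp: ErpTemplate,
    osc: OscillatoryModel,
    montage: MontageSpec,
    rng: np.random.Generator,
    subject_scale: float = 1.0,
    pad_s: float = 10.0,
    return_truth: bool = False,
):
    """Simulate electrode voltages (uV) for one session.

    signal = 1/f background + label-gated alpha/beta oscillations + the ERP
    template at each stimulus onset + Poisson-timed blink artifacts.
    """
    fs = EEG_FS
    n_t = int(np.ceil((schedule.end_time + pad_s) * fs))
    names = montage.eeg_electrodes
    n_el = len(names)
    min_stim = schedule.events["duration_s"].min() if len(schedule.events) else np.inf
    if erp.n_samples / erp.fs > min_stim:
        raise ValueError("ERP template longer than the shortest stimulus")

    x = np.zeros((n_el, n_t))
    if osc.background_uv > 0:
        # volume-conducted background: a few shared 1/f sources mixed across
        # the scalp, plus a small independent sensor-noise floor
        n_src = max(2, n_el // 3)
        mixing = rng.standard_normal((n_el, n_src))
        shared = mixing @ _pink_noise(rng, (n_src, n_t))
        shared *= 1.0 / shared.std(axis=1, keepdims=True)
        x += osc.background_uv * (0.95 * shared
                                  + 0.10 * _pink_noise(rng, (n_el, n_t)))

    boxes = _label_boxcars(schedule, fs, n_t)
    w_alpha = np.array([_ALPHA_WEIGHTS[e] for e in names])
    for freq, amp, gains in (
        (osc.alpha_freq_hz, osc.alpha_amp_uv, osc.alpha_gain),
        (osc.beta_freq_hz, osc.beta_amp_uv, osc.beta_gain),
    ):
        if amp <= 0:
            continue
        carrier = _narrowband(rng, n_t, fs, freq)
        gain_t = np.ones(n_t)
        for lab, box in boxes.items():
            gain_t = np.where(box > 0, gains.get(lab, 1.0), gain_t)
        x += amp * (w_alpha[:, None] * (gain_t * carrier)[None, :])

    blink_truth = np.zeros((n_el, n_t))
    if osc.blink_rate_hz > 0:
        w_blink = np.array([_BLINK_WEIGHTS[e] for e in names])
        n_blinks = rng.poisson(osc.blink_rate_hz * n_t / fs)
        onsets = np.sort(rng.uniform(0, n_t / fs - osc.blink_width_s, size=n_blinks))
        wlen = int(round(osc.blink_width_s * fs))
        shape = 0.5 * (1 - np.cos(2 * np.pi * np.arange(wlen) / wlen))
        for ons in onsets:
            i0 = int(round(ons * fs))
            amp = osc.blink_amp_uv * rng.lognormal(0.0, 0.2)
            blink_truth[:, i0: i0 + wlen] += amp * w_blink[:, None] * shape[None, :wlen]
        x += blink_truth

    trials = schedule.events
    for _, row in trials.iterrows():
        wav = erp.waveforms[row["label"]]
        jitter = (rng.normal(0.0, erp.latency_jitter_s)
                  if erp.latency_jitter_s > 0 else 0.0)
        amp = (np.exp(rng.normal(0.0, erp.amp_jitter_sigma))
               if erp.amp_jitter_sigma > 0 else 1.0)
        i0 = int(round((row["onset_s"] + jitter) * fs))
        if i0 < 0 or i0 + wav.shape[1] > n_t:
            continue
        x[:, i0: i0 + wav.shape[1]] += subject_scale * amp * wav

    if return_truth:
        return x, {"blinks": blink_truth, "fs": fs}
    return x


# ----------------------------------------------------------------- cohort


def generate_session(
    config: SimulationConfig,
    models: CohortModels,
    montage: MontageSpec,
    seed_seq: np.random.SeedSequence,
    subject_id: str,
) -> Session:
    """Generate one subject's session from a dedicated seed sequence."""
    ss_sched, ss_fx, ss_fnirs, ss_eeg = seed_seq.spawn(4)
    rng_fx = np.random.default_rng(ss_fx)
    scale_fnirs = float(np.exp(rng_fx.normal(0.0, models.hrf.subject_sigma)))
    scale_eeg = float(np.exp(rng_fx.normal(0.0, models.hrf.subject_sigma)))
    schedule = generate_schedule(config, np.random.default_rng(ss_sched))
    fnirs = simulate_fnirs(schedule, models.hrf, montage,
                           np.random.default_rng(ss_fnirs),
                           subject_scale=scale_fnirs)
    eeg = simulate_eeg(schedule, models.erp, models.osc, montage,
                       np.random.default_rng(ss_eeg),
                       subject_scale=scale_eeg)
    return Session(
        subject_id=subject_id,
        fnirs_ac=fnirs,
        eeg=eeg,
        schedule=schedule,
        montage=montage,
        provenance={"generator": "hybridbci.simulate",
                    "seed_entropy": str(seed_seq.entropy),
                    "subject_scale_fnirs": scale_fnirs,
                    "subject_scale_eeg": scale_eeg},
    )


def generate_cohort(
    config: SimulationConfig,
    models: CohortModels | None = None,
    montage: MontageSpec | None = None,
    seed: int = 0,
) -> list[Session]:
    """Generate `config.n_subjects` sessions with per-subject seeds derived
    deterministically from the master seed."""
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    montage = montage or default_montage()
    models = models or CohortModels.default(montage)
    root = np.random.SeedSequence(seed)
    return [
        generate_session(config, models, montage, child, f"S{i + 1:02d}")
        for i, child in enumerate(root.spawn(config.n_subjects))
    ]
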