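"""Synthetic fetal cohorts: EEG, haemodynamics and blood gases under the
repeated umbilical-cord-occlusion protocol.

No public recording of this preparation exists, so this generator is the
canonical input source of the pipeline.  It is phenomenological, not
biophysical: each signal reproduces the *statistical structure* the analysis
assumes rather than any cardiovascular mechanism.

EEG.  Four monopolar channels (left/right frontal and parietal) at 256 Hz,
band-limited 0.5–70 Hz.  Each fronto- or parieto-pair is built as a shared
"common" component plus/minus half a "difference" component, so the bipolar
derivation recovered downstream equals the difference component exactly and
its amplitude is directly controllable.  Background activity is coloured
noise shaped by a band/relative-power table; per phase, the band edges are
multiplied by a slowing factor (< 1 shifts power downward) and the amplitude
by a scale factor, emulating the progressive background slowing and amplitude
loss of worsening hypoxia.  During each occlusion the neural signal is
scaled, after a configurable latency, by a phase-specific suppression depth
(fraction of amplitude retained), with raised-cosine ramps; damped ~1-Hz
high-amplitude transient waves may be added at occlusion onset and release.
An additive band-limited noise floor represents the acquisition chain.

Haemodynamics.  Heart rate falls to a phase-specific bradycardia level during
each occlusion and recovers between; mean blood pressure rises during pauses
(phase-dependent hypertension) and, in the severe phase, collapses during
occlusions.  Blood gases follow a dense latent trajectory interpolating
per-phase targets; samples are drawn at the stability midpoint and the
midpoint of the last pause of each phase, which is also where the pH < 6.90
stop rule can fire.

Cohorts.  ``simulate_cohort`` draws per-subject parameter jitter from named
substreams of one master seed, including a latent "vulnerability" factor that
couples deeper EEG suppression to stronger bradycardia, occlusion hypotension
and acidosis — the couplings the correlation analysis is meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .features import DEFAULT_CHANNELS, EEGRecording
from .protocol import (
    OCCLUSION,
    OCCLUSION_PHASES,
    PAUSE,
    PHASES,
    STABILITY,
    ProtocolConfig,
    ProtocolSchedule,
    apply_stop_rule,
    build_protocol,
)
from .rng import derive_seed, substream

GAS_COLUMNS = ("ph", "pco2_mmHg", "po2_mmHg", "lactate_mmol_l")


@dataclass(frozen=True)
class SubjectSimConfig:
    """All knobs of one simulated fetus; ``seed`` fully determines the draws.

    Default levels are calibrated to the study cohort's reported medians
    (stability pH 7.39 falling to 6.98 at the severe phase's last pause,
    stability heart rate 186 bpm with per-occlusion bradycardia at 85 bpm in
    the mild phase, per-occlusion mean blood pressure collapsing to 37 mmHg
    in the severe phase) and to a severity ladder of per-occlusion amplitude
    retention 0.8/0.5/0.1 for phases A/B/C.
    """

    seed: int = 0
    fs_hz: float = 256.0
    # (low_hz, high_hz, relative_power) rows; powers need not sum to 1.
    baseline_spectrum: tuple[tuple[float, float, float], ...] = (
        (0.5, 3.0, 0.40),
        (3.0, 6.0, 0.38),
        (6.0, 10.0, 0.17),
        (10.0, 16.0, 0.04),
        (16.0, 30.0, 0.01),
    )
    baseline_amplitude_uV: float = 15.0  # RMS of each bipolar derivation in stability
    common_mode_ratio: float = 1.0  # common-component RMS relative to baseline amplitude
    suppression_depth: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.8, "B": 0.5, "C": 0.1}
    )
    suppression_latency_s: float = 5.0
    suppression_ramp_s: float = 1.0
    transient_wave_amplitude_uV: float = 40.0
    transient_wave_prob: float = 0.5
    transient_wave_freq_hz: float = 1.0
    background_slowing: Mapping[str, float] = field(
        default_factory=lambda: {"S": 1.0, "A": 0.95, "B": 0.85, "C": 0.75}
    )
    background_amplitude_scale: Mapping[str, float] = field(
        default_factory=lambda: {"S": 1.0, "A": 0.95, "B": 0.85, "C": 0.75}
    )
    noise_floor_uV: float = 0.3
    acquisition_band_hz: tuple[float, float] = (0.5, 70.0)
    # haemodynamics
    physio_fs_hz: float = 1.0
    hr_baseline_bpm: float = 186.0
    hr_occlusion_bpm: Mapping[str, float] = field(
        default_factory=lambda: {"A": 85.0, "B": 80.0, "C": 79.0}
    )
    hr_ramp_s: float = 5.0
    hr_noise_bpm: float = 3.0
    mbp_baseline_mmHg: float = 48.0
    mbp_pause_delta_mmHg: Mapping[str, float] = field(
        default_factory=lambda: {"A": 10.0, "B": 14.0, "C": 16.0}
    )
    mbp_occlusion_mmHg: Mapping[str, float] = field(
        default_factory=lambda: {"A": 56.0, "B": 54.0, "C": 37.0}
    )
    mbp_ramp_s: float = 10.0
    mbp_noise_mmHg: float = 2.0
    # per-phase (pH, pCO2 mmHg, pO2 mmHg, lactate mmol/L) gas targets
    gas_trajectory: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "S": (7.39, 45.3, 12.0, 2.27),
            "A": (7.28, 50.6, 16.0, 6.0),
            "B": (7.10, 54.0, 15.0, 12.8),
            "C": (6.98, 64.9, 16.5, 15.9),
        }
    )
    gas_noise: tuple[float, float, float, float] = (0.01, 1.0, 1.0, 0.3)

    def __post_init__(self) -> None:
        for ph, d in self.suppression_depth.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"suppression_depth[{ph}] must be in [0, 1]")
        if self.baseline_amplitude_uV < 0 or self.transient_wave_amplitude_uV < 0:
            raise ValueError("amplitudes must be >= 0")


@dataclass(frozen=True)
class PhysioRecord:
    """1-Hz haemodynamic series plus discrete blood-gas samples."""

    haemodynamics: pd.DataFrame  # time_s, hr_bpm, mbp_mmHg
    gasometry: pd.DataFrame  # time_s, ph, pco2_mmHg, po2_mmHg, lactate_mmol_l

    def clip(self, end_s: float) -> "PhysioRecord":
        return PhysioRecord(
            self.haemodynamics[self.haemodynamics["time_s"] < end_s].reset_index(drop=True),
            self.gasometry[self.gasometry["time_s"] <= end_s].reset_index(drop=True),
        )


@dataclass(frozen=True)
class Subject:
    subject_id: str
    sim_config: SubjectSimConfig
    schedule: ProtocolSchedule
    eeg: EEGRecording
    physio: PhysioRecord


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------


def _coloured_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    spectrum: Sequence[tuple[float, float, float]],
    slowing: float,
) -> np.ndarray:
    """Unit-RMS coloured noise: rFFT of white noise shaped by a piecewise
    sqrt-power-density gain per band, band edges scaled by ``slowing``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    gain = np.zeros_like(freqs)
    for low, high, power in spectrum:
        lo, hi = low * slowing, high * slowing
        mask = (freqs >= lo) & (freqs < hi)
        width = hi - lo
        if width > 0:
            gain[mask] = np.sqrt(power / width)
    shaped = np.fft.irfft(spec * gain, n=n)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def _phase_segments(schedule: ProtocolSchedule) -> list[tuple[str, float, float]]:
    """Contiguous (phase, start_s, end_s) regions in timeline order."""
    segments: list[tuple[str, float, float]] = []
    for ev in schedule.events:
        if segments and segments[-1][0] == ev.phase:
            segments[-1] = (ev.phase, segments[-1][1], ev.end_s)
        else:
            segments.append((ev.phase, ev.start_s, ev.end_s))
    return segments


def _cosine_ramp(n: int, start: float, end: float) -> np.ndarray:
    if n <= 0:
        return np.empty(0)
    return start + (end - start) * 0.5 * (1 - np.cos(np.linspace(0, np.pi, n)))


def _suppression_gain(
    schedule: ProtocolSchedule, config: SubjectSimConfig, n: int
) -> np.ndarray:
    """Multiplicative gain: per-phase background scale x occlusion gating."""
    fs = config.fs_hz
    gain = np.ones(n)
    for phase, t0, t1 in _phase_segments(schedule):
        scale = config.background_amplitude_scale.get(phase, 1.0)
        gain[round(t0 * fs) : round(t1 * fs)] = scale
    for ev in schedule.events_in(label=OCCLUSION):
        depth = config.suppression_depth.get(ev.phase, 1.0)
        if depth >= 1.0:
            continue
        ramp_n = max(1, round(config.suppression_ramp_s * fs))
        drop_end = ev.start_s + config.suppression_latency_s
        drop_start = drop_end - config.suppression_ramp_s
        i_ds, i_de = round(drop_start * fs), round(drop_end * fs)
        i_end = round(min(ev.end_s, drop_end) * fs)  # guard: latency past event end
        i_ev_end = round(ev.end_s * fs)
        if i_de >= i_ev_end:
            continue  # suppression never develops within this occlusion
        down = _cosine_ramp(i_de - i_ds, 1.0, depth)
        lo = max(0, i_ds)
        gain[lo:i_de] *= down[lo - i_ds :]
        gain[i_de:i_ev_end] *= depth
        i_up_end = min(n, i_ev_end + ramp_n)
        up = _cosine_ramp(i_ev_end + ramp_n - i_ev_end, depth, 1.0)
        gain[i_ev_end:i_up_end] *= up[: i_up_end - i_ev_end]
    return gain


def _transient_waves(
    schedule: ProtocolSchedule, config: SubjectSimConfig, n: int
) -> np.ndarray:
    """Damped low-frequency high-amplitude waves at occlusion onset/release."""
    fs = config.fs_hz
    wave_len = round(2.0 * fs)
    tau = np.arange(wave_len) / fs
    template = np.sin(2 * np.pi * config.transient_wave_freq_hz * tau) * np.exp(-tau / 0.6)
    out = np.zeros(n)
    rng = substream(config.seed, "eeg", "transients")
    for ev in schedule.events_in(label=OCCLUSION):
        for t_anchor in (ev.start_s, ev.end_s):
            amp_jitter = 0.7 + 0.6 * rng.random()
            if rng.random() >= config.transient_wave_prob:
                continue
            i0 = round(t_anchor * fs)
            seg = template[: max(0, min(wave_len, n - i0))]
            out[i0 : i0 + len(seg)] += (
                config.transient_wave_amplitude_uV * amp_jitter * seg
            )
    return out


def simulate_eeg(schedule: ProtocolSchedule, config: SubjectSimConfig) -> EEGRecording:
    """Simulate the four monopolar channels over the whole (possibly
    truncated) schedule.  Same (schedule, config) -> bit-identical output."""
    if not schedule.events:
        raise ValueError("schedule is empty")
    fs = config.fs_hz
    n = round(schedule.span_s * fs)
    segments = _phase_segments(schedule)

    streams: dict[str, np.ndarray] = {}
    for name in ("frontal_common", "parietal_common", "frontal_diff", "parietal_diff"):
        parts = []
        for phase, t0, t1 in segments:
            rng = substream(config.seed, "eeg", name, phase)
            slowing = config.background_slowing.get(phase, 1.0)
            parts.append(
                _coloured_noise(rng, round((t1 - t0) * fs), fs, config.baseline_spectrum, slowing)
            )
        streams[name] = np.concatenate(parts)[:n]

    gain = _suppression_gain(schedule, config, n)
    transients = _transient_waves(schedule, config, n)
    a_diff = config.baseline_amplitude_uV
    a_common = config.common_mode_ratio * config.baseline_amplitude_uV

    channels = {}
    for region, common, diff in (
        ("F", streams["frontal_common"], streams["frontal_diff"]),
        ("P", streams["parietal_common"], streams["parietal_diff"]),
    ):
        neural_common = a_common * common * gain
        neural_diff = a_diff * diff * gain + transients
        channels[f"{region}_left"] = neural_common + 0.5 * neural_diff
        channels[f"{region}_right"] = neural_common - 0.5 * neural_diff

    low, high = config.acquisition_band_hz
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    data = np.empty((4, n))
    for i, label in enumerate(DEFAULT_CHANNELS):
        noise = config.noise_floor_uV * substream(config.seed, "eeg", "floor", label).standard_normal(n)
        data[i] = signal.sosfiltfilt(sos, channels[label] + noise)
    return EEGRecording(data, DEFAULT_CHANNELS, fs, start_time_s=0.0)


# ---------------------------------------------------------------------------
# Physiology
# ---------------------------------------------------------------------------


def _level_profile(
    t: np.ndarray,
    baseline: np.ndarray,
    events: Sequence,
    levels: Mapping[str, float],
    ramp_s: float,
) -> np.ndarray:
    """Piecewise profile: ``baseline`` outside events, ``levels[phase]``
    inside, linear ramps of ``ramp_s`` at entry and exit."""
    out = baseline.astype(float).copy()
    for ev in events:
        level = levels.get(ev.phase)
        if level is None:
            continue
        if ramp_s > 0:
            frac_in = np.clip((t - ev.start_s) / ramp_s, 0.0, 1.0)
            frac_out = np.clip((t - ev.end_s) / ramp_s, 0.0, 1.0)
            w = np.where(t < ev.end_s, frac_in, 1.0 - frac_out)
            w[(t < ev.start_s) | (t > ev.end_s + ramp_s)] = 0.0
        else:
            w = ((t >= ev.start_s) & (t < ev.end_s)).astype(float)
        out = out * (1 - w) + level * w
    return out


def _gas_anchor_times(schedule: ProtocolSchedule) -> dict[str, float]:
    """Blood-sampling times: stability midpoint and midpoint of the last
    pause of each occlusion phase (on the untruncated schedule)."""
    anchors: dict[str, float] = {}
    stab = schedule.events_in(label=STABILITY)
    if stab:
        anchors["S"] = 0.5 * (stab[0].start_s + stab[-1].end_s)
    for phase in OCCLUSION_PHASES:
        pauses = schedule.events_in(label=PAUSE, phase=phase)
        if pauses:
            last = pauses[-1]
            anchors[phase] = 0.5 * (last.start_s + last.end_s)
    return anchors


def simulate_physio(schedule: ProtocolSchedule, config: SubjectSimConfig) -> PhysioRecord:
    """Heart rate, mean blood pressure and blood-gas samples.

    With all noise parameters at zero and zero ramps the series are
    piecewise-constant at exactly the configured levels.
    """
    if not schedule.events:
        raise ValueError("schedule is empty")
    dt = 1.0 / config.physio_fs_hz
    t = np.arange(0.0, schedule.span_s, dt)
    occlusions = schedule.events_in(label=OCCLUSION)
    pauses = schedule.events_in(label=PAUSE)

    hr = _level_profile(
        t,
        np.full_like(t, config.hr_baseline_bpm),
        occlusions,
        config.hr_occlusion_bpm,
        config.hr_ramp_s,
    )
    if config.hr_noise_bpm > 0:
        hr = hr + config.hr_noise_bpm * substream(config.seed, "physio", "hr").standard_normal(t.size)

    # between occlusions MBP sits halfway to the pause (hypertensive) level
    inter_levels = {
        ph: config.mbp_baseline_mmHg + 0.5 * config.mbp_pause_delta_mmHg.get(ph, 0.0)
        for ph in OCCLUSION_PHASES
    }
    pause_levels = {
        ph: config.mbp_baseline_mmHg + config.mbp_pause_delta_mmHg.get(ph, 0.0)
        for ph in OCCLUSION_PHASES
    }
    base = np.full_like(t, config.mbp_baseline_mmHg)
    for phase, t0, t1 in _phase_segments(schedule):
        if phase in inter_levels:
            base[(t >= t0) & (t < t1)] = inter_levels[phase]
    mbp = _level_profile(t, base, pauses, pause_levels, config.mbp_ramp_s)
    mbp = _level_profile(t, mbp, occlusions, config.mbp_occlusion_mmHg, config.mbp_ramp_s)
    if config.mbp_noise_mmHg > 0:
        mbp = mbp + config.mbp_noise_mmHg * substream(config.seed, "physio", "mbp").standard_normal(t.size)

    anchors = _gas_anchor_times(schedule)
    rng = substream(config.seed, "physio", "gas")
    rows = []
    ordered = [p for p in PHASES if p in anchors]
    for phase in ordered:
        targets = config.gas_trajectory[phase]
        noise = rng.standard_normal(len(GAS_COLUMNS)) * np.asarray(config.gas_noise)
        rows.append((anchors[phase], *(np.asarray(targets) + noise)))
    gas = pd.DataFrame(rows, columns=["time_s", *GAS_COLUMNS])
    haemo = pd.DataFrame({"time_s": t, "hr_bpm": hr, "mbp_mmHg": mbp})
    return PhysioRecord(haemo, gas)


def latent_gas_trajectory(
    schedule: ProtocolSchedule, config: SubjectSimConfig, times_s: np.ndarray
) -> pd.DataFrame:
    """Dense piecewise-linear gas trajectory interpolating the per-phase
    anchor targets (noise-free); used for plots and diagnostics."""
    anchors = _gas_anchor_times(schedule)
    ordered = [p for p in PHASES if p in anchors]
    at = np.array([anchors[p] for p in ordered])
    out = {"time_s": times_s}
    for j, col in enumerate(GAS_COLUMNS):
        vals = np.array([config.gas_trajectory[p][j] for p in ordered])
        out[col] = np.interp(times_s, at, vals)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Subjects and cohorts
# ---------------------------------------------------------------------------


def simulate_subject(
    sim_config: SubjectSimConfig,
    protocol: ProtocolConfig = ProtocolConfig(),
    subject_id: str = "subject_01",
) -> Subject:
    """One fetus end to end: schedule, physiology, stop rule, then EEG.

    The stop rule is applied to the blood-gas samples before the EEG is
    synthesised, so a truncated subject's recording ends at the truncation
    point, as a stopped experiment's would.
    """
    schedule = build_protocol(protocol)
    physio = simulate_physio(schedule, sim_config)
    stopped = apply_stop_rule(
        schedule,
        physio.gasometry["time_s"].to_numpy(),
        physio.gasometry["ph"].to_numpy(),
        protocol.ph_stop_threshold,
    )
    if stopped.truncated_at_s is not None:
        physio = physio.clip(stopped.truncated_at_s)
    eeg = simulate_eeg(stopped, sim_config)
    return Subject(subject_id, sim_config, stopped, eeg, physio)


def _jittered_config(
    base: SubjectSimConfig, seed: int, index: int, jitter: float
) -> SubjectSimConfig:
    """Per-subject parameter draw.

    ``vulnerability`` is a latent standard-normal factor shared across the
    subject's EEG and cardiovascular parameters: a fragile fetus suppresses
    more deeply, slows more, is more bradycardic and hypotensive during
    occlusions and acidifies faster.  ``jitter`` scales all variability;
    0 reproduces the base configuration (apart from per-subject seeds).
    """
    rng = substream(seed, "cohort", f"subject_{index}")
    v = float(rng.standard_normal())
    z = rng.standard_normal(8)
    j = jitter

    amp = base.baseline_amplitude_uV * float(np.exp(0.20 * j * z[0]))
    depth = {
        ph: float(np.clip(d ** float(np.exp(0.35 * j * v + 0.15 * j * z[1])), 0.0, 1.0))
        for ph, d in base.suppression_depth.items()
    }
    slowing = {
        ph: float(np.clip(s ** float(np.exp(0.25 * j * v + 0.10 * j * z[2])), 0.05, 1.5))
        if ph != "S"
        else s
        for ph, s in base.background_slowing.items()
    }
    amp_scale = {
        ph: float(np.clip(s ** float(np.exp(0.25 * j * v + 0.10 * j * z[3])), 0.05, 1.0))
        if ph != "S"
        else s
        for ph, s in base.background_amplitude_scale.items()
    }
    hr_occ = {
        ph: float(max(30.0, h - 8.0 * j * v + 5.0 * j * z[4]))
        for ph, h in base.hr_occlusion_bpm.items()
    }
    mbp_occ = {
        ph: float(max(10.0, m - 5.0 * j * v + 3.0 * j * z[5]))
        for ph, m in base.mbp_occlusion_mmHg.items()
    }
    gas = {}
    for ph, (p_h, pco2, po2, lac) in base.gas_trajectory.items():
        drift = 0.0 if ph == "S" else {"A": 0.3, "B": 0.7, "C": 1.0}.get(ph, 1.0)
        gas[ph] = (
            p_h - drift * (0.035 * j * v + 0.02 * j * z[6]),
            pco2 + drift * (4.0 * j * v + 3.0 * j * z[7]),
            po2,
            lac + drift * max(-lac * 0.5, 1.5 * j * v),
        )
    return replace(
        base,
        seed=derive_seed(seed, "cohort", f"subject_{index}", "stream"),
        baseline_amplitude_uV=amp,
        suppression_depth=depth,
        background_slowing=slowing,
        background_amplitude_scale=amp_scale,
        hr_baseline_bpm=float(base.hr_baseline_bpm + 6.0 * j * z[0]),
        hr_occlusion_bpm=hr_occ,
        mbp_occlusion_mmHg=mbp_occ,
        gas_trajectory=gas,
    )


def simulate_cohort(
    n: int,
    base_config: SubjectSimConfig = SubjectSimConfig(),
    seed: int = 0,
    protocol: ProtocolConfig = ProtocolConfig(),
    jitter: float = 1.0,
    overrides: Mapping[int, Mapping] | None = None,
) -> list[Subject]:
    """Simulate ``n`` fetuses with independent, seeded inter-individual
    variability.  ``overrides`` maps a 0-based subject index to config-field
    overrides applied after the jitter draw (e.g. a deliberately severe gas
    trajectory to exercise the stop rule)."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    subjects = []
    for i in range(n):
        cfg = _jittered_config(base_config, seed, i, jitter)
        if overrides and i in overrides:
            cfg = replace(cfg, **dict(overrides[i]))
        subjects.append(
            simulate_subject(cfg, protocol, subject_id=f"subject_{i + 1:02d}")
        )
    return subjects


# ---------------------------------------------------------------------------
# Scaled protocols and summary-level cohorts (statistical calibration)
# ---------------------------------------------------------------------------


def short_protocol() -> ProtocolConfig:
    """Time-scaled protocol (1/5): 720-s phases of 12-s occlusions every
    60/36/24 s, 60-s pauses every 240 s.  Preserves the 9/15/21 occlusion
    counts and the full block structure at a fifth of the duration."""
    return ProtocolConfig(
        phase_duration_s=720.0,
        occlusion_duration_s=12.0,
        inter_occlusion_period_s={"A": 60.0, "B": 36.0, "C": 24.0},
        pause_period_s=240.0,
        pause_duration_s=60.0,
        stability_duration_s=720.0,
    )


def tiny_protocol() -> ProtocolConfig:
    """Minimal protocol for repeated-simulation studies: 240-s phases,
    12-s occlusions, 30-s pauses every 120 s (2/4/6 occlusions per phase)."""
    return ProtocolConfig(
        phase_duration_s=240.0,
        occlusion_duration_s=12.0,
        inter_occlusion_period_s={"A": 60.0, "B": 36.0, "C": 24.0},
        pause_period_s=120.0,
        pause_duration_s=30.0,
        stability_duration_s=240.0,
    )


def scaled_sim_config(seed: int = 0) -> SubjectSimConfig:
    """Study-level amplitudes/rates with occlusion dynamics re-timed for the
    scaled protocols (shorter suppression latency and ramps)."""
    return SubjectSimConfig(
        seed=seed, suppression_latency_s=2.0, suppression_ramp_s=0.5, hr_ramp_s=2.0,
        mbp_ramp_s=3.0,
    )


def null_summary_cohort(
    n_subjects: int,
    rng: np.random.Generator,
    conditions: Sequence[str] = PHASES,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Per-subject per-phase feature medians with *no* phase effect: the null
    hypothesis of the repeated-measures stage.  Subjects get a random level,
    phases add exchangeable noise."""
    level = rng.normal(0.0, scale, size=(n_subjects, 1))
    noise = rng.normal(0.0, scale, size=(n_subjects, len(conditions)))
    return pd.DataFrame(
        level + noise,
        index=[f"subject_{i + 1:02d}" for i in range(n_subjects)],
        columns=list(conditions),
    )
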