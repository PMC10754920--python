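"""Quantitative EEG features: minimum amplitude index, burst suppression
ratio and spectral edge frequency.

The three features are computed on consecutive non-overlapping 2-s intervals
of the fronto-parietal *bipolar* derivations (left minus right frontal, left
minus right parietal) and then averaged across the two derivations:

* **min AI** (µV) — minimum of the aEEG/CFM-style amplitude envelope of the
  2–20 Hz band-passed signal over the interval.
* **BSR** (%) — fraction of the interval spent in suppression, where a
  suppression is a maximal run with envelope amplitude < 10 µV lasting
  strictly longer than 500 ms.  Runs are detected on the continuous timeline
  and intersected with the intervals, so a suppression spanning an interval
  edge contributes its overlap to both intervals.
* **SEF** (Hz) — 95% spectral edge: the lowest frequency below which 95% of
  the 0.5–70 Hz periodogram power of the interval lies.  Intervals whose
  in-band power falls below a configurable floor (default: the total power of
  a 1-µV-RMS signal) yield an *undefined* SEF (NaN), never a spurious
  numeric edge.

The envelope is a documented stand-in for the commercial CFM trace: absolute
value of the 2–20 Hz signal, sliding 125-ms maximum, then 0.5-s moving-average
smoothing.  The suppression criterion is evaluated on this envelope rather
than on raw samples — a raw oscillation crosses any threshold twice per cycle,
which would make an amplitude-below-threshold rule degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

DEFAULT_CHANNELS = ("F_left", "F_right", "P_left", "P_right")


class MontageError(KeyError):
    """A montage references a channel label absent from the recording."""


@dataclass(frozen=True)
class EEGRecording:
    """Multichannel EEG in µV: ``data`` has shape (n_channels, n_samples)."""

    data: np.ndarray
    channel_labels: tuple[str, ...]
    sample_rate_hz: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        if data.ndim != 2 or data.shape[0] != len(self.channel_labels):
            raise ValueError("data must be (n_channels, n_samples) matching labels")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be > 0")
        if not np.all(np.isfinite(data)):
            raise ValueError("EEG samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError as err:
            raise MontageError(f"channel {label!r} not in {self.channel_labels}") from err


@dataclass(frozen=True)
class MontageSpec:
    """Ordered bipolar derivations as (minuend, subtrahend) label pairs."""

    derivations: tuple[tuple[str, str], ...] = (
        ("F_left", "F_right"),
        ("P_left", "P_right"),
    )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"{a}-{b}" for a, b in self.derivations)


class SuppressionSegment(NamedTuple):
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class FeatureParams:
    """Analysis constants; defaults are the study's values."""

    interval_s: float = 2.0
    envelope_band_hz: tuple[float, float] = (2.0, 20.0)
    envelope_max_window_s: float = 0.125
    envelope_smooth_s: float = 0.5
    suppression_threshold_uV: float = 10.0
    suppression_min_duration_s: float = 0.5
    sef_quantile: float = 0.95
    sef_band_hz: tuple[float, float] = (0.5, 70.0)
    sef_power_floor_uV2: float = 1.0


@dataclass(frozen=True)
class QEEGSeries:
    """Per-interval features per derivation plus the channel average.

    Both tables have one row per 2-s interval; ``sef_hz`` is NaN where the
    spectral edge is undefined (interval power below the floor).
    """

    per_derivation: pd.DataFrame  # interval_start_s, derivation, minai_uV, bsr_percent, sef_hz
    averaged: pd.DataFrame  # interval_start_s, minai_uV, bsr_percent, sef_hz
    interval_s: float


def derive_bipolar(rec: EEGRecording, montage: MontageSpec = MontageSpec()) -> EEGRecording:
    """Sample-wise difference of each montage pair, preserving rate/length."""
    rows = [rec.channel(a) - rec.channel(b) for a, b in montage.derivations]
    return EEGRecording(
        np.vstack(rows), montage.labels, rec.sample_rate_hz, rec.start_time_s
    )


def bandpass(
    x: np.ndarray, low_hz: float, high_hz: float, fs: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, so the effective
    attenuation is twice the single-pass design)."""
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(f"invalid band ({low_hz}, {high_hz}) for fs={fs}")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def amplitude_envelope(
    x: np.ndarray,
    fs: float,
    max_window_s: float = 0.125,
    smooth_s: float = 0.5,
) -> np.ndarray:
    """aEEG/CFM-style amplitude envelope of an already band-passed signal."""
    win = max(1, round(max_window_s * fs))
    env = ndimage.maximum_filter1d(np.abs(np.asarray(x, dtype=float)), size=win, mode="nearest")
    smooth = max(1, round(smooth_s * fs))
    return ndimage.uniform_filter1d(env, size=smooth, mode="nearest")


def min_ai(
    envelope: np.ndarray,
    fs: float,
    interval: tuple[float, float],
    start_time_s: float = 0.0,
) -> float:
    """Minimum of the amplitude envelope over ``interval`` (seconds)."""
    i0, i1 = _interval_slice(len(envelope), fs, interval, start_time_s)
    if i1 <= i0:
        raise ValueError(f"empty interval {interval}")
    return float(np.min(envelope[i0:i1]))


def detect_suppressions(
    envelope: np.ndarray,
    fs: float,
    threshold_uV: float = 10.0,
    min_duration_s: float = 0.5,
    start_time_s: float = 0.0,
) -> list[SuppressionSegment]:
    """Maximal runs with envelope < threshold lasting strictly > min_duration_s.

    Detection is strict on both inequalities and runs on the continuous
    timeline of the envelope, independent of any interval grid.
    """
    env = np.asarray(envelope, dtype=float)
    if env.size == 0:
        return []
    below = env < threshold_uV
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = list(edges[~below[edges]] + 1)  # False -> True transitions
    ends = list(edges[below[edges]] + 1)  # True -> False transitions
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(env.size)
    segments = []
    for i, j in zip(starts, ends):
        if (j - i) / fs > min_duration_s:
            segments.append(
                SuppressionSegment(start_time_s + i / fs, start_time_s + j / fs)
            )
    return segments


def bsr(segments: Sequence[SuppressionSegment], interval: tuple[float, float]) -> float:
    """Percent of ``interval`` covered by suppression segments (overlap only)."""
    t0, t1 = interval
    if not t1 > t0:
        raise ValueError(f"interval length must be > 0, got {interval}")
    covered = sum(max(0.0, min(s.end_s, t1) - max(s.start_s, t0)) for s in segments)
    return 100.0 * covered / (t1 - t0)


def sef(
    x: np.ndarray,
    fs: float,
    quantile: float = 0.95,
    band: tuple[float, float] = (0.5, 70.0),
    power_floor_uV2: float = 1.0,
) -> float:
    """Spectral edge frequency of one interval; NaN when power is below floor.

    Hann-tapered periodogram of the interval (0.5-Hz resolution for 2 s at
    256 Hz); the edge is the lowest in-band frequency at which the cumulative
    in-band power reaches ``quantile`` of the total in-band power.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[-1] < 2 * fs:
        raise ValueError("SEF interval must hold at least 2 s of samples")
    out = _sef_batch(x, fs, quantile, band, power_floor_uV2)
    return float(out[0]) if out.shape == (1,) else out


def _sef_batch(
    segments: np.ndarray,
    fs: float,
    quantile: float,
    band: tuple[float, float],
    power_floor_uV2: float,
) -> np.ndarray:
    freqs, pxx = signal.periodogram(segments, fs=fs, window="hann", axis=-1)
    df = freqs[1] - freqs[0]
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    bandfreqs = freqs[in_band]
    power = pxx[..., in_band] * df
    total = power.sum(axis=-1)
    cum = np.cumsum(power, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        reached = cum >= quantile * total[..., None] - 1e-300
    idx = reached.argmax(axis=-1)
    edge = bandfreqs[idx]
    edge = np.where(total >= power_floor_uV2, edge, np.nan)
    return edge


def _interval_slice(
    n: int, fs: float, interval: tuple[float, float], start_time_s: float
) -> tuple[int, int]:
    t0, t1 = interval
    i0 = max(0, int(np.ceil((t0 - start_time_s) * fs - 1e-9)))
    i1 = min(n, int(np.ceil((t1 - start_time_s) * fs - 1e-9)))
    return i0, i1


def compute_features(
    rec: EEGRecording,
    montage: MontageSpec = MontageSpec(),
    params: FeatureParams = FeatureParams(),
) -> QEEGSeries:
    """Full feature extraction: bipolar montage -> per-interval feature tables.

    Channel-averaged values are the arithmetic mean of the two derivations;
    SEF averages over the defined derivations only and is undefined (NaN)
    when both are.
    """
    if rec.duration_s < params.interval_s:
        raise ValueError(
            f"recording shorter than one interval ({params.interval_s} s)"
        )
    fs = rec.sample_rate_hz
    nper = round(params.interval_s * fs)
    bipolar = derive_bipolar(rec, montage)
    n_int = bipolar.n_samples // nper
    starts = rec.start_time_s + np.arange(n_int) * params.interval_s

    frames = []
    for label, row in zip(bipolar.channel_labels, bipolar.data):
        filtered = bandpass(row, *params.envelope_band_hz, fs)
        env = amplitude_envelope(
            filtered, fs, params.envelope_max_window_s, params.envelope_smooth_s
        )
        segs = detect_suppressions(
            env,
            fs,
            params.suppression_threshold_uV,
            params.suppression_min_duration_s,
            rec.start_time_s,
        )
        trimmed = env[: n_int * nper].reshape(n_int, nper)
        minai = trimmed.min(axis=1)
        bsr_vals = np.array(
            [bsr(segs, (t, t + params.interval_s)) for t in starts]
        )
        sef_vals = _sef_batch(
            row[: n_int * nper].reshape(n_int, nper),
            fs,
            params.sef_quantile,
            params.sef_band_hz,
            params.sef_power_floor_uV2,
        )
        frames.append(
            pd.DataFrame(
                {
                    "interval_start_s": starts,
                    "derivation": label,
                    "minai_uV": minai,
                    "bsr_percent": bsr_vals,
                    "sef_hz": sef_vals,
                }
            )
        )
    per_derivation = pd.concat(frames, ignore_index=True)
    by_interval = per_derivation.groupby("interval_start_s")
    averaged = pd.DataFrame(
        {
            "interval_start_s": starts,
            "minai_uV": by_interval["minai_uV"].mean().to_numpy(),
            "bsr_percent": by_interval["bsr_percent"].mean().to_numpy(),
            # mean over defined derivations; NaN only if every derivation is
            "sef_hz": by_interval["sef_hz"].mean().to_numpy(),
        }
    )
    return QEEGSeries(per_derivation, averaged, params.interval_s)
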