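"""Feature engine: bipolar montage, filtering, envelope, suppression
detection, BSR, SEF and the 2-s interval pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps_signal

from fetalqeeg.features import (
    EEGRecording,
    FeatureParams,
    MontageError,
    MontageSpec,
    SuppressionSegment,
    amplitude_envelope,
    bandpass,
    bsr,
    compute_features,
    derive_bipolar,
    detect_suppressions,
    min_ai,
    sef,
)
from .conftest import FS, sine


def brute_force_runs(env, fs, threshold=10.0, min_duration_s=0.5):
    """Sample-by-sample run scanner, the independent oracle for
    detect_suppressions."""
    segments = []
    start = None
    for i, v in enumerate(env):
        if v < threshold and start is None:
            start = i
        elif v >= threshold and start is not None:
            if (i - start) / fs > min_duration_s:
                segments.append((start / fs, i / fs))
            start = None
    if start is not None and (len(env) - start) / fs > min_duration_s:
        segments.append((start / fs, len(env) / fs))
    return segments


def recording_from(channels: dict) -> EEGRecording:
    labels = tuple(channels)
    return EEGRecording(np.vstack([channels[l] for l in labels]), labels, FS)


class TestDeriveBipolar:
    def test_self_difference_is_zero(self):
        x = sine(5, 4)
        rec = recording_from({"A": x})
        out = derive_bipolar(rec, MontageSpec(derivations=(("A", "A"),)))
        assert np.allclose(out.data, 0.0)

    def test_identity_against_zero_reference(self):
        x = sine(7, 4, amplitude=12)
        rec = recording_from({"F_left": x, "F_right": np.zeros_like(x)})
        out = derive_bipolar(rec, MontageSpec(derivations=(("F_left", "F_right"),)))
        assert np.allclose(out.data[0], x)

    def test_random_channels_match_subtraction_oracle(self):
        rng = np.random.default_rng(0)
        chans = {l: rng.normal(size=1024) for l in ("F_left", "F_right", "P_left", "P_right")}
        rec = recording_from(chans)
        out = derive_bipolar(rec)
        assert np.array_equal(out.data[0], chans["F_left"] - chans["F_right"])
        assert np.array_equal(out.data[1], chans["P_left"] - chans["P_right"])
        assert out.channel_labels == ("F_left-F_right", "P_left-P_right")

    def test_missing_label_raises(self):
        rec = recording_from({"A": np.zeros(512)})
        with pytest.raises(MontageError):
            derive_bipolar(rec, MontageSpec(derivations=(("A", "B"),)))


class TestBandpass:
    def test_in_band_sine_retained(self):
        x = sine(10, 8)
        y = bandpass(x, 2, 20, FS)
        mid = slice(2 * 256, 6 * 256)
        assert np.max(np.abs(y[mid])) == pytest.approx(1.0, rel=0.05)

    def test_out_of_band_sine_attenuated(self):
        x = sine(40, 8)
        y = bandpass(x, 2, 20, FS)
        mid = slice(2 * 256, 6 * 256)
        assert np.max(np.abs(y[mid])) < 0.10

    def test_stopband_attenuation_one_octave_out(self):
        """>= 40 dB at 1 Hz and 40 Hz (one octave outside 2-20 Hz),
        accounting for the doubled attenuation of zero-phase filtering."""
        sos = sps_signal.butter(4, [2, 20], btype="bandpass", fs=FS, output="sos")
        w, h = sps_signal.sosfreqz(sos, worN=[1.0, 40.0], fs=FS)
        double_pass_db = 2 * 20 * np.log10(np.abs(h))
        assert np.all(double_pass_db <= -40.0)

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass(np.zeros(1024), 2, 20, FS), 0.0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(512), 20, 2, FS)


class TestEnvelope:
    def test_zero_signal(self):
        assert np.allclose(amplitude_envelope(np.zeros(2048), FS), 0.0)

    def test_constant_sine_converges_to_peak(self):
        env = amplitude_envelope(sine(10, 8, amplitude=30), FS)
        interior = env[256:-256]
        assert np.all(np.abs(interior - 30) / 30 < 0.05)

    def test_tracks_slow_amplitude_modulation(self):
        """Envelope follows a known instantaneous peak profile within 10%."""
        n = round(16 * FS)
        t = np.arange(n) / FS
        profile = 20 + 10 * np.sin(2 * np.pi * 0.2 * t)  # 0.2-Hz modulation
        x = profile * np.sin(2 * np.pi * 10 * t)
        env = amplitude_envelope(x, FS)
        interior = slice(round(FS), -round(FS))
        rel_err = np.abs(env[interior] - profile[interior]) / profile[interior]
        assert np.percentile(rel_err, 95) < 0.10


class TestMinAI:
    def test_constant_envelope(self):
        env = np.full(2048, 12.0)
        assert min_ai(env, FS, (0.0, 4.0)) == 12.0

    def test_single_dip(self):
        env = np.full(2048, 25.0)
        env[700] = 5.0
        assert min_ai(env, FS, (0.0, 8.0)) == 5.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        env = rng.uniform(0, 50, size=4096)
        i0, i1 = 512, 1536
        assert min_ai(env, FS, (i0 / FS, i1 / FS)) == min(env[i0:i1])

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            min_ai(np.ones(256), FS, (1.0, 1.0))


class TestDetectSuppressions:
    def test_too_short_run_ignored(self):
        env = np.full(round(4 * FS), 30.0)
        env[256 : 256 + round(0.4 * FS)] = 2.0
        assert detect_suppressions(env, FS) == []

    def test_all_zero_is_one_segment(self):
        env = np.zeros(round(60 * FS))
        segs = detect_suppressions(env, FS)
        assert len(segs) == 1
        assert (segs[0].start_s, segs[0].end_s) == (0.0, 60.0)

    def test_planted_runs_filtered_by_duration(self):
        env = np.full(round(10 * FS), 30.0)
        plants = [(1.0, 0.3), (3.0, 0.6), (6.0, 1.2)]
        for start, dur in plants:
            env[round(start * FS) : round((start + dur) * FS)] = 1.0
        segs = detect_suppressions(env, FS)
        flat = [t for s in segs for t in (s.start_s, s.end_s)]
        assert flat == pytest.approx([3.0, 3.6, 6.0, 7.2], abs=2 / FS)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_scanner(self, seed):
        """Exact agreement with a sample-wise run-length oracle on random
        envelopes with frequent threshold crossings."""
        rng = np.random.default_rng(seed)
        env = rng.uniform(0, 20, size=rng.integers(10, 2000))
        segs = detect_suppressions(env, FS)
        assert [(s.start_s, s.end_s) for s in segs] == pytest.approx(
            brute_force_runs(env, FS)
        )

    def test_strict_duration_inequality(self):
        env = np.full(round(4 * FS), 30.0)
        env[0 : round(0.5 * FS)] = 1.0  # exactly 500 ms: excluded
        assert detect_suppressions(env, FS) == []
        env[0 : round(0.5 * FS) + 1] = 1.0  # just over: included
        assert len(detect_suppressions(env, FS)) == 1


class TestBSR:
    def test_no_segments(self):
        assert bsr([], (0.0, 2.0)) == 0.0

    def test_full_coverage(self):
        assert bsr([SuppressionSegment(0.0, 5.0)], (1.0, 3.0)) == 100.0

    def test_half_coverage(self):
        assert bsr([SuppressionSegment(0.5, 1.5)], (0.0, 2.0)) == 50.0

    def test_straddling_segment_contributes_overlap_only(self):
        segs = [SuppressionSegment(1.5, 2.5)]
        assert bsr(segs, (0.0, 2.0)) == 25.0
        assert bsr(segs, (2.0, 4.0)) == 25.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        env = rng.uniform(0, 30, size=round(30 * FS))
        env = amplitude_envelope(env, FS)  # smooth so runs exist
        interval = (5.0, 25.0)
        values = []
        for thr in (5.0, 10.0, 15.0, 20.0):
            segs = detect_suppressions(env, FS, threshold_uV=thr)
            values.append(bsr(segs, interval))
        assert values == sorted(values)
        assert all(0.0 <= v <= 100.0 for v in values)


class TestSEF:
    def test_pure_sine_single_line(self):
        assert sef(sine(8, 2, amplitude=20), FS) == pytest.approx(8.0, abs=0.5)

    def test_equal_power_two_lines_edge_on_upper(self):
        x = sine(4, 2, amplitude=20) + sine(16, 2, amplitude=20)
        assert sef(x, FS) == pytest.approx(16.0, abs=0.5)

    def test_all_zero_interval_undefined(self):
        assert np.isnan(sef(np.zeros(512), FS))

    def test_amplitude_invariance_and_minai_scaling(self):
        x = sine(6, 2, amplitude=15) + sine(11, 2, amplitude=5)
        assert sef(x, FS) == sef(10 * x, FS)

    def test_monotone_in_quantile(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=512) * 30
        edges = [sef(x, FS, quantile=q) for q in (0.5, 0.75, 0.9, 0.95)]
        assert edges == sorted(edges)

    def test_short_interval_rejected(self):
        with pytest.raises(ValueError):
            sef(np.zeros(256), FS)


class TestComputeFeatures:
    def _recording(self, deriv_f, deriv_p):
        """Monopolar recording whose bipolar derivations equal the given
        signals exactly (left = +x/2, right = -x/2)."""
        return recording_from(
            {
                "F_left": deriv_f / 2,
                "F_right": -deriv_f / 2,
                "P_left": deriv_p / 2,
                "P_right": -deriv_p / 2,
            }
        )

    def test_identical_derivations_average_to_single_channel(self):
        x = sine(9, 20, amplitude=25) + sine(3, 20, amplitude=10)
        q = compute_features(self._recording(x, x.copy()))
        f = q.per_derivation[q.per_derivation.derivation == "F_left-F_right"]
        for col in ("minai_uV", "bsr_percent", "sef_hz"):
            assert np.allclose(q.averaged[col], f[col].to_numpy(), equal_nan=True)

    def test_suppressed_block_yields_bsr_100_in_exactly_those_intervals(self):
        x = sine(10, 180, amplitude=40)
        x[round(60 * FS) : round(120 * FS)] = 0.0
        q = compute_features(self._recording(x, x.copy()))
        full = q.averaged[q.averaged.bsr_percent == 100.0]
        inside = (q.averaged.interval_start_s >= 60) & (q.averaged.interval_start_s < 120)
        # edge smoothing may graze the two boundary intervals; the 28 interior
        # ones must be exactly 100% and nothing outside the block may be
        assert inside[full.index].all()
        assert len(full) >= 28
        outside = q.averaged[~inside]
        assert (outside.bsr_percent < 50).all()

    def test_stability_like_signal_no_suppression(self):
        rng = np.random.default_rng(2)
        x = bandpass(rng.normal(size=round(60 * FS)), 2, 20, FS)
        x *= 30 / x.std()
        q = compute_features(self._recording(x, x.copy()))
        assert q.averaged.bsr_percent.median() == 0.0
        assert q.averaged.sef_hz.notna().all()

    def test_planted_suppression_fraction_recovered(self):
        """BSR over a window containing a planted 5-s flat gap in a 10-s
        span recovers the 50% fraction within 5 percentage points."""
        x = sine(10, 30, amplitude=40)
        x[round(10 * FS) : round(15 * FS)] = 0.0
        q = compute_features(self._recording(x, x.copy()))
        window = (q.averaged.interval_start_s >= 5) & (q.averaged.interval_start_s < 15)
        measured = q.averaged[window].bsr_percent.mean()
        assert abs(measured - 50.0) <= 5.0

    def test_scaling_signal_scales_minai_leaves_sef(self):
        x = sine(7, 10, amplitude=30) + sine(13, 10, amplitude=10)
        q1 = compute_features(self._recording(x, x.copy()))
        q2 = compute_features(self._recording(3 * x, 3 * x.copy()))
        assert np.allclose(q2.averaged.minai_uV, 3 * q1.averaged.minai_uV, rtol=1e-6)
        assert np.allclose(q2.averaged.sef_hz, q1.averaged.sef_hz, equal_nan=True)

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="shorter than one interval"):
            compute_features(self._recording(np.zeros(256), np.zeros(256)))
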