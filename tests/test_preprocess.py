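"""Signal conditioning: smoothing, envelope normalization, segmentation, notch."""

import numpy as np
import pytest

from ifpwv.preprocess import (
    RawRecording,
    detect_dicrotic_notch,
    normalize_recording,
    segment_cycles,
    smooth_waveform,
)
from ifpwv.synthetic_data import CycleSpec, generate_cycle, generate_recording

FS = 1000.0


def _rec(samples, fs=FS):
    return RawRecording(samples=np.asarray(samples, dtype=float), fs=fs)


class TestSmoothing:
    def test_constant_preserved_exactly(self):
        out = smooth_waveform(_rec(np.full(500, 3.7)))
        np.testing.assert_allclose(out.samples, 3.7, rtol=0, atol=1e-12)

    def test_linear_ramp_preserved_on_interior(self):
        ramp = np.linspace(0.0, 5.0, 1000)
        out = smooth_waveform(_rec(ramp))
        np.testing.assert_allclose(out.samples[30:-30], ramp[30:-30], atol=1e-10)

    @pytest.mark.parametrize("phase", [0.0, 0.4, 1.9])
    def test_50hz_tone_nulled_on_interior(self, phase):
        t = np.arange(2000) / FS
        tone = np.sin(2 * np.pi * 50.0 * t + phase)
        out = smooth_waveform(_rec(tone)).samples[50:-50]
        # window spans exactly two tone periods: the integral vanishes
        attenuation_db = 20 * np.log10(
            np.sqrt(np.mean(tone[50:-50] ** 2)) / np.sqrt(np.mean(out**2))
        )
        assert attenuation_db >= 60.0

    def test_linearity(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=800), rng.normal(size=800)
        lhs = smooth_waveform(_rec(2.5 * x - 1.5 * y)).samples
        rhs = 2.5 * smooth_waveform(_rec(x)).samples - 1.5 * smooth_waveform(_rec(y)).samples
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_output_length_equals_input_length(self):
        n = 777
        assert len(smooth_waveform(_rec(np.random.default_rng(0).normal(size=n))).samples) == n

    def test_too_short_recording_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            smooth_waveform(_rec(np.zeros(20)))

    def test_low_sampling_rate_supported(self):
        out = smooth_waveform(_rec(np.full(300, 1.0), fs=200.0))
        np.testing.assert_allclose(out.samples, 1.0, atol=1e-12)


class TestNormalization:
    @staticmethod
    def _modulated_sinusoid():
        t = np.arange(8000) / FS
        beat = -np.cos(2 * np.pi * 1.25 * t)  # 1.25 Hz "beats"
        am = 1.0 + 0.3 * t / t[-1]  # linear amplitude modulation
        drift = 0.5 * t / t[-1]  # linear baseline drift
        return t, beat * am + drift

    def test_modulated_sinusoid_rescaled_per_beat(self):
        t, s = self._modulated_sinusoid()
        out = normalize_recording(_rec(s)).samples
        # every interior beat must span [0, 1] within 1% (per-beat
        # min-max rescale is the oracle for a pure sinusoid)
        period = int(FS / 1.25)
        for k in range(1, 8):
            beat = out[k * period : (k + 1) * period]
            assert abs(beat.max() - 1.0) < 0.01
            assert abs(beat.min()) < 0.01

    def test_affine_invariance(self):
        _, s = self._modulated_sinusoid()
        base = normalize_recording(_rec(s)).samples
        scaled = normalize_recording(_rec(4.2 * s + 11.0)).samples
        np.testing.assert_allclose(base, scaled, atol=1e-9)

    def test_already_normalized_signal_unchanged(self):
        t = np.arange(8000) / FS
        s = 0.5 - 0.5 * np.cos(2 * np.pi * 1.25 * t)
        out = normalize_recording(_rec(s)).samples
        inner = slice(800, -800)
        np.testing.assert_allclose(out[inner], s[inner], atol=0.02)

    def test_constant_trace_raises(self):
        with pytest.raises(ValueError):
            normalize_recording(_rec(np.full(4000, 2.0)))

    def test_single_beat_raises(self):
        t = np.arange(900) / FS
        with pytest.raises(ValueError):
            normalize_recording(_rec(np.sin(np.pi * t / t[-1])))


class TestSegmentation:
    def test_periodic_recording_recovers_cycles(self):
        k = 10
        rec = generate_recording([CycleSpec(noise_sd=0.0)] * k, seed=0)
        nrm = normalize_recording(smooth_waveform(rec))
        accepted = [c for c in segment_cycles(nrm) if c.accepted]
        assert len(accepted) >= k - 2
        for c in accepted:
            assert abs(c.T - 0.85) * c.fs <= 1.0  # within one sample of T

    def test_strictly_periodic_durations_cv_below_one_percent(self):
        rec = generate_recording([CycleSpec(noise_sd=0.0)] * 12, seed=1)
        nrm = normalize_recording(smooth_waveform(rec))
        T = np.array([c.T for c in segment_cycles(nrm) if c.accepted])
        assert T.std() / T.mean() < 0.01

    def test_too_short_trace_gives_empty_list(self):
        assert segment_cycles(_rec(np.zeros(int(0.3 * FS)))) == []

    def test_spike_artifact_beat_rejected_neighbors_kept(self):
        rec = generate_recording([CycleSpec(noise_sd=0.0)] * 8, seed=2)
        s = rec.samples.copy()
        # large spike artifact mid-way through the 4th beat
        i = int(3.5 * 0.85 * FS)
        s[i : i + 30] += 1.5 * np.ptp(s)
        nrm = normalize_recording(smooth_waveform(_rec(s)))
        cycles = segment_cycles(nrm)
        rejected = [c for c in cycles if not c.accepted]
        accepted = [c for c in cycles if c.accepted]
        assert len(rejected) >= 1
        assert any("outlier" in (c.reject_reason or "") or "peak" in (c.reject_reason or "")
                   for c in rejected)
        assert len(accepted) >= len(cycles) - 2

    def test_accepted_cycles_have_valid_t0(self):
        rec = generate_recording([CycleSpec(noise_sd=0.005)] * 8, wander_amplitude=0.1, seed=3)
        nrm = normalize_recording(smooth_waveform(rec))
        for c in segment_cycles(nrm):
            if not c.accepted:
                continue
            detect_dicrotic_notch(c)
            if c.accepted:
                assert c.T0 is not None and 0.0 < c.T0 < c.T


class TestNotchDetection:
    def test_localized_dip_found_within_10ms(self):
        cyc = generate_cycle(CycleSpec(notch_dip=0.05, noise_sd=0.0))
        t_true = cyc.T0
        cyc.T0 = None
        detect_dicrotic_notch(cyc)
        assert cyc.accepted and cyc.T0 is not None
        assert abs(cyc.T0 - t_true) <= 0.010

    @staticmethod
    def _featureless_decay(dip_at=None):
        """Fast rise, then pure exponential decay: no notch evidence."""
        from ifpwv.preprocess import CardiacCycle

        T = 0.85
        t = np.arange(int(T * FS)) / FS
        rise = t / 0.12
        decay = np.exp(-2.5 * (t - 0.12))
        s = np.where(t < 0.12, rise, decay)
        if dip_at is not None:
            s = s - 0.08 * np.exp(-0.5 * ((t - dip_at * T) / 0.02) ** 2)
        return CardiacCycle(samples=s, fs=FS, T=T)

    def test_monotone_diastole_rejected(self):
        cyc = self._featureless_decay()
        detect_dicrotic_notch(cyc)
        assert not cyc.accepted
        assert cyc.reject_reason == "no notch"

    def test_dip_outside_admissible_window_rejected(self):
        cyc = self._featureless_decay(dip_at=0.05)
        detect_dicrotic_notch(cyc)
        assert not cyc.accepted
        assert cyc.reject_reason == "no notch"
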