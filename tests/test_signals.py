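"""Demodulation pipeline: trigger splitting, DFT, dual gain, uncertainties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rheoref.signals import (
    ChannelCalibration,
    HarmonicComponent,
    RawRecord,
    Segment,
    amplitude_ratio,
    dft_fundamental,
    estimate_uncertainty,
    merge_dual_gain,
    select_periods,
    split_by_trigger,
)


def make_record(n_blocks=5, block=400, fs=100.0):
    n = n_blocks * block
    t = np.arange(n) / fs
    trig = np.zeros(n)
    for b in range(n_blocks):
        trig[b * block : b * block + block // 2] = 5.0
    z = np.zeros(n)
    return RawRecord(t=t, v_theta=z, v_torque_lo=z, v_torque_hi=z,
                     v_trigger=trig, fs=fs)


def make_segment(x, fs=100.0, calib=None):
    return Segment(t0=0.0, fs=fs, v_theta=x, v_torque_lo=x, v_torque_hi=x,
                   calib=calib or ChannelCalibration())


class TestSplitByTrigger:
    def test_five_edges_five_segments(self):
        rec = make_record(n_blocks=5)
        segs = split_by_trigger(rec)
        assert len(segs) == 5
        assert all(len(s) == 400 for s in segs)

    def test_constant_trigger_fails(self):
        rec = make_record(n_blocks=1)
        rec.v_trigger[:] = 0.0
        with pytest.raises(ValueError, match="trigger"):
            split_by_trigger(rec)

    def test_edges_at_known_indices(self):
        rec = make_record(n_blocks=3, block=250)
        segs = split_by_trigger(rec)
        starts = [int(round(s.t0 * rec.fs)) for s in segs]
        assert starts == [0, 250, 500]


class TestSelectPeriods:
    def test_transient_discard_arithmetic(self):
        # 10.6 periods at f=1, fs=100 -> discard 20% -> 8 whole periods
        x = np.zeros(1060)
        seg = make_segment(x)
        trimmed, n_p = select_periods(seg, 1.0, 0.2)
        assert n_p == 8
        assert len(trimmed) == 800

    def test_single_period_no_discard_unchanged(self):
        seg = make_segment(np.arange(100.0))
        trimmed, n_p = select_periods(seg, 1.0, 0.0)
        assert n_p == 1
        assert len(trimmed) == 100
        assert np.array_equal(trimmed.v_theta, seg.v_theta)

    def test_half_period_fails(self):
        seg = make_segment(np.zeros(50))
        with pytest.raises(ValueError):
            select_periods(seg, 1.0, 0.0)

    def test_trim_keeps_suffix(self):
        seg = make_segment(np.arange(1060.0))
        trimmed, _ = select_periods(seg, 1.0, 0.2)
        assert trimmed.v_theta[-1] == 1059.0  # ends where the raw data ends


class TestDFTFundamental:
    @pytest.mark.parametrize("A,phi", [(1.0, 0.3), (2.5, -1.2), (1e-4, 2.9)])
    def test_pure_tone_exact(self, A, phi):
        fs, f, n_p = 100.0, 2.0, 8
        t = np.arange(int(n_p * fs / f)) / fs
        x = A * np.cos(2 * np.pi * f * t + phi)
        comp = dft_fundamental(x, fs, f, gain=1.0, n_periods=n_p)
        assert comp.amplitude == pytest.approx(A, rel=1e-12)
        assert comp.phase == pytest.approx(phi, abs=1e-12)

    def test_gain_scaling(self):
        fs, f, n_p = 100.0, 2.0, 4
        t = np.arange(int(n_p * fs / f)) / fs
        x = 600.0 * np.cos(2 * np.pi * f * t)
        comp = dft_fundamental(x, fs, f, gain=600.0, n_periods=n_p)
        assert comp.amplitude == pytest.approx(1.0, rel=1e-12)

    def test_amplitude_invariant_under_phase_shift(self):
        fs, f, n_p = 100.0, 2.0, 8
        t = np.arange(int(n_p * fs / f)) / fs
        amps = [
            dft_fundamental(
                np.cos(2 * np.pi * f * t + p), fs, f, 1.0, n_p
            ).amplitude
            for p in (0.0, 0.7, 2.1)
        ]
        assert np.ptp(amps) < 1e-12

    def test_undersampled_rejected(self):
        with pytest.raises(ValueError):
            dft_fundamental(np.zeros(16), fs=4.0, f=2.0, gain=1.0, n_periods=4)

    def test_noise_monte_carlo_bound(self, rng):
        """Amplitude error < 3 sigma sqrt(2/N) in >= 99% of draws."""
        N, A, sigma = 4096, 1.0, 0.1
        f, fs = 8.0, float(N) / 8.0 * 8.0 / 64.0  # 8 periods over N samples
        n_p = 8
        fs = N * f / n_p
        t = np.arange(N) / fs
        base = A * np.cos(2 * np.pi * f * t)
        bound = 3 * sigma * np.sqrt(2.0 / N)
        hits = 0
        draws = 1000
        for _ in range(draws):
            x = base + rng.normal(0.0, sigma, N)
            amp = dft_fundamental(x, fs, f, 1.0, n_p).amplitude
            hits += abs(amp - A) < bound
        assert hits / draws >= 0.99


class TestMergeDualGain:
    def _comp(self, amp, src):
        return HarmonicComponent(f=1.0, amplitude=amp, phase=0.0,
                                 n_periods=4, source=src)

    def test_hi_selected_when_unsaturated(self):
        out = merge_dual_gain(self._comp(1.0, "lo"), self._comp(1.0, "hi"),
                              lo_raw_peak=0.02, hi_raw_peak=2.0, v_range=10.0)
        assert out.source == "hi"

    def test_lo_selected_when_hi_saturates(self):
        out = merge_dual_gain(self._comp(1.0, "lo"), self._comp(1.0, "hi"),
                              lo_raw_peak=0.099, hi_raw_peak=9.9, v_range=10.0)
        assert out.source == "lo"

    def test_both_saturated_fails(self):
        with pytest.raises(ValueError, match="saturated"):
            merge_dual_gain(self._comp(1.0, "lo"), self._comp(1.0, "hi"),
                            lo_raw_peak=9.9, hi_raw_peak=9.9, v_range=10.0)


class TestAmplitudeRatio:
    def _comp(self, amp, phase, f=1.0):
        return HarmonicComponent(f=f, amplitude=amp, phase=phase, n_periods=4)

    def test_antiphase_arithmetic(self):
        ar = amplitude_ratio(self._comp(2.0, np.pi), self._comp(1.0, 0.0))
        assert ar.AR == pytest.approx(-2.0 + 0j, abs=1e-12)

    def test_identical_signals_unity(self):
        ar = amplitude_ratio(self._comp(1.3, 0.4), self._comp(1.3, 0.4))
        assert ar.AR == pytest.approx(1.0 + 0j, abs=1e-12)

    def test_zero_angle_rejected(self):
        with pytest.raises(ValueError):
            amplitude_ratio(self._comp(1.0, 0.0), self._comp(0.0, 0.0))

    def test_common_time_shift_invariance(self):
        """Shifting both channels by the same delay leaves AR unchanged."""
        fs, f, n_p = 200.0, 2.0, 6
        n = int(n_p * fs / f)
        t = np.arange(n) / fs
        for delay in (0.0, 0.013, 0.31):
            th = np.cos(2 * np.pi * f * (t - delay))
            tq = 3.0 * np.cos(2 * np.pi * f * (t - delay) + 2.2)
            a = dft_fundamental(th, fs, f, 1.0, n_p)
            q = dft_fundamental(tq, fs, f, 1.0, n_p)
            ar = amplitude_ratio(q, a)
            assert ar.AR == pytest.approx(3.0 * np.exp(2.2j), rel=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(
        amp=st.floats(min_value=1e-6, max_value=1e3),
        ph=st.floats(min_value=-3.1, max_value=3.1),
    )
    def test_modulus_and_phase_recovered(self, amp, ph):
        ar = amplitude_ratio(self._comp(amp, ph), self._comp(1.0, 0.0))
        assert abs(ar.AR) == pytest.approx(amp, rel=1e-12)
        assert np.angle(ar.AR) == pytest.approx(ph, abs=1e-9)


class TestUncertainty:
    def _tone(self, N, A, sigma, rng, n_p=8):
        f = 2.0
        fs = N * f / n_p
        t = np.arange(N) / fs
        x = A * np.cos(2 * np.pi * f * t)
        if sigma > 0:
            x = x + rng.normal(0.0, sigma, N)
        return x, fs, f, n_p

    def test_noiseless_floor(self, rng):
        x, fs, f, n_p = self._tone(1024, 1.0, 0.0, rng)
        comp = dft_fundamental(x, fs, f, 1.0, n_p)
        s_amp, s_ph = estimate_uncertainty(x, 1.0, comp)
        assert s_amp < 1e-12
        assert not comp.below_noise

    def test_white_noise_prediction_vs_monte_carlo(self, rng):
        """Predicted sigma_amplitude within 20% of the Monte-Carlo spread."""
        N, A, sigma = 2048, 1.0, 0.05
        amps, sig_est = [], []
        for _ in range(300):
            x, fs, f, n_p = self._tone(N, A, sigma, rng)
            comp = dft_fundamental(x, fs, f, 1.0, n_p)
            s_amp, _ = estimate_uncertainty(x, 1.0, comp)
            amps.append(comp.amplitude)
            sig_est.append(s_amp)
        mc = float(np.std(amps))
        pred = float(np.mean(sig_est))
        assert pred == pytest.approx(mc, rel=0.2)

    def test_phase_sigma_diverges_at_small_amplitude(self, rng):
        x, fs, f, n_p = self._tone(1024, 1e-9, 0.1, rng)
        comp = dft_fundamental(x, fs, f, 1.0, n_p)
        s_amp, s_ph = estimate_uncertainty(x, 1.0, comp)
        assert comp.below_noise
        assert s_ph > 10.0 * s_amp

    @pytest.mark.parametrize("snr", [3.0, 30.0, 1000.0])
    def test_consistency_across_snr(self, rng, snr):
        """Estimator within 2x of Monte-Carlo truth over a wide SNR span."""
        N, A = 1024, 1.0
        sigma = A / snr
        amps, sig_est = [], []
        for _ in range(200):
            x, fs, f, n_p = self._tone(N, A, sigma, rng)
            comp = dft_fundamental(x, fs, f, 1.0, n_p)
            s_amp, _ = estimate_uncertainty(x, 1.0, comp)
            amps.append(comp.amplitude)
            sig_est.append(s_amp)
        mc = float(np.std(amps))
        pred = float(np.mean(sig_est))
        assert 0.5 * mc < pred < 2.0 * mc
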