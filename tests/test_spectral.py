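"""Windowing, 2-D DFT, PRF masking, spectral scaling/averaging, sonograms."""

import numpy as np
import pytest

from mfudsa import (
    AcquisitionSpec,
    IQDataset,
    PulseSpec,
    Spectrum2D,
    VelocitySpectrum,
    WindowSpec,
    apply_bartlett,
    baseline_1d_spectrum,
    build_sonogram,
    constant_waveform,
    cosine_waveform,
    doppler_to_velocity,
    fft2d,
    lowpass_prf,
    mfudsa_spectrum,
    nyquist_velocity,
    segment_pulse_lines,
    simulate_gate,
    spectral_scale_average,
)
from mfudsa.metrics import fwhm_of_spectrum
from mfudsa.spectral import _pulse_band


class TestSegmentation:
    def test_welch_segment_count(self, iq_constant_clean):
        # n_slow = 1000, win 128, overlap 0.75 -> hop 32, 28 segments
        win = WindowSpec(128, 0.75)
        assert win.hop == 32
        assert win.n_segments(1000) == 28

    def test_window_equal_to_record_gives_one_segment(self, iq_constant_clean):
        win = WindowSpec(iq_constant_clean.n_slow, 0.5)
        segs = list(segment_pulse_lines(iq_constant_clean, None, win))
        assert len(segs) == 1
        assert segs[0].shape == iq_constant_clean.data.shape

    def test_full_roi_keeps_all_fast_rows(self, iq_constant_clean):
        seg = next(segment_pulse_lines(iq_constant_clean, None, WindowSpec(64, 0.0)))
        assert seg.shape[0] == iq_constant_clean.n_fast

    def test_oversized_window_rejected(self, iq_constant_clean):
        with pytest.raises(ValueError):
            list(segment_pulse_lines(iq_constant_clean, None,
                                     WindowSpec(iq_constant_clean.n_slow + 1)))

    def test_bad_roi_rejected(self, iq_constant_clean):
        with pytest.raises(ValueError):
            list(segment_pulse_lines(iq_constant_clean, (10, 100), WindowSpec(64)))


class TestBartlett:
    def test_length_five_window_values(self):
        out = apply_bartlett(np.ones(5), axes=(0,))
        np.testing.assert_allclose(out, [0, 0.5, 1.0, 0.5, 0], atol=1e-12)

    def test_windowing_twice_equals_squared_window(self):
        x = np.arange(12, dtype=complex).reshape(3, 4)
        twice = apply_bartlett(apply_bartlett(x))
        w = np.outer(np.bartlett(3), np.bartlett(4)) ** 2
        np.testing.assert_allclose(twice, x * w, atol=1e-12)

    def test_reduces_sidelobes_of_truncated_tone(self):
        # FFT oracle on a fixed off-bin tone: sidelobe-to-mainlobe improves
        n = 128
        tone = np.exp(2j * np.pi * 10.37 * np.arange(n) / n)

        def side_to_main(x):
            p = np.abs(np.fft.fft(x)) ** 2
            ipk = np.argmax(p)
            keep = np.abs(np.arange(n) - ipk) > 4
            return p[keep].max() / p.max()

        assert side_to_main(apply_bartlett(tone, (0,))) < side_to_main(tone)


class TestFFT2D:
    def test_constant_matrix_concentrates_at_dc(self):
        spec = fft2d(np.ones((8, 16), dtype=complex), 20e6, 4000, 5e6)
        i, j = np.unravel_index(np.argmax(spec.power), spec.power.shape)
        assert spec.f_rf_axis[i] == pytest.approx(5e6)
        assert spec.f_d_axis[j] == pytest.approx(0.0)
        assert spec.power.sum() == pytest.approx(spec.power[i, j])

    def test_slow_time_tone_maps_to_single_doppler_column(self):
        prf, ns = 4000.0, 64
        f0 = 10 * prf / ns
        x = np.ones((4, 1)) * np.exp(2j * np.pi * f0 * np.arange(ns) / prf)
        spec = fft2d(x, 20e6, prf, 5e6)
        j = np.argmax(spec.power.sum(axis=0))
        assert spec.f_d_axis[j] == pytest.approx(f0)

    def test_parseval(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((16, 32)) + 1j * rng.standard_normal((16, 32))
        spec = fft2d(x, 20e6, 4000, 5e6)
        energy = np.sum(np.abs(x) ** 2)
        assert abs(spec.power.sum() / (16 * 32) - energy) / energy < 1e-9

    def test_doppler_axis_interval(self):
        spec = fft2d(np.ones((4, 8), dtype=complex), 20e6, 4000, 5e6)
        assert spec.f_d_axis[0] > -2000.0
        assert spec.f_d_axis[-1] == pytest.approx(2000.0)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fft2d(np.ones((1, 8), dtype=complex), 20e6, 4000, 5e6)

    def test_ridge_slope_recovers_doppler_law(self, pulse5mhz):
        # least-squares fit of per-column peaks: slope = 2 v cos(theta)/c (3%)
        acq = AcquisitionSpec(prf=4000, n_slow=512, snr_db=None, seed=0)
        iq = simulate_gate(constant_waveform(0.2), pulse5mhz, acq,
                           scatterers="single")
        win = WindowSpec(128, 0.75)
        seg = apply_bartlett(next(segment_pulse_lines(iq, None, win)))
        spec = fft2d(seg, 20e6, 4000.0, 5e6)
        bw, _, _ = _pulse_band(iq)
        band = np.abs(spec.f_rf_axis - 5e6) <= bw / 2
        F = spec.f_rf_axis[band]
        peaks = spec.f_d_axis[np.argmax(spec.power[band], axis=1)]
        slope = np.polyfit(F, peaks, 1)[0]
        assert slope == pytest.approx(2 * 0.2 / 1540.0, rel=0.03)


class TestLowpassPRF:
    def _white(self, seed=2):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((32, 256)) + 1j * rng.standard_normal((32, 256))
        return fft2d(x, 20e6, 4000, 5e6)

    def test_interior_unchanged(self):
        spec = self._white()
        out = lowpass_prf(spec, 0.9)
        inside = np.abs(spec.f_d_axis) < 0.9 * 0.9 * 2000
        np.testing.assert_array_equal(out.power[:, inside], spec.power[:, inside])

    def test_nyquist_component_zeroed(self):
        spec = self._white()
        out = lowpass_prf(spec, 0.9)
        at_nyq = np.isclose(np.abs(spec.f_d_axis), 2000.0)
        assert np.all(out.power[:, at_nyq] == 0)

    def test_white_noise_power_matches_passband_fraction(self):
        # closed-form mean of the raised-cosine mask vs Monte-Carlo power
        spec = self._white()
        out = lowpass_prf(spec, 0.9)
        edge, knee = 0.9 * 2000.0, 0.9 * 0.9 * 2000.0
        frac = (knee + 0.5 * (edge - knee)) / 2000.0
        assert out.power.sum() / spec.power.sum() == pytest.approx(frac, rel=0.02)


class TestScaleAverage:
    def _flat_spec(self, n_rf=16, n_d=16):
        f_rf = 5e6 + np.linspace(-2e6, 2e6, n_rf)
        f_d = np.linspace(-2000, 2000, n_d)
        return Spectrum2D(power=np.ones((n_rf, n_d)), f_rf_axis=f_rf,
                          f_d_axis=f_d, fc=5e6, prf=4000.0)

    def test_zero_spectrum_gives_zero_output(self):
        spec = self._flat_spec()
        spec = Spectrum2D(power=spec.power * 0, f_rf_axis=spec.f_rf_axis,
                          f_d_axis=spec.f_d_axis, fc=5e6, prf=4000.0)
        _, out = spectral_scale_average(spec, 5e6, 2e6)
        assert np.all(out == 0)

    def test_flat_spectrum_with_flat_weight_stays_flat(self):
        # brute-force oracle on a 16x16 grid: interior bins keep unit level
        spec = self._flat_spec()
        fd, out = spectral_scale_average(spec, 5e6, 2e6)
        interior = np.abs(fd) <= 2000.0 / (1 + 2e6 / (2 * 5e6)) * 0.95
        np.testing.assert_allclose(out[interior], 1.0, rtol=1e-9)

    def test_bandwidth_exceeding_rf_span_rejected(self):
        with pytest.raises(ValueError):
            spectral_scale_average(self._flat_spec(), 5e6, 10e6)

    def test_collapse_of_the_multifrequency_ridge(self, iq_constant_clean):
        # realigned average at least as narrow as the unscaled RF marginal,
        # strictly narrower for this broadband pulse (BW/fc ~ 0.44)
        iq = iq_constant_clean
        win = WindowSpec(128, 0.75)
        bw, _, _ = _pulse_band(iq)
        acc = None
        for seg in segment_pulse_lines(iq, None, win):
            spec = lowpass_prf(fft2d(apply_bartlett(seg), 20e6, 4000.0, 5e6))
            band = np.abs(spec.f_rf_axis - 5e6) <= bw / 2
            marg = spec.power[band].sum(axis=0)
            acc = marg if acc is None else acc + marg
        v = doppler_to_velocity(spec.f_d_axis, 5e6, 1540.0, 0.0)
        marginal = VelocitySpectrum(power=acc, f_d_axis=spec.f_d_axis, v_axis=v)
        realigned = mfudsa_spectrum(iq, win=win)
        assert fwhm_of_spectrum(realigned) < fwhm_of_spectrum(marginal)


class TestVelocityMapping:
    def test_closed_forms(self):
        assert doppler_to_velocity(0.0, 5e6, 1540.0) == 0.0
        assert doppler_to_velocity(1298.7, 5e6, 1540.0) == pytest.approx(
            0.200, abs=1e-4)

    def test_beam_angle_rejected_at_right_angle(self):
        with pytest.raises(ValueError):
            doppler_to_velocity(100.0, 5e6, 1540.0, np.pi / 2)

    def test_nyquist_velocity_below_cosine_peak_at_prf_4k(self):
        # why a +-40 cm/s cosine aliases at PRF 4 kHz but not at 7 kHz
        assert nyquist_velocity(4000.0, 5e6, 1540.0) == pytest.approx(0.308)
        assert nyquist_velocity(4000.0, 5e6, 1540.0) < 0.40
        assert nyquist_velocity(7000.0, 5e6, 1540.0) > 0.40


class TestEstimators:
    def test_mfudsa_locates_constant_velocity(self, iq_constant):
        vs = mfudsa_spectrum(iq_constant)
        assert abs(vs.peak_velocity() - 0.2) <= vs.dv

    def test_mfudsa_zero_velocity_peaks_at_zero(self, pulse5mhz):
        acq = AcquisitionSpec(prf=4000, n_slow=512, snr_db=20.0, seed=4)
        vs = mfudsa_spectrum(simulate_gate(constant_waveform(0.0), pulse5mhz, acq))
        assert abs(vs.peak_velocity()) <= vs.dv

    def test_opposite_velocities_mirror(self, pulse5mhz):
        acq = AcquisitionSpec(prf=4000, n_slow=2048, snr_db=20.0, seed=5)
        vp = mfudsa_spectrum(simulate_gate(constant_waveform(0.15), pulse5mhz, acq))
        vm = mfudsa_spectrum(simulate_gate(constant_waveform(-0.15), pulse5mhz, acq))
        assert vp.peak_velocity() == pytest.approx(-vm.peak_velocity(), abs=vp.dv)
        assert vp.power.max() == pytest.approx(vm.power.max(), rel=0.10)

    def test_baseline_matches_truth_location(self, iq_constant):
        vs = baseline_1d_spectrum(iq_constant)
        assert abs(vs.peak_velocity() - 0.2) <= 3 * vs.dv  # broadened peak

    def test_baseline_pure_noise_is_flat(self, pulse5mhz):
        rng = np.random.default_rng(11)
        acq = AcquisitionSpec(prf=4000, n_slow=4096, n_fast=64, snr_db=None, seed=0)
        data = rng.standard_normal((64, 4096)) + 1j * rng.standard_normal((64, 4096))
        iq = IQDataset(data=data, pulse=pulse5mhz, acq=acq)
        vs = baseline_1d_spectrum(iq)
        assert vs.power.max() / vs.power.mean() < 2.0

    def test_narrowband_limit_matches_baseline(self):
        # BW -> one RF bin: the 2-D estimator degenerates to the 1-D one
        p = PulseSpec(fc=5e6, half_cycles=28, fs_fast=20e6)
        acq = AcquisitionSpec(prf=4000, n_slow=512, snr_db=None, seed=0)
        iq = simulate_gate(constant_waveform(0.15), p, acq, scatterers="single")
        m = mfudsa_spectrum(iq, window_axes=(1,))
        b = baseline_1d_spectrum(iq, gate_len=64)
        assert np.max(np.abs(m.power / m.power.max()
                             - b.power / b.power.max())) <= 0.05

    def test_mfudsa_wider_than_baseline_for_narrowband_is_false_when_broadband(
            self, iq_constant):
        # broadband pulse: 1-D resolution strictly worse (transit broadening)
        m = fwhm_of_spectrum(mfudsa_spectrum(iq_constant))
        b = fwhm_of_spectrum(baseline_1d_spectrum(iq_constant))
        assert b > m


class TestSonogram:
    def test_constant_velocity_gives_horizontal_ridge(self, iq_constant):
        sono = build_sonogram(iq_constant)
        ridge = sono.ridge()
        dv = sono.v_axis[1] - sono.v_axis[0]
        assert np.all(np.abs(ridge - 0.2) <= 2 * dv)
        assert len(sono.t_axis) == WindowSpec().n_segments(iq_constant.n_slow)

    def test_cosine_ridge_reaches_extremes_at_prf_7k(self, pulse5mhz):
        acq = AcquisitionSpec(prf=7000, n_slow=21000, snr_db=20.0, seed=1)
        iq = simulate_gate(cosine_waveform(0.40, period=1.0), pulse5mhz, acq)
        sono = build_sonogram(iq)
        ridge = sono.ridge()
        dv = sono.v_axis[1] - sono.v_axis[0]
        assert abs(ridge.max() - 0.40) <= dv
        assert abs(ridge.min() + 0.40) <= dv

    def test_cosine_ridge_wraps_at_prf_4k(self, pulse5mhz):
        # 40 cm/s exceeds v_nyq = 30.8 cm/s: the ridge aliases
        acq = AcquisitionSpec(prf=4000, n_slow=2000, snr_db=20.0, seed=1)
        iq = simulate_gate(cosine_waveform(0.40, period=1.0), pulse5mhz, acq)
        ridge = build_sonogram(iq).ridge()
        vnyq = nyquist_velocity(4000.0, 5e6, 1540.0)
        assert ridge.max() <= vnyq
        assert ridge.max() < 0.35  # the 0.40 m/s extreme is never recovered

    def test_baseline_method_produces_same_geometry(self, iq_constant):
        a = build_sonogram(iq_constant, method="mfudsa")
        b = build_sonogram(iq_constant, method="baseline")
        assert a.power.shape == b.power.shape
        np.testing.assert_allclose(a.t_axis, b.t_axis)
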