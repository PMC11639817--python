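"""Model synthesis, Fourier transform conventions, and unit conversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import amaresfit as af
from amaresfit.signal_model import peak_fwhm

from conftest import make_singlet


class TestSynthesis:
    def test_zero_frequency_zero_damping_is_constant(self):
        fid = af.synthesize_fid(
            [af.PeakParameters(1, 0, 0, 0, 0)],
            n_points=16,
            dwell_time=1e-3,
            carrier_mhz=100,
        )
        assert np.allclose(fid.samples, 1.0 + 0.0j)

    def test_first_point_is_amplitude_times_phase_factor(self):
        fid = af.synthesize_fid(
            [af.PeakParameters(2, 0, 0, 90, 0)],
            n_points=8,
            dwell_time=1e-3,
            carrier_mhz=100,
        )
        assert fid.samples[0] == pytest.approx(2j, abs=1e-14)

    def test_additive_over_peaks(self):
        p1 = af.PeakParameters(1.2, 100, 20, 10, 0)
        p2 = af.PeakParameters(0.5, -300, 50, -40, 0.3)
        kwargs = dict(n_points=128, dwell_time=2e-4, carrier_mhz=120.645)
        combined = af.synthesize_fid([p1, p2], **kwargs)
        separate = (
            af.synthesize_fid([p1], **kwargs).samples
            + af.synthesize_fid([p2], **kwargs).samples
        )
        np.testing.assert_allclose(combined.samples, separate, rtol=0, atol=1e-14)

    def test_amplitude_scaling_is_linear(self):
        kwargs = dict(n_points=64, dwell_time=2e-4, carrier_mhz=100)
        base = af.synthesize_fid([af.PeakParameters(1, 150, 30, 25, 0)], **kwargs)
        scaled = af.synthesize_fid([af.PeakParameters(3, 150, 30, 25, 0)], **kwargs)
        np.testing.assert_allclose(scaled.samples, 3 * base.samples, rtol=1e-14)

    def test_lorentzian_modulus_is_pure_exponential(self):
        d = 182.6
        fid = make_singlet(amplitude=1.4, damping=d, phase_deg=77.0)
        expected = 1.4 * np.exp(-d * fid.time_axis)
        np.testing.assert_allclose(np.abs(fid.samples), expected, rtol=1e-12)

    def test_dead_time_enters_the_time_axis(self):
        fid = make_singlet(damping=100.0, dead_time=5e-3)
        assert fid.time_axis[0] == pytest.approx(5e-3)
        assert np.abs(fid.samples[0]) == pytest.approx(np.exp(-100.0 * 5e-3))

    @given(phase=st.floats(-360, 360, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_phase_wraps_every_360_degrees(self, phase):
        kwargs = dict(n_points=32, dwell_time=1e-3, carrier_mhz=100)
        a = af.synthesize_fid([af.PeakParameters(1, 50, 10, phase, 0)], **kwargs)
        b = af.synthesize_fid([af.PeakParameters(1, 50, 10, phase + 360, 0)], **kwargs)
        np.testing.assert_allclose(a.samples, b.samples, rtol=0, atol=1e-12)

    def test_rejects_empty_and_nonfinite(self):
        with pytest.raises(ValueError, match="empty"):
            af.synthesize_fid([], n_points=8, dwell_time=1e-3, carrier_mhz=100)
        with pytest.raises(ValueError, match="amplitude"):
            af.PeakParameters(np.nan, 0, 0, 0, 0)
        with pytest.raises(ValueError, match="g"):
            af.PeakParameters(1, 0, 0, 0, 1.5)


class TestSpectrum:
    def test_impulse_has_flat_magnitude(self):
        samples = np.zeros(64, dtype=complex)
        samples[0] = 1.0
        fid = af.FIDSignal(samples, dwell_time=1e-3, carrier_mhz=100)
        spec = af.fid_to_spectrum(fid)
        np.testing.assert_allclose(spec.magnitude, 1.0, rtol=1e-12)

    def test_constant_fid_peaks_at_zero_hertz(self):
        fid = af.FIDSignal(np.ones(64), dwell_time=1e-3, carrier_mhz=100)
        spec = af.fid_to_spectrum(fid)
        assert spec.freq_hz[np.argmax(spec.magnitude)] == pytest.approx(0.0)

    def test_parseval_under_documented_normalization(self, singlet_fid):
        spec = af.fid_to_spectrum(singlet_fid)
        time_energy = np.sum(np.abs(singlet_fid.samples) ** 2)
        freq_energy = np.sum(np.abs(spec.intensities) ** 2) / singlet_fid.n_points
        assert freq_energy == pytest.approx(time_energy, rel=1e-12)

    def test_singlet_peak_lands_on_nearest_bin(self):
        fid = make_singlet(frequency_hz=237.0)
        spec = af.fid_to_spectrum(fid)
        bin_width = fid.sw_hz / fid.n_points
        assert abs(spec.freq_hz[np.argmax(spec.magnitude)] - 237.0) <= bin_width

    def test_zero_fill_must_cover_the_fid(self, singlet_fid):
        with pytest.raises(ValueError, match="zero_fill"):
            af.fid_to_spectrum(singlet_fid, zero_fill=singlet_fid.n_points - 1)

    def test_first_order_phase_is_a_time_delay(self, singlet_fid):
        tau = 2e-4
        spec = af.fid_to_spectrum(singlet_fid, phase1_s=tau)
        plain = af.fid_to_spectrum(singlet_fid)
        expected = plain.intensities * np.exp(2j * np.pi * plain.freq_hz * tau)
        np.testing.assert_allclose(spec.intensities, expected, rtol=1e-12)


class TestUnitConversions:
    def test_xenon_resolution_in_ppm(self):
        # 20 kHz over 256 points at 35.3 MHz: 78.125 Hz per point = 2.21 ppm
        hz_per_point = 20000.0 / 256
        assert hz_per_point == pytest.approx(78.125)
        assert af.hz_to_ppm(hz_per_point, 35.3) == pytest.approx(2.21, abs=5e-3)

    def test_reference_point_maps_to_zero_hertz(self):
        assert af.ppm_to_hz(4.7, 49.9, ref_ppm=4.7) == pytest.approx(0.0)

    @given(hz=st.floats(-5000, 5000, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_is_identity(self, hz):
        carrier, ref = 120.645, 4.7
        back = af.ppm_to_hz(af.hz_to_ppm(hz, carrier, ref), carrier, ref)
        assert back == pytest.approx(hz, abs=1e-9)

    def test_invalid_carrier_rejected(self):
        with pytest.raises(ValueError):
            af.hz_to_ppm(10.0, 0.0)


class TestLinewidthDamping:
    def test_lorentzian_bijection_is_pi_times_linewidth(self):
        d = af.linewidth_to_damping(58.12, g=0)
        assert d == pytest.approx(np.pi * 58.12)
        assert af.damping_to_linewidth(d, g=0) == pytest.approx(58.12)

    def test_measured_fwhm_matches_the_linewidth(self):
        # numeric FWHM oracle on a densely zero-filled pure singlet
        lw = 58.12
        fid = make_singlet(
            frequency_hz=0.0, damping=af.linewidth_to_damping(lw), phase_deg=0.0,
            n_points=2048,
        )
        # absorption-profile width (magnitude is sqrt(3) wider for a
        # Lorentzian); halving the first sample removes the rectangle-rule
        # baseline offset of the DFT so the discrete width matches the
        # continuous one
        samples = fid.samples.copy()
        samples[0] *= 0.5
        spec = af.fid_to_spectrum(fid.with_samples(samples), zero_fill=64 * fid.n_points)
        measured = peak_fwhm(spec.freq_hz, spec.intensities.real)
        assert measured == pytest.approx(lw, rel=5e-3)

    def test_zero_linewidth_and_monotonicity(self):
        assert af.linewidth_to_damping(0.0, g=0.7) == 0.0
        widths = np.linspace(0, 100, 11)
        dampings = [af.linewidth_to_damping(w, g=0.4) for w in widths]
        assert np.all(np.diff(dampings) > 0)

    def test_negative_linewidth_rejected(self):
        with pytest.raises(ValueError):
            af.linewidth_to_damping(-1.0)


class TestFIDSignal:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            af.FIDSignal(np.ones(1), dwell_time=1e-3, carrier_mhz=100)
        with pytest.raises(ValueError):
            af.FIDSignal(np.ones(8), dwell_time=-1e-3, carrier_mhz=100)
        with pytest.raises(ValueError):
            af.FIDSignal(np.ones(8), dwell_time=1e-3, carrier_mhz=100, dead_time=-1)

    def test_time_axis_strictly_increasing(self, singlet_fid):
        assert np.all(np.diff(singlet_fid.time_axis) > 0)
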