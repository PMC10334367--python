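import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qus_settingcal import (
    CalibrationStack,
    FIRFilter,
    PowerSpectrum,
    RFFrame,
    apply_filter_to_frame,
    compute_gamma,
    design_linear_phase_fir,
    estimate_line_spectrum,
    wiener_regularize,
)
from qus_settingcal.calibration import ANALYSIS_BAND_HZ
from qus_settingcal.transfer import filter_frequency_response

FS = 40e6


def _ps(power, freqs=None):
    power = np.asarray(power, dtype=float)
    if freqs is None:
        freqs = np.linspace(0, FS / 2, len(power))
    return PowerSpectrum(freqs, power)


class TestComputeGamma:
    def test_identity_setting(self):
        ps = _ps(np.full(257, 2.0))
        np.testing.assert_allclose(compute_gamma(ps, ps), 1.0)

    def test_minus_6db_power_ratio(self):
        # -6 dB output power: test power spectrum = 0.251 x train
        tr = _ps(np.full(257, 4.0))
        te = _ps(np.full(257, 4.0) * 10 ** (-6 / 10))
        np.testing.assert_allclose(
            compute_gamma(tr, te), 10 ** (-6 / 20), rtol=1e-12
        )

    def test_zero_train_power_is_flagged_not_fatal(self):
        tr = _ps([0.0, 4.0, 4.0, 1.0])
        te = _ps([9.0, 4.0, 1.0, 1.0])
        g = compute_gamma(tr, te)
        assert g[0] == 0.0
        gw, gwi = wiener_regularize(g, np.array([0.0, 100.0, 100.0, 0.0]))
        assert np.all(np.isfinite(gw)) and np.all(np.isfinite(gwi))

    def test_grid_mismatch_rejected(self):
        tr = _ps(np.ones(8))
        te = _ps(np.ones(8), freqs=np.linspace(0, 10e6, 8))
        with pytest.raises(ValueError, match="grid"):
            compute_gamma(tr, te)


class TestWienerRegularize:
    def test_unit_gamma_unit_snr(self):
        gw, gwi = wiener_regularize(np.array([1.0]), np.array([1.0]))
        assert gw[0] == pytest.approx(0.5)
        assert gwi[0] == pytest.approx(0.5)

    def test_high_snr_limits(self):
        g = np.array([0.25, 1.0, 4.0])
        gw, gwi = wiener_regularize(g, np.full(3, 1e12))
        np.testing.assert_allclose(gw, g, rtol=1e-6)
        np.testing.assert_allclose(gwi, 1.0 / g, rtol=1e-6)

    def test_zero_snr_zeroes_both_responses(self):
        gw, gwi = wiener_regularize(np.array([0.5, 2.0]), np.zeros(2))
        assert np.all(gw == 0.0) and np.all(gwi == 0.0)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        g=st.floats(1e-3, 1e3),
        s=st.floats(0.0, 1e9),
    )
    def test_forward_backward_product_bounded_by_one(self, g, s):
        gw, gwi = wiener_regularize(np.array([g]), np.array([s]))
        assert gw[0] * gwi[0] <= 1.0 + 1e-9
        # equality is reached only in the infinite-SNR limit
        gw_inf, gwi_inf = wiener_regularize(np.array([g]), np.array([1e14]))
        assert gw_inf[0] * gwi_inf[0] == pytest.approx(1.0, rel=1e-6)


class TestFIRDesign:
    def _freqs(self):
        return np.linspace(0, FS / 2, 257)

    def test_all_pass_is_unit_impulse(self):
        f = design_linear_phase_fir(self._freqs(), np.ones(257), 51, FS)
        assert f.taps[25] >= 0.99
        assert np.sum(f.taps**2) - f.taps[25] ** 2 <= 1e-2

    def test_all_stop_is_zero(self):
        f = design_linear_phase_fir(self._freqs(), np.zeros(257), 51, FS)
        np.testing.assert_allclose(f.taps, 0.0, atol=1e-12)

    def test_smooth_bandpass_tracked_within_5pct_in_band(self):
        freqs = self._freqs()
        gains = np.exp(-((freqs - 5e6) ** 2) / (2 * (2e6) ** 2))
        filt = design_linear_phase_fir(freqs, gains, 51, FS)
        realized = filter_frequency_response(filt, freqs, FS)
        band = gains >= 0.5 * gains.max()
        assert np.abs(realized[band] / gains[band] - 1).max() < 0.05

    def test_taps_are_symmetric_and_odd(self):
        freqs = self._freqs()
        gains = np.exp(-((freqs - 6e6) ** 2) / (2 * (2.5e6) ** 2))
        filt = design_linear_phase_fir(freqs, gains, 51, FS)
        assert filt.n_taps == 51
        np.testing.assert_array_equal(filt.taps, filt.taps[::-1])

    def test_invalid_arguments_rejected(self):
        freqs = self._freqs()
        with pytest.raises(ValueError, match="odd"):
            design_linear_phase_fir(freqs, np.ones(257), 50, FS)
        with pytest.raises(ValueError, match="Nyquist"):
            design_linear_phase_fir(freqs * 0.5, np.ones(257), 51, FS)
        with pytest.raises(ValueError, match="nonnegative"):
            design_linear_phase_fir(freqs, np.full(257, -1.0), 51, FS)


class TestApplyFilter:
    def _impulse(self, n=51):
        taps = np.zeros(n)
        taps[n // 2] = 1.0
        return FIRFilter(taps=taps)

    def test_unit_impulse_is_identity(self, rng):
        frame = RFFrame(rng.normal(size=(400, 8)).astype(np.float32), FS)
        out = apply_filter_to_frame(frame, self._impulse())
        np.testing.assert_allclose(out.samples, frame.samples, atol=1e-6)

    def test_flat_half_gain_scales_interior(self, rng):
        freqs = np.linspace(0, FS / 2, 257)
        filt = design_linear_phase_fir(freqs, np.full(257, 0.5), 51, FS)
        frame = RFFrame(rng.normal(size=(500, 4)).astype(np.float32), FS)
        out = apply_filter_to_frame(frame, filt)
        interior = slice(30, -30)
        rel = np.abs(
            out.samples[interior] / (0.5 * frame.samples[interior].astype(float)) - 1
        )
        assert rel.max() < 0.01

    def test_single_tone_scaled_by_realized_gain(self):
        freqs = np.linspace(0, FS / 2, 257)
        gains = np.exp(-((freqs - 5e6) ** 2) / (2 * (2e6) ** 2))
        filt = design_linear_phase_fir(freqs, gains, 51, FS)
        f0 = 4.5e6
        t = np.arange(1000) / FS
        frame = RFFrame(np.sin(2 * np.pi * f0 * t)[:, None].astype(np.float32), FS)
        out = apply_filter_to_frame(frame, filt)
        g_realized = filter_frequency_response(filt, np.array([f0]), FS)[0]
        amp_in = np.abs(frame.samples[100:-100, 0]).max()
        amp_out = np.abs(out.samples[100:-100, 0]).max()
        assert amp_out / amp_in == pytest.approx(g_realized, rel=0.02)

    def test_linearity_and_shift_equivariance(self, rng):
        freqs = np.linspace(0, FS / 2, 257)
        gains = np.exp(-((freqs - 5e6) ** 2) / (2 * (2.5e6) ** 2))
        filt = design_linear_phase_fir(freqs, gains, 51, FS)
        x = rng.normal(size=(400, 2)).astype(np.float32)
        y = rng.normal(size=(400, 2)).astype(np.float32)
        fx = apply_filter_to_frame(RFFrame(x, FS), filt).samples
        fy = apply_filter_to_frame(RFFrame(y, FS), filt).samples
        fxy = apply_filter_to_frame(RFFrame(2 * x + 3 * y, FS), filt).samples
        np.testing.assert_allclose(fxy, 2 * fx + 3 * fy, atol=1e-4)
        # shifting the input shifts the output (away from the edges)
        s = 37
        xs = np.zeros_like(x)
        xs[s:] = x[:-s]
        fxs = apply_filter_to_frame(RFFrame(xs, FS), filt).samples
        np.testing.assert_allclose(fxs[s + 60 : -60], fx[60 : -60 - s], atol=1e-4)

    def test_filter_longer_than_frame_rejected(self, rng):
        frame = RFFrame(rng.normal(size=(30, 2)).astype(np.float32), FS)
        with pytest.raises(ValueError, match="length"):
            apply_filter_to_frame(frame, self._impulse(51))


class TestRoundTrip:
    def test_train_then_test_filter_preserves_in_band_spectrum(
        self, freq_calibration, grid
    ):
        """Applying the train-time filter then the test-time filter to a
        broadband frame returns the in-band spectrum within 1.5 dB."""
        _, _, (stack_a, _), cal = freq_calibration
        line = 4
        frame = stack_a.frames[0]
        once = apply_filter_to_frame(frame, cal.train_filters[line])
        back = apply_filter_to_frame(once, cal.test_filters[line])
        ps0 = estimate_line_spectrum(CalibrationStack([frame], "o"), line, grid)
        ps1 = estimate_line_spectrum(CalibrationStack([back], "b"), line, grid)
        band = (ps0.freqs_hz >= ANALYSIS_BAND_HZ[0]) & (
            ps0.freqs_hz <= ANALYSIS_BAND_HZ[1]
        )
        err_db = np.abs(10 * np.log10(ps1.power[band] / ps0.power[band]))
        assert err_db.max() < 1.5
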