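"""Spectrogram engine: axis, window-scale policy, channel responses, dB map."""

import math

import numpy as np
import pytest

import auriscale as a

RATE = 8000.0


class TestMidiAxis:
    @pytest.mark.parametrize("f, nu", [(440.0, 69.0), (880.0, 81.0), (220.0, 57.0)])
    def test_reference_points(self, f, nu):
        assert a.midi_from_frequency(f) == pytest.approx(nu)

    def test_round_trip(self):
        assert a.frequency_from_midi(a.midi_from_frequency(123.4)) == pytest.approx(123.4)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            a.midi_from_frequency(0.0)

    def test_axis_spacing(self):
        axis = a.make_log_frequency_axis(80.0, 16000.0, 48)
        assert np.allclose(np.diff(axis.nu_values), 12.0 / 48)
        assert axis.frequencies_hz[0] == pytest.approx(80.0)
        assert axis.frequencies_hz[-1] <= 16000.0 * (1 + 1e-9)


class TestWindowScalePolicy:
    def test_wavelength_proportional(self):
        pol = a.WindowScalePolicy(n=8.0, tau0=0.0)
        omega = 2 * math.pi * 440.0
        tau = a.window_variance_for_frequency(omega, pol)
        assert math.sqrt(tau) == pytest.approx(8.0 / 440.0)

    def test_high_frequency_limit_is_tau0(self):
        pol = a.WindowScalePolicy(n=8.0, tau0=1e-6)
        tau = a.window_variance_for_frequency(2 * math.pi * 1e7, pol)
        assert tau == pytest.approx(1e-6, rel=1e-3)

    def test_soft_lower_bound_crossover_frequency(self):
        """With sigma0 = 1 ms, n = 8, beta = 2 the wavelength-proportional
        scale meets beta^2 tau0 at about 4.6 kHz."""
        f = a.soft_lower_bound_frequency(1e-3, 8.0, 2.0)
        assert f == pytest.approx(4618.8, rel=1e-3)
        # consistency: tau at that frequency equals beta^2 tau0
        pol = a.WindowScalePolicy(n=8.0, tau0=1e-6)
        tau = a.window_variance_for_frequency(2 * math.pi * f, pol)
        assert tau == pytest.approx(4e-6, rel=1e-9)

    def test_soft_upper_bound_caps_scale(self):
        pol = a.WindowScalePolicy(n=8.0, tau0=0.0, tau_inf=1e-2, p=2.0)
        tau = a.window_variance_for_frequency(2 * math.pi * 1.0, pol)
        assert tau < 1e-2


@pytest.fixture(scope="module")
def axis():
    return a.make_log_frequency_axis(350, 560, 48)


@pytest.fixture(scope="module")
def tone(axis):
    j = int(np.argmin(np.abs(axis.nu_values - 69.0)))
    f = float(a.frequency_from_midi(axis.nu_values[j]))
    t = np.arange(int(0.5 * RATE)) / RATE
    return np.sin(2 * math.pi * f * t), j


class TestComputeSpectrogram:

    @pytest.mark.parametrize("family, K", [
        ("gaussian", 0), ("time_causal_uniform", 7), ("time_causal_log", 7)])
    def test_steady_state_channel_gain_is_half(self, axis, tone, family, K):
        """Unit tone at a channel center -> |S| ~ 0.5 there (n = 8)."""
        x, j = tone
        params = a.SpectrogramParams(sample_rate=RATE, axis=axis, family=family, K=K)
        S = a.compute_spectrogram(x, params)
        mid = S.magnitude[3 * len(S.times) // 4, j]
        assert mid == pytest.approx(0.5, rel=0.01)

    def test_silent_input_is_zero(self, axis):
        params = a.SpectrogramParams(sample_rate=RATE, axis=axis)
        S = a.compute_spectrogram(np.zeros(2000), params)
        assert np.all(S.magnitude == 0.0)

    def test_linearity(self, axis, tone):
        x, _ = tone
        rng = np.random.default_rng(7)
        y = rng.standard_normal(x.size) * 0.1
        params = a.SpectrogramParams(sample_rate=RATE, axis=axis,
                                     family="time_causal_uniform", K=4)
        Sx = a.compute_spectrogram(x, params).values
        Sy = a.compute_spectrogram(y, params).values
        Sxy = a.compute_spectrogram(2.0 * x - 0.5 * y, params).values
        assert np.allclose(Sxy, 2.0 * Sx - 0.5 * Sy, atol=1e-10)

    def test_temporal_shift_moves_magnitude(self, axis, tone):
        x, j = tone
        hop = 8
        shift = 10 * hop
        params = a.SpectrogramParams(sample_rate=RATE, axis=axis, hop=hop,
                                     family="time_causal_uniform", K=4)
        S1 = a.compute_spectrogram(x, params).magnitude
        S2 = a.compute_spectrogram(np.concatenate([np.zeros(shift), x]),
                                   params).magnitude
        seg = slice(len(S1) // 2, 3 * len(S1) // 4)
        shifted = S2[shift // hop:shift // hop + len(S1)]
        assert np.allclose(shifted[seg], S1[seg], atol=2e-3)

    def test_frequency_shift_covariance(self):
        """With tau0 = 0 the steady-state profile of a tone translates by
        exactly one octave (12 semitones) when the tone doubles."""
        axis = a.make_log_frequency_axis(300, 2000, 48)
        pol = a.WindowScalePolicy(n=8.0, tau0=0.0)
        j = int(np.argmin(np.abs(axis.nu_values - 69.0)))
        f1 = float(a.frequency_from_midi(axis.nu_values[j]))
        t = np.arange(int(0.5 * RATE)) / RATE
        params = a.SpectrogramParams(sample_rate=RATE, axis=axis, policy=pol,
                                     family="time_causal_log", K=7, c=math.sqrt(2.0))
        p1 = a.compute_spectrogram(np.sin(2 * math.pi * f1 * t), params)
        p2 = a.compute_spectrogram(np.sin(2 * math.pi * 2 * f1 * t), params)
        prof1 = p1.magnitude[3 * len(p1.times) // 4]
        prof2 = p2.magnitude[3 * len(p2.times) // 4]
        shift = 48  # one octave of channels
        assert np.allclose(prof2[shift:], prof1[:-shift], atol=5e-4)

    def test_bandwidth_matches_selectivity_theory(self):
        """-3 dB width of a steady tone profile ~ the analytic relative
        bandwidth 12 log2((1+theta/n)/(1-theta/n)) of the window family."""
        axis = a.make_log_frequency_axis(300, 900, 96)
        pol = a.WindowScalePolicy(n=8.0, tau0=0.0)
        j = int(np.argmin(np.abs(axis.nu_values - 69.0)))
        f1 = float(a.frequency_from_midi(axis.nu_values[j]))
        t = np.arange(int(0.5 * RATE)) / RATE
        level = 20.0 * math.log10(0.5)  # half power of the magnitude profile
        params = a.SpectrogramParams(sample_rate=RATE, axis=axis, policy=pol,
                                     family="time_causal_uniform", K=7)
        S = a.compute_spectrogram(np.sin(2 * math.pi * f1 * t), params)
        prof = S.magnitude[3 * len(S.times) // 4]
        db = 20.0 * np.log10(np.maximum(prof, 1e-12) / prof.max())
        nu = axis.nu_values
        p = int(np.argmax(db))
        i = p
        while db[i] > level:
            i -= 1
        left = nu[i] + (level - db[i]) / (db[i + 1] - db[i]) * (nu[i + 1] - nu[i])
        i = p
        while db[i] > level:
            i += 1
        right = nu[i - 1] + (level - db[i - 1]) / (db[i] - db[i - 1]) * (nu[i] - nu[i - 1])
        theta = a.theta_rec_uniform(level, 7)
        predicted = a.relative_bandwidth(theta, 8.0, "semitones")
        assert (right - left) == pytest.approx(predicted, rel=0.05)

    def test_rejects_channel_above_nyquist(self):
        axis = a.make_log_frequency_axis(1000, 6000, 12)
        with pytest.raises(ValueError):
            a.compute_spectrogram(np.zeros(100),
                                  a.SpectrogramParams(sample_rate=RATE, axis=axis))

    def test_rejects_empty_signal(self, axis):
        with pytest.raises(ValueError):
            a.compute_spectrogram(np.array([]),
                                  a.SpectrogramParams(sample_rate=RATE, axis=axis))

    def test_delay_compensation_advances_onset(self, axis):
        """Compensated time-causal channels respond earlier to a gated tone."""
        j = int(np.argmin(np.abs(axis.nu_values - 69.0)))
        f = float(a.frequency_from_midi(axis.nu_values[j]))
        x = a.synth_step_band(axis.nu_values[j], 0.2, 0.45, 0.5, RATE)
        base = a.SpectrogramParams(sample_rate=RATE, axis=axis,
                                   family="time_causal_uniform", K=7)
        comp = a.SpectrogramParams(sample_rate=RATE, axis=axis,
                                   family="time_causal_uniform", K=7,
                                   delay_compensation=True)
        m0 = a.compute_spectrogram(x, base).magnitude[:, j]
        m1 = a.compute_spectrogram(x, comp).magnitude[:, j]
        half = 0.25
        t_half0 = np.argmax(m0 > half)
        t_half1 = np.argmax(m1 > half)
        assert t_half1 < t_half0


class TestLogMagnitude:
    def test_reference_and_scaling(self, tone_log_spectrogram):
        L = tone_log_spectrogram
        assert L.values_dB.max() == pytest.approx(0.0, abs=1e-9)
        assert L.values_dB.min() >= L.floor_dB - 1e-9

    def test_explicit_reference_values(self):
        axis = a.LogFrequencyAxis(nu_values=np.array([60.0, 61.0]),
                                  channels_per_octave=12)
        S = a.ComplexSpectrogram(
            times=np.array([0.0]), axis=axis,
            values=np.array([[1.0 + 0j, 10.0 + 0j]]),
            params=None)
        L = a.to_log_magnitude(S, S0=1.0)
        assert L.values_dB[0, 0] == pytest.approx(0.0)
        assert L.values_dB[0, 1] == pytest.approx(20.0)

    def test_amplitude_scaling_shifts_dB(self, narrow_axis):
        t = np.arange(2000) / RATE
        x = np.sin(2 * math.pi * 440.0 * t)
        params = a.SpectrogramParams(sample_rate=RATE, axis=narrow_axis,
                                     family="time_causal_uniform", K=4)
        L1 = a.to_log_magnitude(a.compute_spectrogram(x, params), S0=1.0)
        L2 = a.to_log_magnitude(a.compute_spectrogram(2.0 * x, params), S0=1.0)
        d = L2.values_dB - L1.values_dB
        interior = L1.values_dB > -60  # away from the floor clamp
        assert np.allclose(d[interior], 20.0 * math.log10(2.0), atol=1e-6)


class TestGammatoneEquivalence:
    def test_parameter_identification(self):
        a_, b_ = a.gammatone_parameters(1.0, 1)
        assert (a_, b_) == (pytest.approx(1.0), pytest.approx(1.0 / (2 * math.pi)))
        _, b2 = a.gammatone_parameters(1.0 / (2 * math.pi), 5)
        assert b2 == pytest.approx(1.0)

    def test_envelope_matches_cascade_kernel(self):
        """a t^{K-1} e^{-2 pi b t} equals the equal-mu cascade kernel."""
        mu, K = 0.01, 4
        a_, b_ = a.gammatone_parameters(mu, K)
        t = np.linspace(0.0, 0.2, 5000)
        envelope = a_ * t ** (K - 1) * np.exp(-2 * math.pi * b_ * t)
        kernel = a.sample_composed_uniform_kernel(mu, K, t).values
        assert np.max(np.abs(envelope - kernel)) < 1e-10 * kernel.max()


class TestWindowDelay:
    def test_uniform_closed_form(self):
        axis = a.make_log_frequency_axis(400, 500, 48)
        pol = a.WindowScalePolicy(n=8.0, tau0=0.0)
        params = a.SpectrogramParams(sample_rate=RATE, axis=axis, policy=pol,
                                     family="time_causal_uniform", K=4)
        omega = 2 * math.pi * 8.0  # tau(omega) = 1 s^2
        expected = (3.0 - math.sqrt(3.0)) / 2.0
        assert a.window_delay(params, omega) == pytest.approx(expected, rel=1e-9)

    def test_uniform_K2_degenerates_to_zero(self):
        axis = a.make_log_frequency_axis(400, 500, 48)
        params = a.SpectrogramParams(sample_rate=RATE, axis=axis,
                                     family="time_causal_uniform", K=2)
        assert a.window_delay(params, 2 * math.pi * 8.0) == pytest.approx(0.0, abs=1e-12)

    def test_log_K1_inflects_at_origin(self):
        axis = a.make_log_frequency_axis(400, 500, 48)
        params = a.SpectrogramParams(sample_rate=RATE, axis=axis,
                                     family="time_causal_log", K=1, c=2.0)
        assert a.window_delay(params, 2 * math.pi * 440.0) == pytest.approx(0.0)

    def test_gaussian_family_not_applicable(self):
        axis = a.make_log_frequency_axis(400, 500, 48)
        params = a.SpectrogramParams(sample_rate=RATE, axis=axis, family="gaussian")
        with pytest.raises(ValueError):
            a.window_delay(params, 2 * math.pi * 440.0)
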