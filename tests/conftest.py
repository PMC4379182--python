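"""Shared fixtures: synthetic stimuli and small spectrograms.

Everything is generated at test time; sample rates and durations are kept
modest (4-16 kHz, <= 1 s) since the properties under test are scale-invariant.
"""

import math

import numpy as np
import pytest

import auriscale as a

RATE = 8000.0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def narrow_axis():
    """Axis around A4 for single-tone channel checks."""
    return a.make_log_frequency_axis(350, 560, 48)


@pytest.fixture(scope="session")
def tone_log_spectrogram(narrow_axis):
    """dB spectrogram of a steady pure tone at a channel center (time-causal)."""
    j = int(np.argmin(np.abs(narrow_axis.nu_values - 69.0)))
    f = float(a.frequency_from_midi(narrow_axis.nu_values[j]))
    t = np.arange(int(0.6 * RATE)) / RATE
    x = np.sin(2 * math.pi * f * t)
    params = a.SpectrogramParams(sample_rate=RATE, axis=narrow_axis,
                                 family="time_causal_log", K=7, c=math.sqrt(2.0))
    S = a.compute_spectrogram(x, params)
    return a.to_log_magnitude(S)


@pytest.fixture(scope="session")
def chirp_log_spectrogram():
    """dB spectrogram of a 20 semitone/s glissando chirp covering its sweep."""
    v_true = 20.0
    x = a.synth_harmonic(a.HarmonicSignalSpec(
        f0=440.0, n_partials=1, duration=0.6, sample_rate=RATE,
        glissando=v_true, onset_ramp=0.02))
    axis = a.make_log_frequency_axis(350, 1500, 48)
    params = a.SpectrogramParams(sample_rate=RATE, axis=axis,
                                 family="time_causal_log", K=7, c=math.sqrt(2.0))
    L = a.to_log_magnitude(a.compute_spectrogram(x, params))
    return L, v_true


@pytest.fixture(scope="session")
def harmonic_log_spectrogram():
    """dB spectrogram of a 20-partial, -6 dB/octave harmonic complex."""
    spec = a.HarmonicSignalSpec(f0=220.0, n_partials=20,
                                slope_db_per_octave=6.0, duration=0.5,
                                sample_rate=16000.0, onset_ramp=0.02)
    x = a.synth_harmonic(spec)
    axis = a.make_log_frequency_axis(180, 7000, 48)
    params = a.SpectrogramParams(sample_rate=16000.0, axis=axis,
                                 family="time_causal_log", K=7, c=math.sqrt(2.0))
    L = a.to_log_magnitude(a.compute_spectrogram(x, params))
    return L, spec


@pytest.fixture(scope="session")
def synthetic_blob_spectrogram():
    """A spectrogram-shaped array that is Gaussian in nu and constant in time
    (synthetic stand-in for a smooth spectral band; no audio behind it)."""
    nu = np.arange(0.0, 40.0, 0.25)
    times = np.arange(0.0, 1.0, 0.005)
    s0, A, center = 2.0, 10.0, 20.0
    blob = A * np.exp(-((nu - center) ** 2) / (2.0 * s0))
    axis = a.LogFrequencyAxis(nu_values=nu, channels_per_octave=48)
    L = a.LogSpectrogram(times=times, axis=axis,
                         values_dB=np.tile(blob, (len(times), 1)),
                         S0=1.0, floor_dB=-120.0)
    return L, dict(s0=s0, A=A, center=center)
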