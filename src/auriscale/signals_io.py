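"""Synthetic test stimuli and WAV I/O.

The synthetic suite mirrors the stimuli used to exercise the analysis chain:
harmonic complexes with a configurable number of partials and a dB/octave
spectral slope (optionally stepped through several fundamentals), pure tones,
gated narrowband events for onset/offset tests, and exponential glissando
chirps whose frequency is linear in log-frequency (a constant rate in
semitones/second).  All generators are deterministic given their spec (and a
seed where noise is involved).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

from .spectrogram import frequency_from_midi

__all__ = [
    "HarmonicSignalSpec",
    "synth_harmonic",
    "synth_step_band",
    "read_wav",
    "write_wav",
]

_LN2_OVER_12 = math.log(2.0) / 12.0


@dataclass(frozen=True)
class HarmonicSignalSpec:
    """Harmonic complex: f0 (Hz) or [(start_time, f0), ...] for stepped
    fundamentals; n_partials partials with amplitudes falling
    slope_db_per_octave; glissando in semitones/second (0 = stationary);
    onset_ramp seconds of raised-cosine fade at segment edges."""

    f0: float | tuple
    n_partials: int = 20
    slope_db_per_octave: float = 6.0
    duration: float = 1.0
    amplitude: float = 1.0
    sample_rate: float = 44100.0
    glissando: float = 0.0
    onset_ramp: float = 0.0

    def __post_init__(self) -> None:
        if self.n_partials < 1:
            raise ValueError("need at least one partial")
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        f0s = self.f0 if isinstance(self.f0, (tuple, list)) else [(0.0, self.f0)]
        for _, f in f0s:
            if f <= 0:
                raise ValueError("fundamental frequency must be positive")


def _partial_amplitudes(spec: HarmonicSignalSpec) -> np.ndarray:
    j = np.arange(1, spec.n_partials + 1, dtype=float)
    return spec.amplitude * 10.0 ** (-spec.slope_db_per_octave * np.log2(j) / 20.0)


def _render_segment(f0: float, t: np.ndarray, spec: HarmonicSignalSpec) -> np.ndarray:
    """Sum of partials j f0 with exponential glissando, exact phase integral."""
    amps = _partial_amplitudes(spec)
    v = spec.glissando
    nyq = spec.sample_rate / 2.0
    t_end = t[-1] if len(t) else 0.0
    out = np.zeros_like(t)
    dropped = 0
    for j, a in enumerate(amps, start=1):
        fj = j * f0
        f_max = fj * 2.0 ** (v * t_end / 12.0) if v > 0 else fj
        if f_max >= nyq:
            dropped += 1
            continue
        if v == 0.0:
            phase = 2.0 * math.pi * fj * t
        else:
            # integral of fj 2^{v t / 12} dt = fj (2^{v t/12} - 1) / (v ln2 / 12)
            k = v * _LN2_OVER_12
            phase = 2.0 * math.pi * fj * (np.exp(k * t) - 1.0) / k
        out += a * np.sin(phase)
    if dropped:
        warnings.warn(f"dropped {dropped} partial(s) at or above the Nyquist frequency")
    return out


def _ramp_envelope(n: int, ramp_samples: int) -> np.ndarray:
    env = np.ones(n)
    r = min(ramp_samples, n // 2)
    if r > 0:
        fade = 0.5 * (1.0 - np.cos(np.linspace(0.0, math.pi, r)))
        env[:r] = fade
        env[n - r:] = fade[::-1]
    return env


def synth_harmonic(spec: HarmonicSignalSpec) -> np.ndarray:
    """Render a harmonic complex (or a sequence of stepped fundamentals)."""
    phi0 = spec.sample_rate
    n_total = int(round(spec.duration * phi0))
    segments = (list(spec.f0) if isinstance(spec.f0, (tuple, list))
                else [(0.0, spec.f0)])
    segments = sorted(segments, key=lambda p: p[0])
    bounds = [int(round(t0 * phi0)) for t0, _ in segments] + [n_total]
    out = np.zeros(n_total)
    ramp = int(round(spec.onset_ramp * phi0))
    for (start, (_, f0)), stop in zip(zip(bounds[:-1], segments), bounds[1:]):
        n = stop - start
        if n <= 0:
            continue
        t = np.arange(n) / phi0
        seg = _render_segment(f0, t, spec)
        out[start:stop] = seg * _ramp_envelope(n, ramp)
    return out


def synth_step_band(
    center_nu: float,
    t_on: float,
    t_off: float,
    duration: float,
    sample_rate: float = 44100.0,
    amplitude: float = 1.0,
    ramp: float = 0.0,
    noise_bandwidth_semitones: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """A narrowband event gated on at t_on and off at t_off.

    By default a pure tone at the given log-frequency (MIDI) center; with
    ``noise_bandwidth_semitones > 0`` a Butterworth-bandpassed white noise of
    that width (deterministic given ``seed``).
    """
    if t_off <= t_on:
        raise ValueError("t_off must exceed t_on")
    phi0 = sample_rate
    n = int(round(duration * phi0))
    t = np.arange(n) / phi0
    f_c = float(frequency_from_midi(center_nu))
    if noise_bandwidth_semitones > 0:
        from scipy.signal import butter, sosfiltfilt

        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        half = noise_bandwidth_semitones / 2.0
        lo = float(frequency_from_midi(center_nu - half))
        hi = min(float(frequency_from_midi(center_nu + half)), 0.49 * phi0)
        sos = butter(4, [lo, hi], btype="bandpass", fs=phi0, output="sos")
        x = sosfiltfilt(sos, x)
        x *= amplitude / max(np.max(np.abs(x)), 1e-12)
    else:
        x = amplitude * np.sin(2.0 * math.pi * f_c * t)
    gate = np.zeros(n)
    i_on, i_off = int(round(t_on * phi0)), int(round(t_off * phi0))
    gate[i_on:i_off] = 1.0
    r = int(round(ramp * phi0))
    if r > 0:
        fade = 0.5 * (1.0 - np.cos(np.linspace(0.0, math.pi, r)))
        if i_on + r <= n:
            gate[i_on:i_on + r] = fade
        if i_off - r >= 0 and i_off <= n:
            gate[i_off - r:i_off] = fade[::-1]
    return x * gate


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------

def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a WAV file as float64 mono in [-1, 1]; stereo is mixed down."""
    rate, data = wavfile.read(path)
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(float) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        x = data.astype(float)
    else:
        raise IOError(f"unsupported WAV sample format {data.dtype}")
    if x.ndim == 2:
        warnings.warn("stereo input mixed down to mono")
        x = x.mean(axis=1)
    return np.asarray(x, dtype=float), float(rate)


def write_wav(path, samples, sample_rate: float, subtype: str = "float") -> None:
    """Write mono samples as float32 (lossless round-trip) or 16-bit PCM WAV."""
    x = np.asarray(samples, dtype=float)
    if subtype == "float":
        wavfile.write(path, int(sample_rate), x.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(x, -1.0, 32767.0 / 32768.0)
        wavfile.write(path, int(sample_rate),
                      np.round(clipped * 32768.0).astype(np.int16))
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")
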