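"""Multi-scale spectrograms by per-channel heterodyning and scale-space smoothing.

For every channel frequency ``omega`` the input is projected onto the two
orthogonal carriers, ``f_cos = f(t) cos(omega t)`` and
``f_sin = f(t) sin(omega t)``, each projection is smoothed with a temporal
scale-space kernel at a window scale ``tau(omega)``, and the two results are
combined into the complex channel response ``S = L(f_cos) - i L(f_sin)``.
With a Gaussian window this is (up to phase) a Gabor filter bank; with an
equal-time-constant causal cascade it is a Gammatone filter bank; with a
logarithmically distributed cascade it is a generalized Gammatone filter bank
trading frequency selectivity against temporal delay.  No block FFTs or frame
windowing are involved, so there are no framing artifacts.

The frequency axis is logarithmic (semitones, MIDI convention: 69 = 440 Hz,
12 per octave).  The window scale follows the wavelength,
``tau = tau_0 + (2 pi n / omega)^2``, which makes the channel bandwidth a
fixed number of semitones independent of frequency; the soft lower bound
``tau_0 = sigma_0^2`` keeps windows from collapsing at high frequencies and an
optional soft upper bound ``tau' = tau / (1 + (tau/tau_inf)^p)^{1/p}`` limits
delay at low frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from . import discrete_scalespace as dss
from .temporal_kernels import make_log_discretization

__all__ = [
    "LogFrequencyAxis",
    "WindowScalePolicy",
    "SpectrogramParams",
    "ComplexSpectrogram",
    "LogSpectrogram",
    "midi_from_frequency",
    "frequency_from_midi",
    "make_log_frequency_axis",
    "window_variance_for_frequency",
    "soft_lower_bound_frequency",
    "window_delay",
    "compute_spectrogram",
    "to_log_magnitude",
    "gammatone_parameters",
]

MIDI_REFERENCE_NOTE = 69.0
MIDI_REFERENCE_HZ = 440.0


def midi_from_frequency(f) -> np.ndarray | float:
    """Frequency in Hz -> logarithmic frequency in semitones (MIDI numbers)."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    nu = MIDI_REFERENCE_NOTE + 12.0 * np.log2(f / MIDI_REFERENCE_HZ)
    return float(nu) if nu.ndim == 0 else nu


def frequency_from_midi(nu) -> np.ndarray | float:
    """Logarithmic frequency in semitones -> frequency in Hz."""
    nu = np.asarray(nu, dtype=float)
    f = MIDI_REFERENCE_HZ * 2.0 ** ((nu - MIDI_REFERENCE_NOTE) / 12.0)
    return float(f) if f.ndim == 0 else f


@dataclass(frozen=True)
class LogFrequencyAxis:
    """Uniform semitone grid of channel center frequencies."""

    nu_values: np.ndarray
    channels_per_octave: int

    @property
    def delta_nu(self) -> float:
        return 12.0 / self.channels_per_octave

    @property
    def frequencies_hz(self) -> np.ndarray:
        return np.asarray(frequency_from_midi(self.nu_values))

    @property
    def omegas(self) -> np.ndarray:
        return 2.0 * math.pi * self.frequencies_hz

    def __len__(self) -> int:
        return len(self.nu_values)


def make_log_frequency_axis(
    f_min: float = 80.0, f_max: float = 16000.0, channels_per_octave: int = 48
) -> LogFrequencyAxis:
    """Channels from f_min to f_max at 12/channels_per_octave semitone spacing."""
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    nu_lo = midi_from_frequency(f_min)
    nu_hi = midi_from_frequency(f_max)
    step = 12.0 / channels_per_octave
    n = int(math.floor((nu_hi - nu_lo) / step + 1e-9)) + 1
    nu = nu_lo + step * np.arange(n)
    return LogFrequencyAxis(nu_values=nu, channels_per_octave=channels_per_octave)


@dataclass(frozen=True)
class WindowScalePolicy:
    """Frequency-dependent window scale: wavelength-proportional with soft bounds.

    ``n`` is the window-length-to-wavelength factor (sigma = n lambda when the
    bounds are inactive), ``tau0 = sigma0^2`` the soft lower variance bound in
    seconds^2, ``tau_inf`` the soft upper bound (np.inf disables it) with
    softness exponent ``p``.
    """

    n: float = 8.0
    tau0: float = 1e-6  # (1 ms)^2
    tau_inf: float = math.inf
    p: float = 1.0

    def __post_init__(self) -> None:
        if self.n <= 0 or self.tau0 < 0 or self.tau_inf <= 0 or self.p <= 0:
            raise ValueError("invalid window scale policy parameters")


def window_variance_for_frequency(omega, policy: WindowScalePolicy):
    """Temporal window variance tau(omega) in seconds^2."""
    w = np.asarray(omega, dtype=float)
    if np.any(w <= 0):
        raise ValueError("omega must be positive")
    tau = policy.tau0 + (2.0 * math.pi * policy.n / w) ** 2
    if math.isfinite(policy.tau_inf):
        tau = tau / (1.0 + (tau / policy.tau_inf) ** policy.p) ** (1.0 / policy.p)
    return float(tau) if tau.ndim == 0 else tau


def soft_lower_bound_frequency(sigma0: float, n: float, beta: float) -> float:
    """Frequency (Hz) where tau(omega) = beta^2 tau0, i.e. where the soft
    lower bound starts to dominate the wavelength-proportional scale."""
    if beta <= 1:
        raise ValueError("beta must exceed 1")
    return n / (math.sqrt(beta * beta - 1.0) * sigma0)


@dataclass(frozen=True)
class SpectrogramParams:
    """Full configuration of a multi-scale spectrogram computation."""

    sample_rate: float
    axis: LogFrequencyAxis
    policy: WindowScalePolicy = field(default_factory=WindowScalePolicy)
    family: str = "gaussian"  # gaussian | time_causal_uniform | time_causal_log
    K: int = 7
    c: float = math.sqrt(2.0)
    hop: int = 0  # output decimation in samples; 0 -> round(1 ms * sample_rate)
    delay_compensation: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "time_causal_uniform", "time_causal_log"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "time_causal_log" and self.c <= 1:
            raise ValueError("time_causal_log requires c > 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.hop == 0:
            object.__setattr__(self, "hop", max(1, round(self.sample_rate * 1e-3)))

    @property
    def is_causal(self) -> bool:
        return self.family != "gaussian"


@dataclass(frozen=True)
class ComplexSpectrogram:
    """Complex channel responses on a time x log-frequency grid."""

    times: np.ndarray
    axis: LogFrequencyAxis
    values: np.ndarray  # (n_times, n_channels) complex
    params: SpectrogramParams

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass(frozen=True)
class LogSpectrogram:
    """dB-magnitude spectrogram S_dB = 20 log10(|S| / S0), floored."""

    times: np.ndarray
    axis: LogFrequencyAxis
    values_dB: np.ndarray
    S0: float
    floor_dB: float

    @property
    def delta_nu(self) -> float:
        return self.axis.delta_nu

    @property
    def time_step(self) -> float:
        if len(self.times) < 2:
            return 0.0
        return float(self.times[1] - self.times[0])


# ---------------------------------------------------------------------------
# Delay of the causal window
# ---------------------------------------------------------------------------

def window_delay(params: SpectrogramParams, omega: float) -> float:
    """Delay (s) of a time-causal window: the time of its first inflection point.

    For the uniform family the closed form (K - 1 - sqrt(K - 1)) mu applies;
    the logarithmic family is handled numerically from the sampled cascade.
    K = 1 kernels (pure exponential) inflect at the origin.
    """
    if not params.is_causal:
        raise ValueError("delay compensation applies to time-causal families only; "
                         "the Gaussian family carries its own delay parameter")
    tau = float(window_variance_for_frequency(omega, params.policy))
    K = params.K
    if params.family == "time_causal_uniform":
        if K < 2:
            return 0.0
        mu = math.sqrt(tau / K)
        return (K - 1 - math.sqrt(K - 1)) * mu
    if K < 2:
        return 0.0
    from .temporal_kernels import sample_composed_log_kernel

    d = make_log_discretization(tau, K, params.c)
    ks = sample_composed_log_kernel(d, None, derivative_order=0)
    h2 = np.gradient(np.gradient(ks.values, ks.times), ks.times)
    peak = int(np.argmax(ks.values))
    sign = np.sign(h2[: peak + 1])
    flips = np.nonzero(np.diff(sign) != 0)[0]
    if flips.size == 0:
        return 0.0
    i = flips[0]
    # linear zero crossing between grid points
    t0, t1 = ks.times[i], ks.times[i + 1]
    y0, y1 = h2[i], h2[i + 1]
    return float(t0 - y0 * (t1 - t0) / (y1 - y0)) if y1 != y0 else float(t0)


# ---------------------------------------------------------------------------
# Spectrogram computation
# ---------------------------------------------------------------------------

def _gaussian_channel_smooth(x: np.ndarray, s_grid: float) -> np.ndarray:
    """Non-causal smoothing with the discrete Gaussian analogue, mirrored ends."""
    kern = dss.discrete_gaussian(s_grid)
    w = kern.values / kern.mass()
    N = kern.halfwidth
    if N == 0:
        return x
    xp = np.pad(x, (N, N), mode="symmetric")
    return fftconvolve(xp, w, mode="valid")


def _causal_channel_smooth(x: np.ndarray, tau_grid: float, family: str,
                           K: int, c: float) -> np.ndarray:
    if family == "time_causal_uniform":
        levels = [(k / K) * tau_grid for k in range(1, K + 1)]
    else:
        levels = [c ** (2 * (k - K)) * tau_grid for k in range(1, K + 1)]
    cascade = dss.make_recursive_cascade(levels)
    return dss.recursive_smooth(x, cascade)[-1]


def compute_spectrogram(signal, params: SpectrogramParams) -> ComplexSpectrogram:
    """Heterodyne + scale-space low-pass spectrogram of a mono signal.

    The carriers use absolute sample time, so the complex values carry the
    heterodyne phase convention; the magnitude (the supported downstream
    quantity) is unaffected.  A long steady tone of unit amplitude at a
    channel center yields channel magnitude ~0.5 (the second harmonic term at
    2 omega is suppressed by the low-pass window for n >= 8).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional (mono)")
    if x.size == 0:
        raise ValueError("signal must be non-empty")
    phi0 = params.sample_rate
    nyquist = math.pi * phi0
    omegas = params.axis.omegas
    if np.any(omegas >= nyquist):
        raise ValueError("channel frequencies must lie below the Nyquist frequency")
    t = np.arange(x.size) / phi0
    hop = params.hop
    out = np.empty((int(np.ceil(x.size / hop)), len(params.axis)), dtype=complex)
    for j, omega in enumerate(omegas):
        tau = float(window_variance_for_frequency(omega, params.policy))
        tau_grid = dss.temporal_scale_to_grid(tau, phi0)
        f_cos = x * np.cos(omega * t)
        f_sin = x * np.sin(omega * t)
        if params.family == "gaussian":
            lc = _gaussian_channel_smooth(f_cos, tau_grid)
            ls = _gaussian_channel_smooth(f_sin, tau_grid)
        else:
            lc = _causal_channel_smooth(f_cos, tau_grid, params.family, params.K, params.c)
            ls = _causal_channel_smooth(f_sin, tau_grid, params.family, params.K, params.c)
        ch = lc - 1j * ls
        if params.delay_compensation and params.is_causal:
            shift = int(round(window_delay(params, omega) * phi0))
            if shift > 0:
                ch = np.concatenate([ch[shift:], np.full(shift, ch[-1])])
        out[:, j] = ch[::hop]
    times = t[::hop]
    return ComplexSpectrogram(times=times, axis=params.axis, values=out, params=params)


def to_log_magnitude(
    S: ComplexSpectrogram, S0: float | str = "max", floor_dB: float = -120.0
) -> LogSpectrogram:
    """dB magnitude, referenced to S0 ('max' -> spectrogram peak) and floored."""
    mag = S.magnitude
    if S0 == "max":
        ref = float(mag.max())
        if ref == 0.0:
            ref = 1.0  # silent input: all values land on the floor
    else:
        ref = float(S0)
        if ref <= 0:
            raise ValueError("S0 must be positive")
    tiny = ref * 10.0 ** (floor_dB / 20.0)
    vals = 20.0 * np.log10(np.maximum(mag, tiny) / ref)
    return LogSpectrogram(times=S.times, axis=S.axis, values_dB=vals,
                          S0=ref, floor_dB=floor_dB)


def gammatone_parameters(mu: float, K: int) -> tuple[float, float]:
    """(a, b) of the classical Gammatone a t^{K-1} e^{-2 pi b t} cos(2 pi phi t)
    equivalent to the equal-time-constant causal window: a = 1/(mu^K Gamma(K)),
    b = 1/(2 pi mu)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if K < 1:
        raise ValueError("K must be >= 1")
    a = 1.0 / (mu**K * math.gamma(K))
    b = 1.0 / (2.0 * math.pi * mu)
    return a, b
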