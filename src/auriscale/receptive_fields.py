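"""Second-layer spectro-temporal receptive fields over the log spectrogram.

The idealized receptive-field family is

    A(t, nu; Sigma) = d_t^alpha d_nu^beta [ g(nu - v t; s) T(t; tau_a) ]

a separable product of a temporal smoothing kernel ``T`` (Gaussian or
time-causal cascade, temporal variance ``tau_a``) and a Gaussian over
log-frequency (variance ``s`` semitones^2), sheared by the glissando rate
``v`` (semitones/second) and differentiated ``alpha`` times in time and
``beta`` times in log-frequency.  Applied to the dB spectrogram these
operators are invariant to global sound-pressure changes (any additive
constant dies under the derivatives) and, with ``v`` matched to a frequency
drift, covariant under glissando transformations.

Filtering is implemented separably on the spectrogram grid: shear-warp by
``-v`` (cubic spline interpolation along the frequency axis), causal
recursive / discrete-Gaussian smoothing in time, discrete-Gaussian smoothing
in log-frequency, small-support difference operators, unwarp.  Derivatives
are converted to physical units (per second, per semitone) and multiplied by
the variance-power scale-normalization factor ``tau_a^{alpha/2} s^{beta/2}``
so that response magnitudes are comparable across scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from . import discrete_scalespace as dss
from .spectrogram import LogSpectrogram
from .temporal_kernels import (
    GaussianWindow,
    make_log_discretization,
    make_uniform_discretization,
    sample_composed_log_kernel,
    sample_composed_uniform_kernel,
    sample_gaussian_kernel,
)

__all__ = [
    "ReceptiveFieldSpec",
    "FeatureMap",
    "render_rf_kernel",
    "apply_rf",
    "shear_warp",
]


@dataclass(frozen=True)
class ReceptiveFieldSpec:
    """Parameters of one second-layer spectro-temporal receptive field.

    tau_a   second-layer temporal variance, seconds^2
    s       logspectral variance, semitones^2
    v       glissando rate, semitones/second (0 -> separable kernel)
    alpha   temporal derivative order
    beta    logspectral derivative order
    temporal_family  gaussian | time_causal_uniform | time_causal_log
    K, c    cascade shape for the time-causal families
    delta   temporal delay of the Gaussian family (seconds)
    """

    tau_a: float
    s: float
    v: float = 0.0
    alpha: int = 0
    beta: int = 0
    temporal_family: str = "time_causal_uniform"
    K: int = 4
    c: float = math.sqrt(2.0)
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_a < 0 or self.s < 0:
            raise ValueError("scales must be non-negative")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("derivative orders must be non-negative")
        if self.temporal_family not in (
            "gaussian", "time_causal_uniform", "time_causal_log"
        ):
            raise ValueError(f"unknown temporal family {self.temporal_family!r}")
        if self.temporal_family != "gaussian" and self.alpha >= self.K:
            raise ValueError(
                f"time-causal cascade of K={self.K} stages supports temporal "
                f"derivatives up to order {self.K - 1}, got alpha={self.alpha}"
            )
        if self.temporal_family == "time_causal_log" and self.c <= 1:
            raise ValueError("time_causal_log requires c > 1")

    @property
    def is_separable(self) -> bool:
        return self.v == 0.0


@dataclass(frozen=True)
class FeatureMap:
    """A receptive-field response on the spectrogram grid."""

    times: np.ndarray
    axis: object  # LogFrequencyAxis
    values: np.ndarray
    spec: ReceptiveFieldSpec
    normalization: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Kernel rendering (visualization / direct-convolution tests)
# ---------------------------------------------------------------------------

def _gaussian_1d(x: np.ndarray, var: float, order: int) -> np.ndarray:
    g = np.exp(-x * x / (2.0 * var)) / math.sqrt(2.0 * math.pi * var)
    if order == 0:
        return g
    if order == 1:
        return -x / var * g
    if order == 2:
        return (x * x / (var * var) - 1.0 / var) * g
    raise ValueError("logspectral derivative orders above 2 are not supported")


def _temporal_window_samples(spec: ReceptiveFieldSpec, t: np.ndarray) -> np.ndarray:
    if spec.temporal_family == "gaussian":
        return sample_gaussian_kernel(GaussianWindow(spec.tau_a, spec.delta), t).values
    if spec.temporal_family == "time_causal_uniform":
        mu = math.sqrt(spec.tau_a / spec.K)
        return sample_composed_uniform_kernel(mu, spec.K, t).values
    d = make_log_discretization(spec.tau_a, spec.K, spec.c)
    return sample_composed_log_kernel(d, t).values


def render_rf_kernel(spec: ReceptiveFieldSpec, t_grid, nu_grid) -> np.ndarray:
    """Sample A(t, nu; Sigma) on an explicit (time x log-frequency) grid.

    The logspectral Gaussian and its derivatives are analytic in the sheared
    coordinate nu - v t; temporal derivatives are applied numerically along
    the time axis, which also captures the shear coupling for v != 0.
    Returned without scale normalization (raw kernel values).
    """
    t = np.asarray(t_grid, dtype=float)
    nu = np.asarray(nu_grid, dtype=float)
    temporal = _temporal_window_samples(spec, t)
    sheared = nu[None, :] - spec.v * t[:, None]
    kern = temporal[:, None] * _gaussian_1d(sheared, spec.s, spec.beta)
    for _ in range(spec.alpha):
        kern = np.gradient(kern, t, axis=0)
    return kern


# ---------------------------------------------------------------------------
# Shear warp
# ---------------------------------------------------------------------------

def shear_warp(matrix: np.ndarray, times, nu_values, v: float,
               direction: str = "forward") -> np.ndarray:
    """Shift each time column along nu by -+ v t (cubic spline interpolation).

    ``forward`` maps into the glissando-rectified frame nu' = nu - v t;
    ``inverse`` undoes it.  Out-of-range samples are filled by edge
    replication; forward followed by inverse restores the interior up to
    interpolation error.
    """
    if direction not in ("forward", "inverse"):
        raise ValueError("direction must be 'forward' or 'inverse'")
    x = np.asarray(matrix, dtype=float)
    t = np.asarray(times, dtype=float)
    nu = np.asarray(nu_values, dtype=float)
    if v == 0.0:
        return x.copy()
    dnu = nu[1] - nu[0]
    sign = 1.0 if direction == "forward" else -1.0
    # value at output (t_i, nu_j) comes from input at nu_j + sign * v * t_i
    shift_channels = sign * v * t / dnu
    rows = np.arange(x.shape[0])[:, None] * np.ones((1, x.shape[1]))
    cols = np.arange(x.shape[1])[None, :] + shift_channels[:, None]
    return map_coordinates(x, [rows, cols], order=3, mode="nearest")


# ---------------------------------------------------------------------------
# Applying a receptive field to a log spectrogram
# ---------------------------------------------------------------------------

def _temporal_smooth_grid(values: np.ndarray, spec: ReceptiveFieldSpec,
                          sample_rate: float) -> np.ndarray:
    """Smooth along axis 0 at tau_a, per the spec's temporal family."""
    tau_grid = dss.temporal_scale_to_grid(spec.tau_a, sample_rate)
    if tau_grid == 0.0:
        return values
    if spec.temporal_family == "gaussian":
        return dss.smooth_1d(values, tau_grid, axis=0)
    if spec.temporal_family == "time_causal_uniform":
        levels = [(k / spec.K) * tau_grid for k in range(1, spec.K + 1)]
    else:
        levels = [spec.c ** (2 * (k - spec.K)) * tau_grid for k in range(1, spec.K + 1)]
    cascade = dss.make_recursive_cascade(levels)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[:, j] = dss.recursive_smooth(values[:, j], cascade)[-1]
    return out


def apply_rf(SdB: LogSpectrogram, spec: ReceptiveFieldSpec,
             scale_normalize: bool = True) -> FeatureMap:
    """Apply a second-layer receptive field to a dB spectrogram.

    Pipeline: optional shear-warp into the glissando frame, temporal
    smoothing at tau_a, logspectral discrete-Gaussian smoothing at s,
    difference-operator derivatives (converted to per-second / per-semitone
    units), scale normalization by tau_a^{alpha/2} s^{beta/2}, unwarp.
    """
    vals = np.asarray(SdB.values_dB, dtype=float)
    dt = SdB.time_step
    if dt <= 0:
        raise ValueError("spectrogram must have at least two time samples")
    dnu = SdB.delta_nu
    rate = 1.0 / dt

    warped = spec.v != 0.0
    if warped:
        vals = shear_warp(vals, SdB.times, SdB.axis.nu_values, spec.v, "forward")

    vals = _temporal_smooth_grid(vals, spec, rate)
    s_grid = dss.spectral_scale_to_grid(spec.s, dnu)
    if s_grid > 0:
        vals = dss.smooth_1d(vals, s_grid, axis=1)

    # derivatives: use the dedicated 2nd-order stencils, compose for higher orders
    a = spec.alpha
    while a >= 2:
        vals = dss.difference_operator(vals, "dtt")
        a -= 2
    if a == 1:
        vals = dss.difference_operator(vals, "dt")
    b = spec.beta
    while b >= 2:
        vals = dss.difference_operator(vals, "dnunu")
        b -= 2
    if b == 1:
        vals = dss.difference_operator(vals, "dnu")

    unit_factor = rate**spec.alpha / dnu**spec.beta
    vals = vals * unit_factor
    norm: dict = {"unit_factor": unit_factor}
    if scale_normalize:
        sn = spec.tau_a ** (spec.alpha / 2.0) * (
            spec.s ** (spec.beta / 2.0) if spec.beta else 1.0
        )
        vals = vals * sn
        norm["scale_factor"] = sn

    if warped:
        vals = shear_warp(vals, SdB.times, SdB.axis.nu_values, spec.v, "inverse")

    return FeatureMap(times=SdB.times, axis=SdB.axis, values=vals,
                      spec=spec, normalization=norm)
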