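"""Continuous-domain temporal scale-space kernels.

Two kernel families generate all temporal smoothing used in this package:

* the (possibly time-shifted) Gaussian ``g(t - delta; tau)`` for non-causal
  off-line analysis, and
* cascades of truncated exponential kernels ``h_exp(t; mu) = exp(-t/mu)/mu``
  (``t >= 0``), the unique primitive *time-causal* smoothers that never
  create new local extrema with increasing scale.

A cascade is described by a :class:`TemporalScaleDiscretization`: the composed
variance ``tau_max``, the number of first-order integrators ``K``, and how the
intermediate scale levels ``tau_k`` are distributed between 0 and ``tau_max``
(uniformly, ``tau_k = k tau_max / K``, or logarithmically / self-similarly,
``tau_k = c^{2(k-K)} tau_max`` with ratio ``c > 1``).  The per-stage time
constants satisfy ``sum_k mu_k^2 = tau_max`` (variance additivity under
convolution), so both distributions realize the same composed scale but trade
frequency selectivity against temporal delay differently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "GaussianWindow",
    "TemporalScaleDiscretization",
    "KernelSamples",
    "make_uniform_discretization",
    "make_log_discretization",
    "c_from_tau_bounds",
    "sample_gaussian_kernel",
    "sample_composed_uniform_kernel",
    "sample_composed_log_kernel",
    "default_time_grid",
    "numeric_mean",
    "numeric_variance",
    "count_local_extrema",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianWindow:
    """Time-shifted temporal Gaussian window.

    Parameters
    ----------
    tau : float
        Temporal variance in seconds^2 (sigma = sqrt(tau)).
    delta : float
        Temporal delay in seconds (0 for off-line, symmetric use).
    """

    tau: float
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.delta < 0:
            raise ValueError(f"delta must be non-negative, got {self.delta}")

    @property
    def sigma(self) -> float:
        return math.sqrt(self.tau)


@dataclass(frozen=True)
class TemporalScaleDiscretization:
    """Cascade structure of a time-causal kernel.

    ``tau_levels[k-1]`` is the composed variance after stage ``k`` and
    ``mu[k-1]`` the time constant of stage ``k``; ``sum(mu**2) == tau_max``.
    """

    tau_max: float
    K: int
    distribution: str  # "uniform" | "logarithmic"
    c: float | None
    tau_levels: tuple[float, ...]
    mu: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.tau_max <= 0:
            raise ValueError(f"tau_max must be positive, got {self.tau_max}")
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if len(self.tau_levels) != self.K or len(self.mu) != self.K:
            raise ValueError("tau_levels and mu must have length K")
        if self.distribution not in ("uniform", "logarithmic"):
            raise ValueError(f"unknown distribution {self.distribution!r}")

    @property
    def temporal_mean(self) -> float:
        """Mean (first moment) of the composed kernel, sum of time constants."""
        return float(np.sum(self.mu))

    @property
    def variance(self) -> float:
        """Variance of the composed kernel, additive over the cascade."""
        return float(np.sum(np.square(self.mu)))


@dataclass(frozen=True)
class KernelSamples:
    """A kernel (or kernel derivative) sampled on an explicit time grid."""

    times: np.ndarray
    values: np.ndarray
    derivative_order: int = 0

    def __post_init__(self) -> None:
        if self.derivative_order < 0:
            raise ValueError("derivative_order must be >= 0")
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")

    def integral(self) -> float:
        """Trapezoid integral: 1 for smoothing kernels, 0 for derivatives."""
        return float(np.trapezoid(self.values, self.times))


# ---------------------------------------------------------------------------
# Scale discretizations
# ---------------------------------------------------------------------------

def make_uniform_discretization(tau_max: float, K: int) -> TemporalScaleDiscretization:
    """Uniformly distributed scale levels: tau_k = k tau_max / K.

    All stages share the same time constant mu = sqrt(tau_max / K); the
    composed kernel has the closed gamma-density form sampled by
    :func:`sample_composed_uniform_kernel`.
    """
    if tau_max <= 0:
        raise ValueError(f"tau_max must be positive, got {tau_max}")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    mu = math.sqrt(tau_max / K)
    tau_levels = tuple((k / K) * tau_max for k in range(1, K + 1))
    return TemporalScaleDiscretization(
        tau_max=float(tau_max), K=int(K), distribution="uniform", c=None,
        tau_levels=tau_levels, mu=(mu,) * K,
    )


def make_log_discretization(tau_max: float, K: int, c: float) -> TemporalScaleDiscretization:
    """Logarithmic (self-similar, geometric) scale levels tau_k = c^{2(k-K)} tau_max.

    The geometric series corresponds to a uniform spacing in effective scale
    log(tau); mu_1 = c^{1-K} sqrt(tau_max) and
    mu_k = c^{k-K-1} sqrt(c^2 - 1) sqrt(tau_max) for k >= 2.
    """
    if tau_max <= 0:
        raise ValueError(f"tau_max must be positive, got {tau_max}")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if c <= 1:
        raise ValueError(f"distribution ratio c must exceed 1, got {c}")
    sigma = math.sqrt(tau_max)
    tau_levels = tuple(c ** (2 * (k - K)) * tau_max for k in range(1, K + 1))
    mu = [c ** (1 - K) * sigma]
    for k in range(2, K + 1):
        mu.append(c ** (k - K - 1) * math.sqrt(c * c - 1) * sigma)
    return TemporalScaleDiscretization(
        tau_max=float(tau_max), K=int(K), distribution="logarithmic", c=float(c),
        tau_levels=tau_levels, mu=tuple(mu),
    )


def c_from_tau_bounds(tau_min: float, tau_max: float, K: int) -> float:
    """Distribution ratio placing tau_1 = tau_min in a K-level geometric ladder."""
    if K < 2:
        raise ValueError(f"K must be >= 2 to fit a ratio, got {K}")
    if not (0 < tau_min < tau_max):
        raise ValueError("need 0 < tau_min < tau_max")
    return (tau_max / tau_min) ** (1.0 / (2 * (K - 1)))


# ---------------------------------------------------------------------------
# Kernel sampling
# ---------------------------------------------------------------------------

def sample_gaussian_kernel(
    w: GaussianWindow, times: Sequence[float] | np.ndarray, derivative_order: int = 0
) -> KernelSamples:
    """Sample the time-shifted Gaussian or its first/second time derivative."""
    if derivative_order not in (0, 1, 2):
        raise ValueError("derivative_order must be 0, 1 or 2 for the Gaussian family")
    t = np.asarray(times, dtype=float)
    x = t - w.delta
    g = np.exp(-x * x / (2.0 * w.tau)) / math.sqrt(2.0 * math.pi * w.tau)
    if derivative_order == 0:
        v = g
    elif derivative_order == 1:
        v = -x / w.tau * g
    else:
        v = (x * x / (w.tau * w.tau) - 1.0 / w.tau) * g
    return KernelSamples(times=t, values=v, derivative_order=derivative_order)


def sample_composed_uniform_kernel(
    mu: float, K: int, times: Sequence[float] | np.ndarray, derivative_order: int = 0
) -> KernelSamples:
    """Sample the equal-time-constant cascade kernel t^{K-1} e^{-t/mu} / (mu^K Gamma(K)).

    The cascade of K equal first-order integrators is continuous of order
    K - 1 at the origin, so derivatives are only defined up to order K - 1.
    """
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if derivative_order >= K:
        raise ValueError(
            f"cascade of K={K} integrators is continuous of order {K - 1}; "
            f"derivative order {derivative_order} is not defined"
        )
    if derivative_order > 2:
        raise ValueError("derivative orders above 2 are not supported")
    t = np.asarray(times, dtype=float)
    v = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    lg = gammaln(K)
    expf = np.exp(-tp / mu - lg)
    if derivative_order == 0:
        # t^{K-1} e^{-t/mu} / (mu^K Gamma(K))
        v[pos] = tp ** (K - 1) * expf / mu**K
        if K == 1:
            v[t == 0] = 1.0 / mu  # right limit of the truncated exponential
    elif derivative_order == 1:
        # mu^{-K-1} t^{K-2} ((K-1) mu - t) e^{-t/mu} / Gamma(K)
        v[pos] = tp ** (K - 2) * ((K - 1) * mu - tp) * expf / mu ** (K + 1)
        if K == 2:
            v[t == 0] = 1.0 / mu**2
    else:
        # mu^{-K-2} t^{K-3} ((K^2-3K+2) mu^2 - 2(K-1) t mu + t^2) e^{-t/mu} / Gamma(K)
        poly = (K * K - 3 * K + 2) * mu * mu - 2 * (K - 1) * tp * mu + tp * tp
        v[pos] = tp ** (K - 3) * poly * expf / mu ** (K + 2)
        if K == 3:
            v[t == 0] = 1.0 / mu**3
    return KernelSamples(times=t, values=v, derivative_order=derivative_order)


def default_time_grid(d: TemporalScaleDiscretization) -> np.ndarray:
    """Fine sampling grid for a time-causal kernel.

    Step sqrt(tau_max)/1000 over [0, m + 10 sqrt(tau_max)] captures all but
    a negligible fraction (< 1e-8) of the kernel mass.
    """
    sigma = math.sqrt(d.tau_max)
    step = sigma / 1000.0
    t_end = d.temporal_mean + 10.0 * sigma
    n = int(round(t_end / step)) + 1
    return np.arange(n) * step


def _cascade_impulse_response(d: TemporalScaleDiscretization, t: np.ndarray) -> np.ndarray:
    """Impulse response of the cascade on a uniform grid.

    The widest-time-constant primitive is sampled analytically; every further
    stage is applied by integrating the first-order ODE
    dL/dt = (L_in - L)/mu exactly under piecewise-linear interpolation of its
    input (an exponential integrator).  Each stage therefore has exactly unit
    DC gain, and stages with mu comparable to the grid step remain accurate.
    """
    dt = t[1] - t[0]
    # unit-area hat impulse: adds only dt^2/6 of spurious variance, and keeps
    # the discrete mass of the composed response exactly 1
    out = np.zeros_like(t)
    out[0] = 1.0 / dt
    for mu in sorted(d.mu, reverse=True):  # widest stage first
        out = _exp_integrator_stage(out, mu, dt)
    return out


def _exp_integrator_stage(x: np.ndarray, mu: float, dt: float) -> np.ndarray:
    """One first-order integrator stage, exact for piecewise-linear input."""
    from scipy.signal import lfilter

    a = dt / mu
    e = math.exp(-a)
    w1 = 1.0 - e                 # weight of left sample (zero-order part)
    w2 = 1.0 - w1 / a            # extra weight of the linear ramp part
    # y[n] = e y[n-1] + (w1 - w2) x[n-1] + w2 x[n]: an order-(1,1) LTI filter
    return lfilter([w2, w1 - w2], [1.0, -e], x)


def sample_composed_log_kernel(
    d: TemporalScaleDiscretization,
    times: Sequence[float] | np.ndarray | None = None,
    derivative_order: int = 0,
) -> KernelSamples:
    """Sample the cascade kernel for arbitrary (e.g. logarithmic) time constants.

    No compact closed form exists for distinct time constants, so the impulse
    response is computed numerically by running the stages in sequence on a
    fine grid; derivatives are taken by central differences on that grid.
    When ``times`` is omitted the default fine grid is used.
    """
    if derivative_order >= d.K:
        raise ValueError(
            f"cascade of K={d.K} integrators supports derivatives up to order {d.K - 1}"
        )
    grid = default_time_grid(d)
    h = _cascade_impulse_response(d, grid)
    for _ in range(derivative_order):
        h = np.gradient(h, grid)
    if times is None:
        t_out, v = grid, h
    else:
        t_out = np.asarray(times, dtype=float)
        v = np.interp(t_out, grid, h, left=0.0, right=0.0)
    return KernelSamples(times=t_out, values=v, derivative_order=derivative_order)


# ---------------------------------------------------------------------------
# Moment and structure helpers
# ---------------------------------------------------------------------------

def numeric_mean(samples: KernelSamples) -> float:
    """First moment of a sampled non-negative kernel (trapezoid rule)."""
    m0 = samples.integral()
    m1 = float(np.trapezoid(samples.times * samples.values, samples.times))
    return m1 / m0


def numeric_variance(samples: KernelSamples) -> float:
    """Central second moment of a sampled non-negative kernel."""
    m = numeric_mean(samples)
    m0 = samples.integral()
    m2 = float(np.trapezoid((samples.times - m) ** 2 * samples.values, samples.times))
    return m2 / m0


def count_local_extrema(x: np.ndarray, atol: float = 0.0) -> int:
    """Number of strict local extrema of a 1-D sequence.

    Flat runs are collapsed before counting so that plateaus introduced by
    smoothing do not register as multiple extrema.
    """
    x = np.asarray(x, dtype=float)
    d = np.diff(x)
    s = np.sign(np.where(np.abs(d) <= atol, 0.0, d))
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[1:] != s[:-1]))
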