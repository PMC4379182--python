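"""Analytical characterization of the temporal window families.

Frequency selectivity
---------------------
With the window scale proportional to the wavelength,
``tau(omega) = (2 pi n / omega)^2``, the normalized magnitude response of a
spectrogram channel centred at ``omega_0`` to a pure tone is a function of the
single dimensionless quantity ``theta = n (omega - omega_0) / omega``:

* Gaussian window:        ``R = exp(-2 pi^2 theta^2)``
* uniform cascade (K):    ``R = (1 + 4 pi^2 theta^2 / K)^(-K/2)``
* logarithmic cascade:    product of the K per-stage first-order responses
  with geometrically distributed time constants.

Solving ``R_dB(theta) = R`` for a given attenuation level gives the
bandwidth parameter ``theta``; the two-sided relative bandwidth of a channel
follows as ``(1/(1 - theta/n)) - (1/(1 + theta/n))`` (or its equivalent in
semitones).  The Gaussian and uniform families admit closed forms; the
logarithmic family is root-found by bisection.

Temporal dynamics
-----------------
For time-causal cascades the delay is characterized by the temporal mean
``m = sum_k mu_k`` and, more sharply, by the position of the kernel maximum:
``t_max = (K - 1) mu`` in closed form for the uniform family, numeric (with
parabolic peak refinement) for the logarithmic family.  All delay metrics are
reported in units of ``sqrt(tau)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .temporal_kernels import (
    TemporalScaleDiscretization,
    _cascade_impulse_response,
    make_log_discretization,
    make_uniform_discretization,
)

__all__ = [
    "SelectivitySpec",
    "DelayMetrics",
    "selectivity_db",
    "selectivity_curve",
    "theta_gaussian",
    "theta_rec_uniform",
    "theta_rec_log",
    "relative_bandwidth",
    "temporal_mean",
    "temporal_mean_log_limit",
    "delay_metrics",
    "bandwidth_table",
    "temporal_mean_table",
    "kernel_peak_table",
]

_FOURPI2 = 4.0 * math.pi * math.pi


@dataclass(frozen=True)
class SelectivitySpec:
    """Window family plus the parameters entering its selectivity formula."""

    family: str  # "gaussian" | "rec_uniform" | "rec_log"
    K: int = 1
    c: float | None = None
    n: float = 8.0

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "rec_uniform", "rec_log"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "rec_log" and (self.c is None or self.c <= 1):
            raise ValueError("rec_log requires a distribution ratio c > 1")


@dataclass(frozen=True)
class DelayMetrics:
    """Delay characteristics of a time-causal kernel, in units of sqrt(tau)."""

    m: float
    t_max: float
    t_infl1: float | None = None
    t_infl2: float | None = None


# ---------------------------------------------------------------------------
# Selectivity in dB as a function of theta
# ---------------------------------------------------------------------------

def _db_gaussian(theta: float) -> float:
    return -40.0 * math.pi**2 * theta * theta * math.log10(math.e)


def _db_rec_uniform(theta: float, K: int) -> float:
    return -10.0 * K * math.log10(1.0 + _FOURPI2 * theta * theta / K)


def _db_rec_log(theta: float, K: int, c: float) -> float:
    t2 = theta * theta
    out = -10.0 * math.log10(1.0 + _FOURPI2 * t2 * c ** (2.0 * (1 - K)))
    for k in range(2, K + 1):
        out -= 10.0 * math.log10(
            1.0 + _FOURPI2 * (c * c - 1.0) * t2 * c ** (2.0 * (k - K - 1))
        )
    return out


def selectivity_db(spec: SelectivitySpec, theta) -> np.ndarray | float:
    """Attenuation R_dB at bandwidth parameter theta (0 dB at theta = 0)."""
    th = np.asarray(theta, dtype=float)
    if spec.family == "gaussian":
        vals = np.vectorize(_db_gaussian)(th)
    elif spec.family == "rec_uniform":
        vals = np.vectorize(lambda t: _db_rec_uniform(t, spec.K))(th)
    else:
        vals = np.vectorize(lambda t: _db_rec_log(t, spec.K, spec.c))(th)
    return float(vals) if np.isscalar(theta) else vals


def selectivity_curve(spec: SelectivitySpec, omega_over_omega0) -> np.ndarray:
    """R_dB over a grid of omega / omega_0 with wavelength-proportional tau(omega)."""
    w = np.asarray(omega_over_omega0, dtype=float)
    if np.any(w <= 0):
        raise ValueError("omega must be positive")
    theta = spec.n * (w - 1.0) / w
    return np.asarray(selectivity_db(spec, np.abs(theta)), dtype=float)


# ---------------------------------------------------------------------------
# theta at a given dB level
# ---------------------------------------------------------------------------

def theta_gaussian(R_dB: float) -> float:
    """Bandwidth parameter of the Gaussian window at attenuation R_dB < 0."""
    if R_dB >= 0:
        raise ValueError("R_dB must be negative")
    return math.sqrt(-R_dB * math.log(10.0) / 10.0) / (2.0 * math.pi)


def theta_rec_uniform(R_dB: float, K: int) -> float:
    """Bandwidth parameter of the uniform K-stage cascade at attenuation R_dB < 0."""
    if R_dB >= 0:
        raise ValueError("R_dB must be negative")
    if K < 1:
        raise ValueError("K must be >= 1")
    return math.sqrt(K) / (2.0 * math.pi) * math.sqrt(10.0 ** (-R_dB / (10.0 * K)) - 1.0)


def theta_rec_log(R_dB: float, K: int, c: float, tol: float = 1e-9) -> float:
    """Bandwidth parameter of the logarithmic cascade, by bisection.

    The dB response is strictly decreasing in theta, so the root of
    ``selectivity_db(theta) = R_dB`` on (0, 4] is bracketed and bisected to
    ``tol``.
    """
    if R_dB >= 0:
        raise ValueError("R_dB must be negative")
    if K < 1:
        raise ValueError("K must be >= 1")
    if c <= 1:
        raise ValueError("c must exceed 1")
    lo, hi = 0.0, 4.0
    while _db_rec_log(hi, K, c) > R_dB:
        hi *= 2.0  # low-K kernels have heavy spectral skirts; widen as needed
        if hi > 1e6:
            raise ValueError(f"no root found for R_dB={R_dB}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _db_rec_log(mid, K, c) > R_dB:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def relative_bandwidth(theta: float, n: float, units: str = "fraction") -> float:
    """Two-sided relative bandwidth of a channel at bandwidth parameter theta.

    ``fraction`` gives (omega_2 - omega_1)/omega_0; ``semitones`` gives the
    corresponding width 12 log2(omega_2/omega_1) on the MIDI axis.
    """
    r = theta / n
    if r >= 1:
        raise ValueError("theta/n must be below 1")
    if units == "fraction":
        return 1.0 / (1.0 - r) - 1.0 / (1.0 + r)
    if units == "semitones":
        return 12.0 * math.log2((1.0 + r) / (1.0 - r))
    raise ValueError(f"unknown units {units!r}")


# ---------------------------------------------------------------------------
# Temporal dynamics
# ---------------------------------------------------------------------------

def temporal_mean(d: TemporalScaleDiscretization) -> float:
    """Temporal mean sum_k mu_k in units of sqrt(tau_max)."""
    return d.temporal_mean / math.sqrt(d.tau_max)


def temporal_mean_log_limit(c: float) -> float:
    """K -> infinity limit of the logarithmic-family mean, sqrt(c^2-1)/(c-1)."""
    return math.sqrt(c * c - 1.0) / (c - 1.0)


def delay_metrics(d: TemporalScaleDiscretization) -> DelayMetrics:
    """Delay metrics of a time-causal cascade, in units of sqrt(tau_max).

    Uniform family: closed forms t_max = (K-1) mu and inflection points
    (K - 1 -+ sqrt(K-1)) mu.  Logarithmic family: numeric peak of the sampled
    impulse response on a fine grid (1e5 points over [0, m + 6 sqrt(tau)])
    refined by parabolic interpolation; no closed-form inflection points.
    K = 1 kernels are monotone with their maximum at the origin.
    """
    sigma = math.sqrt(d.tau_max)
    m = temporal_mean(d)
    if d.distribution == "uniform":
        mu = d.mu[0] / sigma
        K = d.K
        t_max = (K - 1) * mu
        if K >= 2:
            root = math.sqrt(K - 1)
            return DelayMetrics(m=m, t_max=t_max,
                                t_infl1=(K - 1 - root) * mu,
                                t_infl2=(K - 1 + root) * mu)
        return DelayMetrics(m=m, t_max=0.0)
    if d.K == 1:
        return DelayMetrics(m=m, t_max=0.0)
    t = np.linspace(0.0, (m + 6.0) * sigma, 100_000)
    h = _cascade_impulse_response(d, t)  # directly on the fine grid
    i = int(np.argmax(h))
    t_max = t[i]
    if 0 < i < len(t) - 1:
        y0, y1, y2 = h[i - 1], h[i], h[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0:
            t_max = t[i] + 0.5 * (y0 - y2) / denom * (t[1] - t[0])
    return DelayMetrics(m=m, t_max=float(t_max) / sigma)


# ---------------------------------------------------------------------------
# Table reproduction
# ---------------------------------------------------------------------------

_DB_LEVELS = (-3.0, -10.0, -20.0, -30.0)
_LOG_RATIOS = (math.sqrt(2.0), 2.0 ** 0.75, 2.0)
_RATIO_LABELS = ("c=sqrt(2)", "c=2^(3/4)", "c=2")


def bandwidth_table() -> pd.DataFrame:
    """theta per window family and attenuation level (3-decimal rounding).

    Rows: Gaussian, uniform cascades (K = 4, 7), logarithmic cascades
    (K = 4, 7 crossed with c = sqrt(2), 2^(3/4), 2).  Columns: -3, -10, -20,
    -30 dB.
    """
    rows: dict[str, list[float]] = {}
    rows["theta_gauss"] = [theta_gaussian(db) for db in _DB_LEVELS]
    for K in (4, 7):
        rows[f"theta_rec_uni (K={K})"] = [theta_rec_uniform(db, K) for db in _DB_LEVELS]
        for c, lab in zip(_LOG_RATIOS, _RATIO_LABELS):
            rows[f"theta_rec_log (K={K}, {lab})"] = [
                theta_rec_log(db, K, c) for db in _DB_LEVELS
            ]
    order = ["theta_gauss"]
    for K in (4, 7):
        order.append(f"theta_rec_uni (K={K})")
        order += [f"theta_rec_log (K={K}, {lab})" for lab in _RATIO_LABELS]
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"{int(db)} dB" for db in _DB_LEVELS])
    return df.loc[order].round(3)


def temporal_mean_table(K_range=range(2, 9)) -> pd.DataFrame:
    """Temporal mean m = sum mu_k in units of sqrt(tau), per K and family."""
    recs = []
    for K in K_range:
        row = {"K": K, "m_uni": temporal_mean(make_uniform_discretization(1.0, K))}
        for c, lab in zip(_LOG_RATIOS, _RATIO_LABELS):
            row[f"m_log ({lab})"] = temporal_mean(make_log_discretization(1.0, K, c))
        recs.append(row)
    return pd.DataFrame(recs).set_index("K").round(3)


def kernel_peak_table(K_range=range(2, 9)) -> pd.DataFrame:
    """Kernel-maximum delay t_max in units of sqrt(tau), per K and family."""
    recs = []
    for K in K_range:
        row = {"K": K,
               "t_max_uni": delay_metrics(make_uniform_discretization(1.0, K)).t_max}
        for c, lab in zip(_LOG_RATIOS, _RATIO_LABELS):
            row[f"t_max_log ({lab})"] = delay_metrics(
                make_log_discretization(1.0, K, c)).t_max
        recs.append(row)
    return pd.DataFrame(recs).set_index("K").round(3)
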