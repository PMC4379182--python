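"""Auditory feature operators built on second-layer receptive-field responses.

All features operate on the dB spectrogram, so they inherit invariance to
global sound-pressure changes:

* **onset / offset maps** — positive / negative parts of the scale-normalized
  first temporal derivative of the smoothed spectrogram;
* **band map** — positive part of the negated scale-normalized second
  logspectral derivative; at fine logspectral scale (~0.5 semitone) it
  enhances partial tones, at coarse scale (~4 semitones) formants;
* **ridge curves** — sub-grid frequency trajectories of partials, the
  zero crossings of the first logspectral derivative of the band response
  where its second derivative is negative, thresholded and linked over time;
* **glissando estimation** — either by the argmax over a filter bank of
  glissando-adapted receptive fields (with parabolic refinement in v), or
  directly from the spectro-temporal second-moment matrix: the shear
  ``v = -Y_tn / Y_nn`` that diagonalizes the smoothed outer products of the
  first derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from . import discrete_scalespace as dss
from .receptive_fields import FeatureMap, ReceptiveFieldSpec, apply_rf
from .spectrogram import LogSpectrogram

__all__ = [
    "RidgeCurveSet",
    "SecondMomentMatrix",
    "temporal_derivative_map",
    "onset_map",
    "offset_map",
    "band_map",
    "ridge_curves",
    "glissando_filterbank",
    "second_moment_glissando",
]

DEFAULT_RIDGE_THRESHOLD = 3.0
RIDGE_LINK_GATE_SEMITONES = 1.0


@dataclass(frozen=True)
class RidgeCurveSet:
    """Partial-tone trajectories: polylines of (t, nu, strength) vertices."""

    curves: list  # list of (n, 3) arrays with columns (t, nu, strength)
    threshold: float


@dataclass(frozen=True)
class SecondMomentMatrix:
    """Smoothed outer products of the spectro-temporal first derivatives."""

    Ytt: np.ndarray
    Ytn: np.ndarray
    Ynn: np.ndarray
    tau_int: float
    s_int: float


# ---------------------------------------------------------------------------
# Onset / offset and band enhancement
# ---------------------------------------------------------------------------

def temporal_derivative_map(SdB: LogSpectrogram, spec: ReceptiveFieldSpec) -> FeatureMap:
    """Raw signed scale-normalized first temporal derivative response."""
    if spec.alpha != 1:
        raise ValueError("temporal derivative map requires alpha = 1")
    return apply_rf(SdB, spec)


def onset_map(SdB: LogSpectrogram, spec: ReceptiveFieldSpec) -> FeatureMap:
    """Positive part of the D_t response: energy arriving in a channel."""
    raw = temporal_derivative_map(SdB, spec)
    return FeatureMap(times=raw.times, axis=raw.axis,
                      values=np.maximum(raw.values, 0.0),
                      spec=spec, normalization=raw.normalization)


def offset_map(SdB: LogSpectrogram, spec: ReceptiveFieldSpec) -> FeatureMap:
    """Positive part of the negated D_t response: energy leaving a channel."""
    raw = temporal_derivative_map(SdB, spec)
    return FeatureMap(times=raw.times, axis=raw.axis,
                      values=np.maximum(-raw.values, 0.0),
                      spec=spec, normalization=raw.normalization)


def band_map(SdB: LogSpectrogram, spec: ReceptiveFieldSpec) -> FeatureMap:
    """Spectral-band enhancement: positive part of -D_nunu.

    A local magnitude maximum over nu has negative second derivative, so
    -D_nunu is positive on partials/formants and ~0 between them.
    """
    if spec.beta != 2:
        raise ValueError("band map requires beta = 2")
    raw = apply_rf(SdB, spec)
    return FeatureMap(times=raw.times, axis=raw.axis,
                      values=np.maximum(-raw.values, 0.0),
                      spec=spec, normalization=raw.normalization)


# ---------------------------------------------------------------------------
# Ridge curves
# ---------------------------------------------------------------------------

def _column_ridge_points(band_col: np.ndarray, nu: np.ndarray, C: float):
    """Sub-grid local maxima of one time column of a -D_nunu map."""
    d = dss.difference_operator(band_col[None, :], "dnu")[0]
    d2 = dss.difference_operator(band_col[None, :], "dnunu")[0]
    pts = []
    for j in range(len(nu) - 1):
        if d[j] > 0.0 >= d[j + 1] and (d2[j] < 0 or d2[j + 1] < 0):
            frac = d[j] / (d[j] - d[j + 1]) if d[j] != d[j + 1] else 0.0
            nu_star = nu[j] + frac * (nu[j + 1] - nu[j])
            strength = band_col[j] + frac * (band_col[j + 1] - band_col[j])
            if strength >= C:
                pts.append((nu_star, strength))
    return pts


def ridge_curves(band: FeatureMap, C: float = DEFAULT_RIDGE_THRESHOLD) -> RidgeCurveSet:
    """Link per-column band-response maxima into frequency trajectories.

    Vertices in adjacent time columns are linked when within 1 semitone
    (nearest-nu first); unmatched vertices start new curves.
    """
    nu = np.asarray(band.axis.nu_values, dtype=float)
    values = band.values
    times = band.times
    active: list[dict] = []   # {"nu": last nu, "pts": list}
    finished: list[list] = []
    for i, t in enumerate(times):
        pts = _column_ridge_points(values[i], nu, C)
        used = [False] * len(pts)
        still_active = []
        for tr in active:
            best, best_d = None, RIDGE_LINK_GATE_SEMITONES
            for idx, (nu_star, strength) in enumerate(pts):
                dist = abs(nu_star - tr["nu"])
                if not used[idx] and dist <= best_d:
                    best, best_d = idx, dist
            if best is None:
                finished.append(tr["pts"])
            else:
                used[best] = True
                nu_star, strength = pts[best]
                tr["pts"].append((t, nu_star, strength))
                tr["nu"] = nu_star
                still_active.append(tr)
        for idx, (nu_star, strength) in enumerate(pts):
            if not used[idx]:
                still_active.append({"nu": nu_star, "pts": [(t, nu_star, strength)]})
        active = still_active
    finished.extend(tr["pts"] for tr in active)
    curves = [np.asarray(c, dtype=float) for c in finished if c]
    return RidgeCurveSet(curves=curves, threshold=C)


# ---------------------------------------------------------------------------
# Glissando estimation
# ---------------------------------------------------------------------------

def glissando_filterbank(SdB: LogSpectrogram, base_spec: ReceptiveFieldSpec,
                         v_grid) -> tuple[FeatureMap, np.ndarray]:
    """Best response over a bank of glissando-adapted fields and the argmax v.

    Each grid rate v gives a -D_nunu band response; per point the maximum
    over v is taken and, where the maximum is interior to the grid, refined
    by 3-point parabolic interpolation over v.
    """
    v_grid = np.asarray(v_grid, dtype=float)
    if v_grid.size == 0:
        raise ValueError("v_grid must be non-empty")
    stack = np.stack([
        band_map(SdB, dc_replace(base_spec, v=float(v))).values for v in v_grid
    ])
    best_idx = np.argmax(stack, axis=0)
    best = np.take_along_axis(stack, best_idx[None], axis=0)[0]
    v_hat = v_grid[best_idx].astype(float)
    if v_grid.size >= 3:
        interior = (best_idx > 0) & (best_idx < v_grid.size - 1)
        ii, jj = np.nonzero(interior)
        k = best_idx[ii, jj]
        y0 = stack[k - 1, ii, jj]
        y1 = stack[k, ii, jj]
        y2 = stack[k + 1, ii, jj]
        denom = y0 - 2.0 * y1 + y2
        ok = denom != 0
        frac = np.zeros_like(y1)
        frac[ok] = 0.5 * (y0[ok] - y2[ok]) / denom[ok]
        # assumes a locally uniform v grid around the maximum
        step = np.where(k < v_grid.size - 1, v_grid[np.minimum(k + 1, v_grid.size - 1)]
                        - v_grid[k], v_grid[k] - v_grid[k - 1])
        v_hat[ii, jj] = v_grid[k] + np.clip(frac, -1.0, 1.0) * step
    best_map = FeatureMap(times=SdB.times, axis=SdB.axis, values=best,
                          spec=base_spec, normalization={"v_grid": v_grid})
    return best_map, v_hat


def second_moment_glissando(
    SdB: LogSpectrogram,
    spec: ReceptiveFieldSpec,
    tau_int: float | None = None,
    s_int: float | None = None,
    Ynn_rel_threshold: float = 1e-3,
) -> tuple[SecondMomentMatrix, np.ndarray]:
    """Glissando rate from the spectro-temporal second-moment matrix.

    L_t and L_nu are the (physical-unit, unnormalized) first derivatives of
    the smoothed spectrogram at the derivative scales in ``spec``; their
    pointwise products are smoothed by a third spectro-temporal layer at the
    integration scales (default 4x the derivative scales), and
    ``v = -Y_tn / Y_nn`` wherever ``Y_nn`` exceeds a relative threshold
    (NaN elsewhere).  Matched shears diagonalize the matrix, so on a chirp
    ridge the estimate recovers the true rate.
    """
    if tau_int is None:
        tau_int = 4.0 * spec.tau_a
    if s_int is None:
        s_int = 4.0 * spec.s
    Lt = apply_rf(SdB, dc_replace(spec, alpha=1, beta=0, v=0.0),
                  scale_normalize=False).values
    Ln = apply_rf(SdB, dc_replace(spec, alpha=0, beta=1, v=0.0),
                  scale_normalize=False).values

    dt = SdB.time_step
    rate = 1.0 / dt
    tau_grid = dss.temporal_scale_to_grid(tau_int, rate)
    s_grid = dss.spectral_scale_to_grid(s_int, SdB.delta_nu)

    def integrate(x: np.ndarray) -> np.ndarray:
        out = dss.smooth_1d(x, tau_grid, axis=0) if tau_grid > 0 else x
        return dss.smooth_1d(out, s_grid, axis=1) if s_grid > 0 else out

    Ytt = integrate(Lt * Lt)
    Ytn = integrate(Lt * Ln)
    Ynn = integrate(Ln * Ln)
    moments = SecondMomentMatrix(Ytt=Ytt, Ytn=Ytn, Ynn=Ynn,
                                 tau_int=tau_int, s_int=s_int)
    v = np.full_like(Ynn, np.nan)
    mask = Ynn > Ynn_rel_threshold * Ynn.max()
    v[mask] = -Ytn[mask] / Ynn[mask]
    return moments, v
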