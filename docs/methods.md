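# Methods

## Model overview

`auriscale` implements a two-layer linear model of early auditory processing
grounded in temporal scale-space theory. The guiding constraint is that every
smoothing step, in time or in log-frequency, must be a *scale-space kernel*:
coarser representations may remove structure (local extrema, zero crossings)
but never create it. Over a symmetric domain this forces Gaussian kernels;
over a time-causal domain it forces cascades of truncated exponential kernels
`h_exp(t; mu) = exp(-t/mu)/mu` (first-order integrators).

**Layer 1 (spectrogram).** Each channel at angular frequency `omega`
heterodynes the signal against `cos(omega t)` and `sin(omega t)` and low-passes
both projections with a temporal window of variance `tau(omega)`, giving a
complex response whose magnitude is the spectrogram. Depending on the window
family this is exactly a Gabor filter bank (Gaussian window), a Gammatone
filter bank (equal-time-constant causal cascade; the classical parameters are
`a = 1/(mu^K Gamma(K))`, `b = 1/(2 pi mu)`), or a generalized Gammatone bank
(geometrically distributed time constants). The window scale follows the
wavelength, `tau = tau0 + (2 pi n / omega)^2`, so channel bandwidth is a fixed
number of semitones at every frequency; a pure frequency shift of the input
then translates the log-frequency axis. The frequency axis uses MIDI
semitones (69 = 440 Hz).

**Layer 2 (spectro-temporal receptive fields).** The dB magnitude
`S_dB = 20 log10(|S|/S0)` is filtered by separable kernels
`d_t^alpha d_nu^beta [g(nu - v t; s) T(t; tau_a)]`: temporal smoothing
(Gaussian or causal cascade) times a log-spectral Gaussian, sheared by a
glissando rate `v`, differentiated, and scale-normalized. Working in dB makes
every derivative feature invariant to sound pressure and source distance;
working in log-frequency makes it covariant under transposition; the shear
makes it adaptable to frequency drift. Features built on top: onset/offset
maps (signed parts of `D_t`), spectral-band/formant maps (positive part of
`-D_nunu`), sub-grid partial-tone ridge curves, and two glissando estimators
(filter-bank argmax over `v`, and the second-moment shear `v = -Y_tn/Y_nn`).

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| `n` | window length in wavelengths (`sigma = n lambda`) | 8 | channel bandwidth ~0.6 semitones at -3 dB; resolves adjacent semitones |
| `sigma0` | soft lower bound on window duration | 1 ms | keeps high-frequency windows physical; bound bites (`tau = 4 tau0`) near 4.6 kHz |
| `tau_inf`, `p` | soft upper bound on window variance | off | only needed for latency-critical low-frequency use |
| `K` (layer 1) | causal cascade stages | 7 | selectivity close to Gaussian while time-causal |
| `c` | scale ratio of the geometric cascade | sqrt(2) | half-octave spacing of intermediate scales; good delay/selectivity trade |
| axis | 80 Hz – 16 kHz, 48 channels/octave | — | quarter-semitone resolution over the musically relevant range |
| hop | output decimation | 1 ms | second-layer features live at >= ms scales |
| `tau_a`, `s` | second-layer scales | per feature | ~(10 ms)^2 and (0.5 st)^2 for partials; s ~ (4 st)^2 for formants |
| `K` (layer 2) | second-layer cascade stages | 4 | shorter cascade; derivative orders up to 3 remain defined |
| `C` | ridge strength threshold | 3 | suppresses sidelobe ridges while keeping >= 10 partials of a -6 dB/octave complex |

Units: temporal scales are *variances* in seconds^2 (`sigma_t = sqrt(tau)`),
log-spectral scales variances in semitones^2, glissando rates in
semitones/second (1 octave/s = 12 st/s).

## Discretization

* **Causal smoothing** uses first-order recursive filters
  `y[n] = y[n-1] + (x[n] - y[n-1])/(1 + mu)`. The grid time constant solves
  `mu^2 + mu = delta_tau` exactly, so the composed impulse-response variance
  equals the requested grid variance to machine precision (variance is
  additive under convolution; the discrete mean `mu` differs slightly from
  the continuous one). Filter state is seeded with the first input sample so
  constants pass through without an onset transient (initialization is a free
  choice of the implementation).
* **Symmetric smoothing** uses the discrete analogue of the Gaussian
  `T(n; s) = exp(-s) I_n(s)` (scaled Bessel evaluation), truncated where the
  mass exceeds `1 - 1e-6`, renormalized to unit DC gain, applied under
  mirrored (adiabatic) boundaries. It satisfies the exact discrete semigroup
  `T(s1) * T(s2) = T(s1+s2)`. Above `s = 1e4` a sampled continuous Gaussian
  is used instead; the two agree to high accuracy there and the Bessel
  recursion becomes numerically fragile.
* **Derivatives** come from small-support differences: backward two-tap
  `delta_t` (aligned to the later sample, preserving causality; its
  half-sample delay is documented, not compensated), centered `delta_nu`,
  and the common `(1, -2, 1)` second-difference. Temporal derivatives can
  equivalently be read from differences of adjacent cascade stages
  (`temporal_derivative_from_channels`), which needs no extra temporal buffer.
* **Glissando-adapted filtering** shear-warps the spectrogram by `-v t`
  (cubic spline interpolation, edge replication), filters separably, and
  unwarps. The shear origin is the global time origin for whole-spectrogram
  filtering (a pure shear); kernels rendered for visualization use their own
  frame origin.
* **Scale normalization** multiplies grid derivatives (converted to
  per-second / per-semitone) by `tau_a^{alpha/2} s^{beta/2}`. The first-order
  temporal and second-order spectral cases fix the variance-power convention;
  it is generalized to arbitrary orders.

## Numeric kernel sampling

Continuous cascade kernels with distinct time constants have no compact
closed form, so their impulse response is computed on a fine grid
(step `sqrt(tau)/1000`, support `[0, m + 10 sqrt(tau)]`): a unit-area
discrete impulse is passed through each stage using an exponential
integrator that is exact for piecewise-linear input. Each stage has exactly
unit DC gain, so the sampled kernel's mass is 1 up to interpolation error
(< 1e-6 observed), and the only systematic bias is an extra `dt^2/6` of
variance from the initial hat impulse (relative error ~1e-7 at the default
step). Kernel-peak delays are located on a 1e5-point grid with 3-point
parabolic refinement, which reproduces the analytic two-stage peak position
to < 5e-5. Derivatives of distinct-time-constant kernels are taken by
central differences on the fine grid. Equal-time-constant cascades use their
closed gamma-density form and its analytic first two derivatives; orders
`alpha >= K` are rejected rather than returning distributional derivatives,
since the cascade is only `K-1` times continuously differentiable.

The root solve for the logarithmic family's bandwidth parameter `theta`
bisects its strictly decreasing dB response on `(0, hi]` to 1e-9, doubling
`hi` from 4 when a deep attenuation level on a heavy-tailed (small `K`)
window pushes the root out of the initial bracket.

## Synthetic stimuli

The generator mirrors the stimuli the model is meant to analyze: harmonic
complexes with 20 partials and a -6 dB/octave spectral slope (stepped
fundamentals supported), pure tones, gated narrowband events, and exponential
glissando chirps with phase computed from the exact integral of
`f0 * 2^(v t / 12)`. Partials at or above Nyquist are dropped with a warning.
What it does **not** emulate: measurement noise, reverberation, amplitude
modulation/vibrato, phase coupling between partials, or any cochlear
nonlinearity. Tests passing on this suite therefore demonstrate correctness
of the linear analysis chain and its invariances — not robustness to
real-world recording conditions.

Test and verification runs use sample rates of 8–16 kHz and durations of
0.4–1 s with axes restricted to the band of interest; all analysis steps are
rate-independent by construction (the 44.1 kHz default is only a default).

## Design choices made where the design was open

* dB reference `S0` defaults to the spectrogram's own maximum (0 dB = peak),
  floored at -120 dB.
* Delay compensation of causal spectrograms shifts each channel earlier by
  the window's first inflection point, rounded to integer samples.
* Ridge linking uses a 1-semitone gate between adjacent frames,
  nearest-frequency first; unmatched vertices start new curves.
* The glissando filter bank maximizes raw responses over `v` (no per-`v`
  normalization) and refines interior maxima by 3-point parabolic
  interpolation; the default grid `±{20, 40, 80}` st/s is configuration, not
  a constant, since display units for drift rates vary by convention.
* Second-moment integration scales default to 4x the derivative scales and
  the third smoothing layer is the symmetric discrete Gaussian on both axes;
  the shear estimate is reported only where `Y_nn > 1e-3` of its maximum.
* The plain temporal derivative `d_t` is the default in glissando-adapted
  fields; the convected derivative `d_t + v d_nu` is available by composing
  the two returned derivative maps but is not the default.
* The Gaussian window's delay `delta` is exposed and defaults to 0 (off-line
  use).

## Known limitations

* Offset detection against *silence* is smeared: in dB a causal decay to
  zero magnitude is a long ramp toward the floor, so the offset peak lags by
  the kernel delay plus the decay visible above the floor. Offsets between
  two sound levels localize as sharply as onsets.
* Sound-pressure invariance of features involving log-spectral smoothing is
  exact only up to IEEE rounding of the added constant (~1e-9 absolute on
  typical maps); purely temporal derivative features are bit-exact.
* Integer-sample delay compensation leaves a sub-sample residual; the
  two-tap `delta_t` carries an uncompensated half-sample latency.
* The model is linear and feed-forward: no adaptation, no gain control, no
  phase information in layer 2, no binaural processing.
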