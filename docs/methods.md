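# Methods and numerical conventions

This note records the modelling conventions and numerical choices baked
into `rppgflow`, in the order signal flow encounters them.

## Signal model and sign convention

The back-scattered irradiance is decomposed as

```
E = E_DC + E_V(P) + E_Q(Q),        PPG = a' + b'·P − E_Q
```

- `E_V` is affine in transmural pressure: vessel distension increases
  the illuminated blood volume, so pressure *raises* the PPG
  (`b' = 2.15 a.u./mmHg` in the bundled constants, intercept folded
  into `a'`).
- `E_Q` enters with a **negative sign**: shear-induced red-cell
  orientation increases forward scattering and *lowers* the reflected
  signal. This sign is what produces counter-phase beats (below).
- The sensor map is `V = c·E^d` with `d = 1.3` (Beer–Lambert-type
  compression). `sensor_linearized` provides the first-order expansion
  around a reference irradiance; its error is bounded by `(ΔE/Ē)²`.

## Flow pathway: regime-switching saturation/relaxation

High shear (orientation is fast, treated as instantaneous):

```
E_Q = m'·(Q/Q_c)/(1 + Q/Q_c),      m' = 1613 a.u.,  Q_c = 328 mL/min
```

so `E_Q(Q_c) = m'/2` exactly. Equivalently, in shear-rate form the
aligned fraction is `γ̇/(γ̇ + γ̇_c)` with `γ̇_c = 870 s⁻¹`; the two are
linked by the Poiseuille wall shear rate `γ̇ = 32·Q/(π·D³)`, which is
also how the 4-mm reference diameter is back-solved
(`solve_reference_diameter`).

Low shear (deceleration below `0.5·Q_c` or near-zero flow): the output
relaxes through an `r:1` mixture of two **exact-decay first-order
lags** with weights

```
w[k] = (r·(1−a_d)·a_d^k + (1−a_a)·a_a^k)/(r+1),  a = exp(−Δt/τ)
```

Implemented with two `scipy.signal.lfilter` one-pole recursions, this
is O(n), has unit DC gain (the regime transition is continuous), and
its response to a step-to-zero input is *exactly* the normalized
biexponential `(r·e^(−t/τ_d) + e^(−t/τ_a))/(r+1)` — verified against
the closed form at 1e−14 and against an O(n²) direct-convolution oracle
at 1e−9. `decay_kernel` separately exposes the unit-time-integral
relaxation *shape* for analysis and plotting.

Regime labels come from a Savitzky–Golay smoothed derivative (50 ms
window): enter low shear on deceleration below `0.5·Q_c` or flow below
`0.02·Q_c`; exit on re-acceleration above `0.1·Q_c`; label runs shorter
than 20 ms are suppressed (hysteresis against noise chatter).

Constants: `τ_d = 0.39 s`, `τ_a = 1.78 s`, `n_d/n_a = 2.2` (3.6 when
aggregation is inhibited). The ratio change is pure arithmetic:
`(3.6−2.2)/2.2 = 700/11 % ≈ 63.6 %` increase, and the
aggregation-attributed fraction `1/(1+r)` falls by
`1 − (1+2.2)/(1+3.6) ≈ 38.9 %`.

## Wall law and synthesis

The elastic wall is linear over 50–200 mmHg:
`D(P) = D_ref + b·(P − P_ref)` with `b = 1.245×10⁻³ mm/mmHg`,
`D_ref = 4 mm` at 100 mmHg; `is_stiff` pins the diameter (rigid-tube
sweeps). Outside the characterized range the model warns rather than
extrapolating silently.

Protocol generators run at 1 kHz and are bit-exact reproducible from
`ProtocolSpec.seed` (child streams via `numpy.random.SeedSequence`;
spawned seeds are kept below 2³¹ so they survive any 32-bit consumer).
Noise is additive white Gaussian per channel with defaults
σ_P = 0.5 mmHg, σ_Q = 2 mL/min, σ_PPG = 5 a.u., σ_D = 0.002 mm
(0.008 mm in the wall-law Monte-Carlo study, matching video-calliper
dispersion). Plateau protocols hold each level ≥ 4 s with 1-s ramps.

Pulsatile beats use a 4-harmonic pressure template (amplitudes
1/0.5/0.23/0.10) with the systolic peak placed at 20 % of the beat, and
a gamma-shaped flow pulse peaking at 18 % — on a resistance-terminated
rig flow slightly *leads* pressure; an early version of the template
had pressure peaking at beat onset, which reversed that lead and was
fixed as a construction bug.

## Calibration

Plateaus are detected from 1-s block means, grouping neighbours whose
difference is ≤ `rel_tol`·(signal span) with `rel_tol = 0.02`;
`rel_tol` must stay below half the smallest level step relative to the
span, or adjacent ramp blocks chain into one plateau. A plateau is the
last 4 s of a group of ≥ 4 blocks.

- `fit_pressure_slope`: OLS on plateau means; requires ≥ 3 plateaus and
  near-zero flow.
- `fit_flow_saturation`: multi-start (5 geometric `Q_c` starts)
  bounded nonlinear least squares; refuses records whose flow never
  reaches 20 % of the initial `Q_c` guess (the saturation scale is
  unidentifiable there). Gauss–Newton standard errors from
  `pinv(JᵀJ)·s²`, with an ill-conditioning warning above condition
  1e6.
- `fit_biexponential`: parameterized as
  `θ = [C, A, log r, log τ_d, φ]` with `τ_a = τ_d(1+e^φ)`, which
  enforces `τ_d < τ_a` and removes the label-switching degeneracy;
  5 `τ_d` starts geometric over (0.02, 0.3)·pause span;
  delta-method standard errors; per-pause fits are pooled as
  mean (SD). Pauses shorter than 5·τ̂_a trigger a truncation warning.
- `fit_pressure_diameter`: OLS; warns when the fitted pressure range
  spans less than 50 mmHg.

All fitted estimators follow the scikit-learn protocol
(`fit`/`predict`, `get_params`/`set_params`, trailing-underscore
fitted attributes) and serialize through a common `FitResult`.

## Evaluation

- `lowpass_50`: order-12 Butterworth SOS, zero-phase
  (`sosfiltfilt`). Order 12 is needed to keep passband droop at 40 Hz
  under 0.1 dB *and* ≥ 30 dB attenuation at 100 Hz; an order-4 design
  fails the passband contract.
- `welch_msc`: `scipy.signal.coherence`, boxcar window of 2048 samples
  with 50 % overlap; requires ≥ 4096 samples (≥ 3 averaged segments —
  with fewer, the estimator degenerates toward 1). The DC bin is
  excluded from invariance comparisons: after per-segment mean removal
  it is a 0/0 residual.
- `wavelet_coherence`: complex Morlet (ω₀ = 6), dyadic scales at 12
  voices per octave, Gaussian time smoothing with σ = scale and a
  0.6-octave boxcar scale smoothing of scale-normalized spectra
  (without smoothing, magnitude-squared coherence is identically 1).
  Cone of influence at the e-folding time √2·scale;
  `masked_phase` hides phase outside it.
- `beat_phase`: per beat, each channel is projected on the beat-rate
  complex exponential; the phase difference is
  `angle(z_ppg·conj(z_pressure))`, and a beat is flagged
  **counter-phase** when |Δφ| > π/2. Beats shorter than 16 samples are
  merged into their neighbour with a warning.

Counter-phase reproduction: with the bundled constants, a beat with
systolic pressure below ~100 mmHg and strong flow pulsatility
(600–800 mL/min swing) is dominated by the negative flow term and flags
counter-phase; the same flow pulse at systolic 160 mmHg is pressure
dominated and does not.

## Monte-Carlo study sizes

The `reproduce` bundle and `scripts/acceptance.py` use 100 seeds for
the slope, saturation and wall-law recoveries and 20 pauses (10 s) for
the biexponential recovery; sizes were chosen a priori so that each
Monte-Carlo standard error is a small fraction of the published
uncertainty band (e.g. the wall-law tolerance of 1×10⁻⁶ mm/mmHg is
≈ 6.6 standard errors at 100 seeds and 15 000 samples per ramp).
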