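# Methods

## 1. Physical model

### 1.1 Tensioned shear beam

The tendon is modeled as a one-dimensional tensioned beam in the
shear-dominated (low bending stiffness) limit. Transverse displacement
`w(x, t)` obeys

```
rho_eff * w_tt = (k' * mu + sigma) * w_xx
```

giving a non-dispersive wave speed

```
c = sqrt((k' * mu + sigma) / rho_eff)
```

Assumptions:

- Bending stiffness is negligible relative to shear and tension
  (slender tendon, transverse excitation).
- Stress is uniform along the measured segment and quasi-static on the
  time scale of a single tap (wave transit ~0.1-1 ms versus load
  variation >= 10 ms).
- The surrounding fluid/tissue moves with the tendon, contributing an
  added mass; this is folded into `rho_eff` rather than modeled as a
  separate medium.

`rho_eff = rho_tissue + rho_fluid * (a_perp / a_motion)` for an elliptical
cross-section vibrating along one axis (`effective_density`).

### 1.2 Constitutive model

Uniaxial tendon response uses an incompressible, transversely isotropic
hyperelastic model: a two-coefficient Mooney-Rivlin matrix plus a piecewise
fiber family (zero below stretch 1, exponential toe region, linear above a
transition stretch `lambda_star`, with the linear-branch offset `c6` fixed
by continuity). The tangent shear modulus entering the wave equation is
`mu_t(lambda) = 2 * (C1 + C2 / lambda)`.

The shipped coefficients (`ILLUSTRATIVE_TENDON`) are illustrative: they are
chosen so the ground-state shear modulus is 0.06 MPa and the linear-region
axial modulus is of order 100 MPa — representative magnitudes, not fitted
to any specimen.

## 2. Parameters

### 2.1 Beam presets

| Parameter | Ex vivo (`EXVIVO_BEAM`) | In vivo (`INVIVO_BEAM`) | Units | Rationale |
|---|---|---|---|---|
| `rho_eff` | 1730 | 3500 | kg/m^3 | ex vivo: wet tendon 1060 + saline added mass for the measured aspect ratio (1000 x 0.67); in vivo: surrounding soft tissue entrains more mass, raising the effective density |
| `mu` | 0.06e6 | 0.06e6 | Pa | ground-state shear modulus; lower end of the considered 0.04-1.6 MPa range |
| `k_shear` | 0.9 | 0.9 | — | shear correction factor for the cross-section |
| `area` | 22.6e-6 | 65e-6 | m^2 | porcine digital flexor vs human Achilles cross-sections |
| `length` | 0.1 | 0.15 | m | grip-to-grip vs tendon free length |

### 2.2 Instrumentation

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `PIEZO_STACK_DISPLACEMENT` | 19.8e-6 | m | piezo stack actuation at full drive; direct push-rod amplitude ex vivo |
| `TAPPER_LEVER_GAIN` | 2.0 | — | skin-mounted tapper lever amplification; `SKIN_TAP_AMPLITUDE` = 39.6 um |
| tap rate | 25 (ex vivo), 50 (in vivo) | Hz | repetition rates of the two tappers |
| tap pulse width | 1e-3 | s | drive pulse duration; raised-cosine prescribed displacement |
| RF frame rate | 14100 | frames/s | single-element M-mode rate needed to track transverse vibration |
| RF sampling rate | 40e6 | Hz | per-sample depth increment 1560/(2*40e6) = 19.5 um |
| accelerometer rate | 50000 | Hz | DAQ rate; 10 mm sensor spacing resolves lags down to tens of us |

### 2.3 Estimator settings

| Setting | Default | Rationale |
|---|---|---|
| ex vivo band-pass | 50-2000 Hz, order 2, zero-lag | isolates tap-induced vibration; zero-phase so lags are unbiased |
| in vivo band-pass | 150-1000 Hz, order 2, zero-lag | wavefront energy band at the skin |
| in vivo tap window | 20 ms (1000 frames at 50 kHz) | one inter-tap interval at 50 Hz |
| ex vivo tap window | one inter-tap interval (from trigger spacing) | the standing wave rings down between taps; the full interval maximizes FFT resolution (a fixed 20 ms window quantizes estimates onto 12.5 Hz padded bins) |
| FFT peak | Hann window, x4 zero-padding, parabolic refinement, 8-bin DC guard | sub-bin frequency without leakage from DC |
| correlation floor | 0.6 (accelerometer), 0.5 (speckle) | flags windows without a coherent wavefront |
| speed plausibility band | 2-200 m/s | rejects lags from echoes or noise; also caps the lag search (`max_lag = distance / 2 m/s`) |
| speckle kernels | 0.5 mm, non-overlapping, x4 polyphase upsampling, +-1 mm search | kernel shorter than the tendon band, search far beyond physiological per-frame motion |
| sub-sample refinement | cosine interpolation of the correlation peak | exact on pure-cosine correlation; parabolic fallback flagged |
| calibration low-pass | 20 Hz, zero-lag | smooths tap-rate jitter before regression against slowly varying load |
| heel-strike detection | 8 x MAD of the signed band-passed trace, 0.3 s refractory | floor ~5.4 sigma sits above the expected maximum of pure noise yet far below heel-strike spikes |

## 3. Numerical methods

- **Wave solver.** Explicit leapfrog finite differences on `rho w_tt =
  (k' mu + sigma(t)) w_xx`, grid `dx = L/300` (convergence checked against
  `L/600`; lag estimates change < 0.5%), time step from a CFL number of 0.9
  at the maximum stress in the run. Stress is held constant within each
  inter-tap interval (quasi-static) and updated between taps.
- **Taps** are prescribed raised-cosine displacement pulses at the tap node
  — matching a displacement-drive actuator — not force impulses.
- **Boundaries.** `fixed-fixed` (gripped specimen) pins both ends;
  `absorbing` uses first-order Mur radiation conditions to emulate a long
  tendon. Mur absorption is imperfect (a few percent reflection), which is
  why time-of-flight windows emphasize the first arrival.
- **Damping.** For fixed-fixed runs a Kelvin-Voigt (stiffness-proportional)
  term is applied spectrally via a type-I DST each step, modal decay
  `lambda_n = eta * (n pi / L)^2 / 2` with `eta = 0.10 m^2/s`: the
  fundamental rings down within one inter-tap interval while biasing the
  spectral peak by less than 1% at the lowest fundamental used. Absorbing
  runs default to zero damping (energy leaves through the ends).
- **Sensor resampling.** Simulation-grid traces are low-pass filtered
  (zero-phase Butterworth at 0.45 x the output rate) before interpolation
  onto sensor clocks. Without this, grid-scale ripples in the
  twice-differenced acceleration alias into the output band and bias
  cross-correlation lags by several percent.
- **Speckle synthesis.** Random scatterers within a 4-10 mm band are
  convolved with a Gaussian-enveloped 10 MHz pulse; transverse tissue
  motion rigidly translates the scatterer field. Zero motion yields
  bit-identical frames; the same seed yields the same sequence.
- **Speckle tracker bias correction.** The three-point cosine refinement
  reports a small fixed offset per kernel even for a perfect self-match
  (finite speckle windows make the correlation peak slightly asymmetric).
  Each reference kernel's self-match delta is estimated against its own
  frame and subtracted; identical frames then give exactly zero
  displacement and cumulative displacement does not drift.

## 4. Fidelity limits of the synthetic data

The simulations validate the estimators, not the biology. Known gaps:

- The beam is 1-D and non-dispersive: no bending stiffness, no
  frequency-dependent speed, no guided-wave modes, no through-thickness
  structure.
- Mur boundaries reflect a few percent of incident energy; real tendons
  terminate in muscle and bone with different (and unknown) impedances.
- Accelerometer noise is white and multiplicative-RMS-scaled; real sensor
  noise is colored and includes motion artifact, skin coupling, and
  cross-talk.
- RF speckle moves rigidly with the tendon; real speckle decorrelates with
  deformation, out-of-plane motion, and electronic noise.
- The gait stress profile is a stylized two-bump waveform (stance peak at
  45% of the cycle, late-swing bump at 90%) with a ground-reaction-force
  curve built from overlapping bumps; it reproduces the qualitative shape,
  not subject-specific magnitudes.
- Added-mass effective densities are single constants per setting; in
  reality they vary with geometry and surrounding tissue.

## 5. Limitations

- Absolute tension requires `A` and `rho_eff`, both uncertain in vivo;
  without a per-subject calibration the method is most reliable for
  relative load changes.
- The shear-dominated approximation degrades for very slack tendons where
  `sigma` is comparable to `k' mu`.
- The standing-wave estimator assumes the first vibratory mode dominates;
  a second-peak contamination ratio above 0.8 is logged as a warning.
- Repeated-measures ANOVA on calibration slopes requires a complete
  specimen x rate matrix; missing cells are rejected rather than imputed.
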