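# tensiometry

Shear wave tensiometry: estimating the axial load carried by a tendon from
the propagation speed of externally induced transverse (shear) waves.

## The science

Tendons transmit muscle forces, but those forces cannot be measured directly
in people without implanted sensors. Tensiometry exploits a simple piece of
beam mechanics instead: for a tensioned beam in the shear-dominated limit, a
transverse wave travels at

```
c^2 = (k' * mu + sigma) / rho_eff
```

where `sigma` is the axial stress, `mu` the shear modulus, `k'` a shear
correction factor, and `rho_eff` the effective density (tissue density plus
an added-mass term from fluid entrained by the vibrating tendon). At
physiological loads the stress term dominates (`sigma >> k' * mu`), so the
squared wave speed is essentially proportional to stress and the tension is
`T ≈ A * rho_eff * c^2`. Tapping the skin over a tendon and timing the wave
between two points therefore gives a non-invasive, per-tap load gauge.

This package implements the full measurement chain twice over:

- **Forward models** — the tensioned-beam dispersion relation (`physics`), a
  fiber-reinforced hyperelastic constitutive model for tendon
  (`constitutive`), and a finite-difference simulator of the tapped beam
  plus ultrasound RF speckle and accelerometer synthesis (`synthetic`).
- **Estimation pipelines** — signal-processing primitives (`dsp`), 1-D RF
  speckle tracking (`speckle`), the gripped-tendon standing-wave estimator
  `c = 2 f L` (`standing_wave`), the dual-accelerometer time-of-flight
  tensiometer (`tensiometer`), squared-speed-versus-load calibration and
  rate-independence statistics (`calibration`), and stride-level gait
  analysis (`gait`).
- **Plumbing** — CSV/HDF5/YAML formats (`io`) and a `tensiometry` CLI
  (`cli`) that chains the stages into reproducible runs.

Because the original in vivo and ex vivo data cannot be re-collected, every
estimator is validated against simulation oracles: waves are simulated with
known stress, pushed through the same pipelines that would process real
sensor data, and required to recover the known answer within tight
tolerances (see `tests/test_acceptance.py`).

## Worked example

Simulate a tapped Achilles-like tendon loaded so the true wave speed is
60 m/s, run the dual-accelerometer tensiometer on the simulated sensors,
and invert the speed back into stress and tension:

```python
import numpy as np

from tensiometry.physics import INVIVO_BEAM, stress_from_speed, tension_from_speed
from tensiometry.synthetic import TapTrain, SKIN_TAP_AMPLITUDE, simulate_beam_wave
from tensiometry.tensiometer import speed_series

# simulate a tapped Achilles tendon held at 60 m/s wave speed
sigma = stress_from_speed(INVIVO_BEAM, 60.0).sigma
taps = TapTrain(rate=50.0, amplitude=SKIN_TAP_AMPLITUDE)
sim = simulate_beam_wave(INVIVO_BEAM, sigma, taps, sensor_positions=[0.04, 0.05],
                         boundary="absorbing", duration=0.3)

sp = speed_series(sim.acceleration[0], sim.acceleration[1], sim.trigger,
                  distance=0.01)
c = np.nanmedian(sp.speed[sp.valid])
state = stress_from_speed(INVIVO_BEAM, c)
print(f"valid taps          : {sp.n_valid}/{len(sp)}")
print(f"median wave speed   : {c:.2f} m/s")
print(f"axial stress        : {state.sigma / 1e6:.2f} MPa")
print(f"tendon tension      : {tension_from_speed(INVIVO_BEAM.area, INVIVO_BEAM.rho_eff, c):.0f} N")
```

Output:

```
valid taps          : 14/14
median wave speed   : 60.03 m/s
axial stress        : 12.56 MPa
tendon tension      : 820 N
```

The same flow is available from the command line; `tensiometry demo
--out-dir demo` regenerates the three canonical figures (binned
speed-vs-stress calibration, torque-vs-squared-speed fit, gait-cycle
ensemble) from pure simulation, byte-reproducibly for a given `--seed`.

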