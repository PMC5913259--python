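"""Tensioned shear-beam relations between axial stress and transverse wave speed.

A tendon vibrated at high frequency behaves as a tensioned Timoshenko beam in
its shear-dominated limit: the restoring force per unit transverse curvature is
the sum of the effective shear stiffness ``k' * mu`` and the axial Cauchy
stress ``sigma``, so the transverse (shear) wave speed obeys

    c**2 = (k' * mu + sigma) / rho_eff

with ``rho_eff`` the effective density including fluid added mass.  At
physiological loads the stress term dominates, which is what makes wave speed
usable as a load sensor.  All quantities are SI (Pa, m, s, kg m^-3); unit
conversions belong to the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BeamSpec",
    "StressState",
    "wave_speed",
    "stress_from_speed",
    "tension_from_speed",
    "standing_wave_speed",
    "effective_density",
    "EXVIVO_BEAM",
    "INVIVO_BEAM",
]


@dataclass(frozen=True)
class BeamSpec:
    """Geometric and material description of a tendon segment.

    Attributes
    ----------
    rho_eff:
        Effective density in kg m^-3 (tissue density plus entrained-fluid
        added mass).
    mu:
        Tangent shear modulus about the current stressed state, Pa.
    k_shear:
        Shear correction factor (cross-section shape factor, 0 < k' <= 1).
    area:
        Cross-sectional area, m^2.
    length:
        Grip-to-grip (free vibrating) length, m.
    """

    rho_eff: float = 1730.0
    mu: float = 0.06e6
    k_shear: float = 0.9
    area: float = 22.6e-6
    length: float = 0.1

    def __post_init__(self) -> None:
        if self.rho_eff <= 0:
            raise ValueError("rho_eff must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not 0 < self.k_shear <= 1:
            raise ValueError("k_shear must lie in (0, 1]")
        if self.area <= 0:
            raise ValueError("area must be positive")
        if self.length <= 0:
            raise ValueError("length must be positive")


#: Ex vivo digital-flexor preset: measured wet density plus saline added mass.
EXVIVO_BEAM = BeamSpec(rho_eff=1730.0, mu=0.06e6, k_shear=0.9,
                       area=22.6e-6, length=0.1)

#: In vivo preset. The effective density of a tendon vibrating against skin,
#: fat and muscle is not directly measurable; this value places walking-scale
#: stresses (~2-20 MPa) onto the 15-80 m/s speed range seen in vivo.
INVIVO_BEAM = BeamSpec(rho_eff=3500.0, mu=0.06e6, k_shear=0.9,
                       area=65e-6, length=0.15)


@dataclass(frozen=True)
class StressState:
    """Axial Cauchy stress acting on the transverse cross-section, Pa."""

    sigma: float


def _sigma_value(stress) -> np.ndarray | float:
    if isinstance(stress, StressState):
        return stress.sigma
    return stress


def wave_speed(beam: BeamSpec, stress) -> np.ndarray | float:
    """Shear wave speed on a tensioned beam, m/s.

    ``stress`` may be a :class:`StressState`, a float, or an array of axial
    stresses in Pa.  Negative (slack) stress is allowed as long as the
    effective restoring term ``k'*mu + sigma`` stays positive.
    """
    sigma = np.asarray(_sigma_value(stress), dtype=float)
    restoring = beam.k_shear * beam.mu + sigma
    if np.any(restoring < 0):
        raise ValueError(
            "non-positive restoring term k_shear*mu + sigma = "
            f"{beam.k_shear}*{beam.mu} + {np.min(sigma)}: the beam cannot "
            "support a transverse wave"
        )
    c = np.sqrt(restoring / beam.rho_eff)
    return float(c) if c.ndim == 0 else c


def stress_from_speed(beam: BeamSpec, speed) -> StressState | np.ndarray:
    """Invert the wave-speed relation: sigma = rho_eff*c**2 - k'*mu (Pa)."""
    speed = np.asarray(speed, dtype=float)
    if np.any(speed < 0):
        raise ValueError("speed must be non-negative")
    sigma = beam.rho_eff * speed**2 - beam.k_shear * beam.mu
    if sigma.ndim == 0:
        return StressState(float(sigma))
    return sigma


def tension_from_speed(area: float, rho_eff: float, speed) -> np.ndarray | float:
    """Axial tension T = A * rho_eff * c**2 (N), valid when k'*mu << sigma."""
    if area <= 0:
        raise ValueError("area must be positive")
    if rho_eff <= 0:
        raise ValueError("rho_eff must be positive")
    t = area * rho_eff * np.asarray(speed, dtype=float) ** 2
    return float(t) if t.ndim == 0 else t


def standing_wave_speed(frequency, length: float) -> np.ndarray | float:
    """Wave speed from the fundamental standing-wave frequency: c = 2*f*L.

    A fixed-fixed beam vibrating in its first mode has wavelength 2*L, so the
    wave speed follows directly from the observed vibration frequency.
    """
    frequency = np.asarray(frequency, dtype=float)
    if np.any(frequency <= 0):
        raise ValueError("frequency must be positive")
    if length <= 0:
        raise ValueError("length must be positive")
    c = 2.0 * frequency * length
    return float(c) if c.ndim == 0 else c


def effective_density(tissue_density: float, fluid_density: float,
                      semiaxis_perp: float, semiaxis_motion: float) -> float:
    """Effective density of an elliptical beam vibrating in fluid, kg m^-3.

    Potential flow around an elliptical cylinder oscillating along one
    principal axis entrains an added mass of ``rho_fluid * pi * a_perp**2``
    per unit length, where ``a_perp`` is the cross-section semi-axis
    perpendicular to the motion.  Normalised by the section area
    ``pi * a_perp * a_motion`` this contributes
    ``rho_fluid * a_perp / a_motion`` to the density:

        rho_eff = rho_tissue + rho_fluid * (a_perp / a_motion)

    ``fluid_density = 0`` recovers the vacuum (bare tissue) limit and a
    circular section recovers the classical added mass equal to the displaced
    fluid.
    """
    if tissue_density <= 0:
        raise ValueError("tissue_density must be positive")
    if fluid_density < 0:
        raise ValueError("fluid_density must be non-negative")
    if semiaxis_perp <= 0 or semiaxis_motion <= 0:
        raise ValueError("ellipse semi-axes must be positive")
    return tissue_density + fluid_density * (semiaxis_perp / semiaxis_motion)
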