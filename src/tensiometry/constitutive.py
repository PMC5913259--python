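"""Transversely isotropic hyperelastic tendon material.

The tissue is modelled as aligned collagen fibers embedded in an isotropic
Mooney-Rivlin matrix.  The strain energy is

    W = C1*(I1~ - 3) + C2*(I2~ - 3) + F2(lambda~)   (exact incompressibility)

where the fiber term F2 is defined through the piecewise fiber stress
``lambda~ * dF2/dlambda``: zero below the reference stretch (crimped fibers),
exponential while fibers uncrimp, and linear once all fibers are straight.
The constant of the linear branch is forced by continuity at the straightening
stretch ``lambda_star``.

Only the uniaxial response and the tangent shear modulus about the stretched
state are needed here; both have closed forms under incompressibility, so no
volumetric solver is carried.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .physics import BeamSpec, wave_speed

__all__ = [
    "MaterialParams",
    "fiber_stress",
    "cauchy_stress_uniaxial",
    "tangent_shear_modulus",
    "predicted_speed_vs_strain",
    "ILLUSTRATIVE_TENDON",
]


@dataclass(frozen=True)
class MaterialParams:
    """Coefficients of the fiber-reinforced Mooney-Rivlin model.

    ``c1``, ``c2`` (Pa) set the matrix response; ``c3`` (Pa) scales the
    exponential toe-region fiber stress; ``c4`` (dimensionless) sets the
    uncrimping rate; ``c5`` (Pa) is the straightened-fiber modulus;
    ``lambda_star`` (> 1) is the stretch at which fibers straighten.
    ``bulk`` is retained for fidelity with penalty formulations but unused:
    the model is evaluated in the exact-incompressibility limit.  The linear
    branch constant C6 is not stored; it is derived from continuity.
    """

    c1: float
    c2: float
    c3: float
    c4: float
    c5: float
    lambda_star: float
    bulk: Optional[float] = None

    def __post_init__(self) -> None:
        if self.c1 + self.c2 <= 0:
            raise ValueError("C1 + C2 must be positive (ground-state shear modulus)")
        if self.c3 < 0:
            raise ValueError("C3 must be non-negative")
        if self.c4 <= 0:
            raise ValueError("C4 must be positive")
        if self.c5 < 0:
            raise ValueError("C5 must be non-negative")
        if self.lambda_star <= 1:
            raise ValueError("lambda_star must exceed 1")

    @property
    def c6(self) -> float:
        """Linear-branch constant enforcing fiber-stress continuity at lambda_star."""
        toe_at_star = self.c3 * (np.exp(self.c4 * (self.lambda_star - 1.0)) - 1.0)
        return toe_at_star - self.c5 * self.lambda_star


#: Illustrative parameter set: ground-state shear modulus 2*(C1+C2) = 0.06 MPa
#: (the classical-elastography estimate for unloaded tendon) and a
#: straightened-fiber modulus of order 100 MPa.  Illustrative, not fitted.
ILLUSTRATIVE_TENDON = MaterialParams(
    c1=0.02e6, c2=0.01e6, c3=0.1e6, c4=100.0, c5=150e6, lambda_star=1.03
)


def fiber_stress(lambda_tilde, params: MaterialParams):
    """Fiber Cauchy stress term lambda~ * dF2/dlambda, Pa.

    Piecewise in stretch: 0 for ``lambda~ <= 1``;
    ``C3*(exp(C4*(lambda~-1)) - 1)`` in the uncrimping toe region;
    ``C5*lambda~ + C6`` once straightened, with C6 from continuity.
    """
    lam = np.asarray(lambda_tilde, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    toe = params.c3 * (np.exp(params.c4 * (lam - 1.0)) - 1.0)
    linear = params.c5 * lam + params.c6
    out = np.where(lam <= 1.0, 0.0,
                   np.where(lam <= params.lambda_star, toe, linear))
    return float(out) if out.ndim == 0 else out


def cauchy_stress_uniaxial(lam, params: MaterialParams):
    """Axial Cauchy stress under incompressible uniaxial stretch, Pa.

    With J = 1 the transverse stretch is ``lam**-0.5`` and the matrix
    contributes ``2*(C1 + C2/lam)*(lam**2 - 1/lam)``; the fiber term adds
    :func:`fiber_stress`.
    """
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ValueError("stretch must be positive")
    matrix = 2.0 * (params.c1 + params.c2 / lam_arr) * (lam_arr**2 - 1.0 / lam_arr)
    out = matrix + fiber_stress(lam_arr, params)
    return float(out) if out.ndim == 0 else out


def tangent_shear_modulus(lam, params: MaterialParams):
    """Matrix tangent shear modulus about the uniaxially stretched state, Pa.

    For an incompressible Mooney-Rivlin solid the generalized shear modulus
    for shearing in the plane containing the stretch axis is
    ``2*(C1 + C2/(lam_axial**2 * lam_transverse**2)) = 2*(C1 + C2/lam)``
    under uniaxial kinematics; at lam = 1 this is the ground-state modulus
    ``2*(C1 + C2)``.  Fibers are taken not to contribute to transverse shear
    resistance.
    """
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 1.0):
        raise ValueError("tangent shear modulus defined for lam >= 1")
    out = 2.0 * (params.c1 + params.c2 / lam_arr)
    return float(out) if out.ndim == 0 else out


def predicted_speed_vs_strain(params: MaterialParams, beam: BeamSpec,
                              strains=None) -> pd.DataFrame:
    """Predicted wave speed across axial strain (default grid 0-10%).

    Composes the uniaxial stress response and the tangent shear modulus with
    the tensioned-beam wave-speed relation.  Returns a DataFrame with columns
    ``strain``, ``stress_pa``, ``mu_t_pa``, ``speed_mps``.
    """
    if strains is None:
        strains = np.linspace(0.0, 0.10, 101)
    strains = np.asarray(strains, dtype=float)
    if np.any(strains < 0) or np.any(strains > 0.10):
        raise ValueError("strain grid must lie within [0, 0.10]")
    lam = 1.0 + strains
    sigma = cauchy_stress_uniaxial(lam, params)
    mu_t = tangent_shear_modulus(lam, params)
    speeds = np.array([
        wave_speed(BeamSpec(rho_eff=beam.rho_eff, mu=float(m),
                            k_shear=beam.k_shear, area=beam.area,
                            length=beam.length), float(s))
        for m, s in zip(np.atleast_1d(mu_t), np.atleast_1d(sigma))
    ])
    return pd.DataFrame({
        "strain": strains,
        "stress_pa": np.atleast_1d(sigma),
        "mu_t_pa": np.atleast_1d(mu_t),
        "speed_mps": speeds,
    })
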