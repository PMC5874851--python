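"""Multiple-Coulomb-scattering widths and Fermi-Eyges slab moment integrals.

The Gaussian-core width of multiple Coulomb scattering is taken from the
Highland parameterization,

    theta = (14.1 MeV / pv) * sqrt(L / L_R) * (1 + (1/9) log10(L / L_R)),

with the Lynch-Dahl refit (13.6 MeV, 0.038 ln) available as an
alternative.  For a thick slab the angular, covariance and position
moment increments follow from Fermi-Eyges theory by integrating the
scattering power over depth with lever arms to a downstream reference
plane.  Following Gottschalk's procedure, the logarithmic thickness
correction is never applied per depth step; it can optionally be applied
once, on the full slab thickness, as a constant prefactor.  The default
leaves it off, the convention used by the analytical reference this
package benchmarks against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson

from .exceptions import StoppedBeamError
from .kinematics import (
    RangeShifterSetup,
    energy_at_depth,
    kinematic_factor,
    range_of_energy,
)

__all__ = [
    "ScatteringMoments",
    "highland_sigma",
    "lynch_dahl_sigma",
    "rs_fermi_eyges_moments",
]

_HIGHLAND_MEV = 14.1
_LYNCH_DAHL_MEV = 13.6


@dataclass(frozen=True)
class ScatteringMoments:
    """Additive Fermi-Eyges moment increments produced by a scatterer.

    ``delta_A`` (cm^2), ``delta_B`` (cm rad) and ``delta_C`` (rad^2) are the
    increments to the position variance, position-angle covariance and
    angular variance at a chosen reference plane.  They satisfy the
    Cauchy-Schwarz relation delta_B**2 <= delta_A * delta_C because all
    three arise from the same nonnegative measure over depth.
    """

    delta_A: float
    delta_B: float
    delta_C: float

    def __post_init__(self) -> None:
        if self.delta_A < 0 or self.delta_C < 0:
            raise ValueError("moment increments must be nonnegative")
        limit = self.delta_A * self.delta_C
        if self.delta_B**2 > limit * (1.0 + 1e-9) + 1e-300:
            raise ValueError(
                f"delta_B^2 = {self.delta_B**2:.3e} exceeds delta_A*delta_C = {limit:.3e}"
            )

    @classmethod
    def zero(cls) -> "ScatteringMoments":
        return cls(0.0, 0.0, 0.0)

    def scaled(self, factor: float) -> "ScatteringMoments":
        return ScatteringMoments(factor * self.delta_A, factor * self.delta_B,
                                 factor * self.delta_C)


def highland_sigma(pv: float, mass_thickness: float, radiation_length_mass: float,
                   log_correction: bool = True) -> float:
    """Highland multiple-scattering angle (rad) for a slab of given mass thickness.

    ``mass_thickness`` and ``radiation_length_mass`` in g/cm^2; ``pv`` in MeV.
    A zero-thickness slab scatters nothing.  With ``log_correction`` off the
    (1 + (1/9) log10(L/L_R)) factor is omitted.
    """
    if pv <= 0:
        raise ValueError("pv must be positive")
    if mass_thickness < 0:
        raise ValueError("mass thickness must be nonnegative")
    if mass_thickness == 0.0:
        return 0.0
    ratio = mass_thickness / radiation_length_mass
    theta = _HIGHLAND_MEV / pv * np.sqrt(ratio)
    if log_correction:
        theta *= 1.0 + np.log10(ratio) / 9.0
    return float(theta)


def lynch_dahl_sigma(pv: float, x_over_x0: float) -> float:
    """Lynch-Dahl Gaussian-core scattering angle (rad).

    theta0 = (13.6 MeV / pv) * sqrt(x/X0) * (1 + 0.038 ln(x/X0)); a refit of
    the Moliere core that is accurate for 1e-3 < x/X0 < 100.
    """
    if pv <= 0:
        raise ValueError("pv must be positive")
    if x_over_x0 <= 0:
        raise ValueError("x/X0 must be positive")
    return float(_LYNCH_DAHL_MEV / pv * np.sqrt(x_over_x0)
                 * (1.0 + 0.038 * np.log(x_over_x0)))


def rs_fermi_eyges_moments(energy_in: float, rs: RangeShifterSetup, S: float,
                           log_correction: bool = False,
                           n_points: int = 257) -> ScatteringMoments:
    """Fermi-Eyges moment increments of a range-shifter slab.

    Integrates the Highland scattering power over the slab depth z' with
    lever arms (S + t - z') to a reference plane a distance ``S`` (cm of
    air) downstream of the slab's exit face:

        delta_A = f^2 (14.1)^2 \\int_0^t (S + t - z')^2 (rho/L_R) / pv(z')^2 dz'

    and correspondingly with first and zeroth powers of the lever arm for
    ``delta_B`` and ``delta_C``.  ``pv(z')`` follows from the material's
    range-energy law; f is the optional full-slab Highland log factor
    (default off).  Composite-Simpson quadrature on ``n_points`` nodes; the
    integrand is smooth because the beam is required to exit the slab.
    """
    if S < 0:
        raise ValueError("air gap S must be nonnegative")
    t = rs.physical_thickness
    mat = rs.material
    if range_of_energy(energy_in, mat) <= t:
        raise StoppedBeamError(
            f"{energy_in} MeV beam stops inside the {t} cm {mat.name} slab"
        )
    if t == 0.0:
        return ScatteringMoments.zero()

    z = np.linspace(0.0, t, n_points)
    pv = kinematic_factor(energy_at_depth(energy_in, z, mat))
    power = (_HIGHLAND_MEV / pv) ** 2 * (mat.density / mat.radiation_length_mass)
    if log_correction:
        ratio = t * mat.density / mat.radiation_length_mass
        power *= (1.0 + np.log10(ratio) / 9.0) ** 2
    lever = S + t - z
    delta_C = simpson(power, x=z)
    delta_B = simpson(power * lever, x=z)
    delta_A = simpson(power * lever**2, x=z)
    return ScatteringMoments(delta_A, delta_B, delta_C)
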