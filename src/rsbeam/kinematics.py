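"""Proton kinematics, range-energy relations and beam-line geometry.

Energies are kinetic energies in MeV, lengths in cm, mass thicknesses in
g/cm**2.  Longitudinal positions follow the treatment-room convention used
throughout the package: centimetres from isocenter, positive toward the
nozzle, so the beam travels in the direction of *decreasing* position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.integrate import cumulative_trapezoid

from .exceptions import GeometryError, StoppedBeamError

__all__ = [
    "PROTON_MASS_MEV",
    "Material",
    "RangeShifterSetup",
    "SnoutConvention",
    "beta_of_energy",
    "bethe_stopping_power",
    "csda_range_bethe",
    "energy_at_depth",
    "energy_of_beta",
    "get_material",
    "kinematic_factor",
    "load_materials",
    "range_of_energy",
    "snout_to_rs",
    "water_equivalent_thickness",
]

#: Proton rest energy in MeV.
PROTON_MASS_MEV = 938.272

_ELECTRON_MASS_MEV = 0.51099895
_BETHE_K = 0.307075  # MeV cm^2 / g  (4 pi N_A r_e^2 m_e c^2)


def kinematic_factor(energy: float, rest_mass: float = PROTON_MASS_MEV):
    """Kinematic factor pv = E(E + 2E0)/(E + E0), the product of momentum and velocity.

    Strictly increasing in the kinetic energy ``energy``; vanishes only at
    E = 0.  Accepts scalars or arrays.
    """
    E = np.asarray(energy, dtype=float)
    if np.any(E < 0):
        raise ValueError("kinetic energy must be nonnegative")
    pv = E * (E + 2.0 * rest_mass) / (E + rest_mass)
    return float(pv) if np.isscalar(energy) else pv


def beta_of_energy(energy: float, rest_mass: float = PROTON_MASS_MEV):
    """Speed relative to c: beta = sqrt(1 - (E0/(E + E0))**2)."""
    E = np.asarray(energy, dtype=float)
    if np.any(E < 0):
        raise ValueError("kinetic energy must be nonnegative")
    gamma = 1.0 + E / rest_mass
    beta = np.sqrt(1.0 - 1.0 / gamma**2)
    return float(beta) if np.isscalar(energy) else beta


def energy_of_beta(beta: float, rest_mass: float = PROTON_MASS_MEV) -> float:
    """Kinetic energy for a given beta (inverse of :func:`beta_of_energy`)."""
    if not 0.0 <= beta < 1.0:
        raise ValueError("beta must lie in [0, 1)")
    gamma = 1.0 / math.sqrt(1.0 - beta * beta)
    return rest_mass * (gamma - 1.0)


@dataclass(frozen=True)
class Material:
    """Stopping and scattering description of a slab medium.

    ``range_coeff_alpha`` and ``range_exponent_p`` define the Bragg-Kleeman
    range-energy power law R = alpha * E**p (R in cm).  ``z_over_a`` and
    ``mean_excitation_ev`` document the Bethe-theory inputs the power law
    was fitted against and allow an independent quadrature cross-check.
    """

    name: str
    density: float                 # g/cm^3
    radiation_length_mass: float   # g/cm^2
    range_coeff_alpha: float       # cm/MeV^p
    range_exponent_p: float
    z_over_a: float | None = None
    mean_excitation_ev: float | None = None

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.radiation_length_mass <= 0:
            raise ValueError("radiation_length_mass must be positive")
        if not 1.0 < self.range_exponent_p < 2.5:
            raise ValueError("range_exponent_p outside the plausible (1, 2.5) band")

    @property
    def radiation_length_cm(self) -> float:
        return self.radiation_length_mass / self.density


def load_materials(path: str | Path | None = None) -> dict[str, Material]:
    """Load a material registry from YAML (the packaged registry by default)."""
    if path is None:
        text = resources.files("rsbeam.data").joinpath("materials.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {key: Material(**entry) for key, entry in raw.items()}


_REGISTRY: dict[str, Material] | None = None


def get_material(name: str) -> Material:
    """Look up a material in the packaged registry."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = load_materials()
    try:
        return _REGISTRY[name.lower()]
    except KeyError:
        raise KeyError(f"unknown material {name!r}; registry has {sorted(_REGISTRY)}") from None


def range_of_energy(energy, material: Material):
    """Bragg-Kleeman range in cm: R = alpha * E**p."""
    E = np.asarray(energy, dtype=float)
    if np.any(E < 0):
        raise ValueError("kinetic energy must be nonnegative")
    R = material.range_coeff_alpha * E**material.range_exponent_p
    return float(R) if np.isscalar(energy) else R


def energy_at_depth(energy_in: float, depth, material: Material):
    """Kinetic energy after traversing ``depth`` cm of ``material``.

    Obtained by inverting the power law on the residual range,
    E_out = ((R(E_in) - depth)/alpha)**(1/p).  Raises
    :class:`StoppedBeamError` when the depth exceeds the range (the beam
    does not exit the slab).
    """
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be nonnegative")
    R = range_of_energy(energy_in, material)
    residual = R - d
    if np.any(residual < -1e-12 * max(R, 1.0)):
        raise StoppedBeamError(
            f"beam of {energy_in} MeV (range {R:.3f} cm in {material.name}) "
            f"stops before depth {np.max(d):.3f} cm"
        )
    residual = np.maximum(residual, 0.0)
    E = (residual / material.range_coeff_alpha) ** (1.0 / material.range_exponent_p)
    return float(E) if np.isscalar(depth) else E


def bethe_stopping_power(energy, z_over_a: float, mean_excitation_ev: float):
    """Mass stopping power (MeV cm^2/g) from the uncorrected Bethe formula.

    Serves as the provenance of, and an independent check on, the fitted
    range power law; valid for protons above a few MeV.
    """
    E = np.asarray(energy, dtype=float)
    gamma = 1.0 + E / PROTON_MASS_MEV
    beta2 = 1.0 - 1.0 / gamma**2
    I = mean_excitation_ev * 1e-6
    S = _BETHE_K * z_over_a / beta2 * (
        np.log(2.0 * _ELECTRON_MASS_MEV * beta2 * gamma**2 / (I * (1.0 - beta2))) - beta2
    )
    return float(S) if np.isscalar(energy) else S


def csda_range_bethe(energy: float, material: Material, e_min: float = 0.5,
                     n_points: int = 20001) -> float:
    """Continuous-slowing-down range in cm by quadrature of 1/S(E).

    Independent of the power-law path through :func:`range_of_energy`; the
    sub-``e_min`` contribution (< 2e-4 g/cm^2) is neglected.
    """
    if material.z_over_a is None or material.mean_excitation_ev is None:
        raise ValueError(f"material {material.name!r} carries no Bethe parameters")
    grid = np.linspace(e_min, energy, n_points)
    S = bethe_stopping_power(grid, material.z_over_a, material.mean_excitation_ev)
    R_mass = cumulative_trapezoid(1.0 / S, grid, initial=0.0)[-1]
    return R_mass / material.density


def water_equivalent_thickness(energy_in: float, material: Material,
                               physical_thickness: float,
                               water: Material | None = None) -> float:
    """Water-equivalent thickness of a slab at a given beam energy.

    Computed from range differences: WET = R_w(E_in) - R_w(E_out) where
    E_out is the exit energy from the physical slab.
    """
    if water is None:
        water = get_material("water")
    e_out = energy_at_depth(energy_in, physical_thickness, material)
    return range_of_energy(energy_in, water) - range_of_energy(e_out, water)


class SnoutConvention(str, Enum):
    """Vendor conventions relating the reported snout position to the RS.

    * ``eclipse_downstream_face`` - the snout position *is* the downstream
      face of the range shifter (DICOM ion-therapy default).
    * ``iba_upstream_face`` - the RS is mounted with its upstream surface
      at the snout position (aperture-holder mount).
    * ``hitachi_snout_face`` - the RS extends downstream of the reported
      snout face by its physical thickness.
    """

    ECLIPSE_DOWNSTREAM_FACE = "eclipse_downstream_face"
    IBA_UPSTREAM_FACE = "iba_upstream_face"
    HITACHI_SNOUT_FACE = "hitachi_snout_face"


def snout_to_rs(snout_position: float, physical_thickness: float,
                convention: SnoutConvention | str) -> float:
    """Translate a reported snout position into the RS downstream-face position.

    Mirrors the translation table a treatment planning system needs when
    the delivery-system vendor and the TPS disagree on what "RS position"
    means.  Affine in the snout position with slope one for every
    convention.
    """
    if snout_position <= 0:
        raise GeometryError("snout position must be downstream-positive and nonzero")
    conv = SnoutConvention(convention)
    if conv is SnoutConvention.ECLIPSE_DOWNSTREAM_FACE:
        face = snout_position
    else:
        # IBA: upstream RS surface at the snout position.
        # Hitachi: RS extends one physical thickness downstream of the snout face.
        face = snout_position - physical_thickness
    if face <= 0:
        raise GeometryError(
            f"range shifter downstream face at {face:.2f} cm would cross isocenter"
        )
    return face


@dataclass
class RangeShifterSetup:
    """A range-shifter slab and its position in the beam line.

    ``downstream_face_position`` is in cm from isocenter (positive toward
    the nozzle).  ``wet`` is the water-equivalent thickness; when omitted
    it is computed from range ratios at ``wet_reference_energy``.
    """

    material: Material
    physical_thickness: float          # cm
    downstream_face_position: float    # cm from isocenter
    wet: float | None = None           # cm of water
    position_convention: SnoutConvention = SnoutConvention.ECLIPSE_DOWNSTREAM_FACE
    wet_reference_energy: float = field(default=160.0, repr=False)

    def __post_init__(self) -> None:
        if self.physical_thickness <= 0:
            raise ValueError("physical_thickness must be positive")
        if self.downstream_face_position <= 0:
            raise GeometryError("range shifter must sit upstream of isocenter")
        if self.wet is None:
            self.wet = water_equivalent_thickness(
                self.wet_reference_energy, self.material, self.physical_thickness
            )
        if self.wet <= 0:
            raise ValueError("wet must be positive")

    @property
    def upstream_face_position(self) -> float:
        return self.downstream_face_position + self.physical_thickness

    def with_face_at(self, downstream_face_position: float) -> "RangeShifterSetup":
        """Copy of this setup moved to a new downstream-face position."""
        return RangeShifterSetup(
            material=self.material,
            physical_thickness=self.physical_thickness,
            downstream_face_position=downstream_face_position,
            wet=self.wet,
            position_convention=self.position_convention,
        )
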