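"""Fermi-Eyges phase-space representation and transport for one transverse axis.

A Gaussian pencil beam is fully specified per axis by the second moments
(A, B, C): position variance (cm^2), position-angle covariance (cm rad)
and angular variance (rad^2) at a reference plane.  Under a free drift of
length dz along the beam,

    A' = C dz^2 + 2 B dz + A,    B' = C dz + B,    C' = C,

which conserves the emittance-like determinant A C - B^2.  Scattering in
a slab adds the :class:`~rsbeam.scattering.ScatteringMoments` increments
evaluated at the same reference plane.

Positions are cm from isocenter, positive toward the nozzle; the beam
propagates toward decreasing position, so the drift distance from the
reference plane to a plane z is ``z_ref - z``.

Two bookkeeping conventions for A are supported: ``variance`` stores
sigma^2 directly, while the cylindrically-symmetric convention used by
some planning systems stores A = 2 sigma^2 (and scales B and C alike).
All cross-convention comparisons should go through :func:`sigma_at`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .exceptions import NonPhysicalPhaseSpaceError
from .scattering import ScatteringMoments

__all__ = [
    "PhaseSpace",
    "SigmaConvention",
    "emittance",
    "free_drift",
    "sigma_at",
    "transport_with_scattering",
]


class SigmaConvention(str, Enum):
    """Relation between the stored A parameter and the spot variance."""

    VARIANCE = "variance"                    # sigma^2 = A
    ECLIPSE_CYLINDRICAL = "eclipse_cylindrical"  # A = 2 sigma^2

    @property
    def factor(self) -> float:
        return 2.0 if self is SigmaConvention.ECLIPSE_CYLINDRICAL else 1.0


@dataclass(frozen=True)
class PhaseSpace:
    """Second moments of one transverse axis at a reference plane."""

    A: float                    # cm^2 (times convention factor)
    B: float                    # cm rad
    C: float                    # rad^2
    z_ref: float = 0.0          # cm from isocenter
    axis: str = "x"
    convention: SigmaConvention = SigmaConvention.VARIANCE

    def __post_init__(self) -> None:
        if self.A < 0 or self.C < 0:
            raise NonPhysicalPhaseSpaceError(
                f"negative variance moment: A={self.A}, C={self.C}"
            )
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")

    # -- convenience -------------------------------------------------------
    @property
    def emittance(self) -> float:
        return self.A * self.C - self.B**2

    @property
    def sigma(self) -> float:
        """Spot sigma (cm) at the reference plane."""
        return math.sqrt(self.A / self.convention.factor)

    @property
    def covariance(self) -> np.ndarray:
        """Physical (x, theta) covariance matrix, convention factor removed."""
        f = self.convention.factor
        return np.array([[self.A, self.B], [self.B, self.C]]) / f

    def waist(self) -> tuple[float, float]:
        """(position cm from isocenter, sigma cm) of the beam waist.

        The waist sits a drift distance -B/C downstream of the reference
        plane, where sigma^2 = (A C - B^2) / (C * factor).
        """
        if self.C <= 0:
            raise ValueError("a beam with zero angular variance has no waist")
        d = -self.B / self.C
        var = self.emittance / self.C / self.convention.factor
        return self.z_ref - d, math.sqrt(var)


def free_drift(ps: PhaseSpace, dz: float) -> PhaseSpace:
    """Drift ``dz`` cm along the beam direction (negative dz back-projects).

    Exactly conserves A C - B^2.  Raises
    :class:`NonPhysicalPhaseSpaceError` if the drifted position variance
    would be negative (possible only for a nonphysical determinant).
    """
    A = ps.C * dz * dz + 2.0 * ps.B * dz + ps.A
    if A < 0:
        raise NonPhysicalPhaseSpaceError(
            f"drift by {dz} cm gives A = {A:.3e} < 0 "
            f"(determinant {ps.emittance:.3e})"
        )
    return replace(ps, A=A, B=ps.C * dz + ps.B, z_ref=ps.z_ref - dz)


def transport_with_scattering(ps: PhaseSpace, moments: ScatteringMoments,
                              dz_drift_after: float = 0.0) -> PhaseSpace:
    """Add slab scattering moments (evaluated at ``ps.z_ref``) and then drift.

    The moment increments are physical variances; under the cylindrical
    convention they are doubled before being added, so that the spot sigma
    is convention independent.  With zero moments this reduces exactly to
    :func:`free_drift`.
    """
    f = ps.convention.factor
    out = replace(
        ps,
        A=ps.A + f * moments.delta_A,
        B=ps.B + f * moments.delta_B,
        C=ps.C + f * moments.delta_C,
    )
    if dz_drift_after != 0.0:
        out = free_drift(out, dz_drift_after)
    return out


def sigma_at(ps: PhaseSpace, z) -> float | np.ndarray:
    """Spot sigma (cm) at plane position ``z`` (cm from isocenter).

    Evaluates the drifted position variance at propagation distance
    ``z_ref - z`` and converts through the sigma convention.
    """
    d = ps.z_ref - np.asarray(z, dtype=float)
    var = (ps.C * d * d + 2.0 * ps.B * d + ps.A) / ps.convention.factor
    if np.any(var < 0):
        raise NonPhysicalPhaseSpaceError(
            f"negative variance at z={z} (determinant {ps.emittance:.3e})"
        )
    out = np.sqrt(var)
    return float(out) if np.isscalar(z) else out


def emittance(ps: PhaseSpace) -> float:
    """Covariance determinant A C - B^2 (invariant under free drift)."""
    return ps.emittance
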