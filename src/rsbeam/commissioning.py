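"""TPS-side range-shifter modelling: constrained phase-space fits and the V-parameter model.

The planning-system model evaluated here does not use the nominal slab
properties (density, radiation length).  Instead it folds the material's
scattering behaviour into a single energy-independent constant V (MeV),
determined during commissioning from paired spot measurements with and
without the range shifter.  The moment increments are closed-form
combinations of three nested beta integrals ("five-thirds approximation"
of the stopping power),

    phi(b) = int_{bc}^{b} db' / (b'^{4/3} (1 - b'^2)^{4/3})
    chi(b) = int_{bc}^{b} phi(b') b'^{8/3} / (1 - b'^2)^{3/2} db'
    psi(b) = int_{bc}^{b} chi(b') b'^{8/3} / (1 - b'^2)^{3/2} db'

evaluated at the slab entrance and exit speeds, with lever arms built
from the water-equivalent thickness L and the air gap S to the reference
plane:

    dA = V/(a^3 E0) { a^2 [(S+L)^2 phi_i - S^2 phi_o]
                      - 2 a E0 [(S+L) chi_i - S chi_o]
                      + 2 E0^2 (psi_i - psi_o) }
    dB = V/(a^2 E0) { a [(S+L) phi_i - S phi_o] - E0 (chi_i - chi_o) }
    dC = V/(a  E0) (phi_i - phi_o)

where a is the material factor of the five-thirds approximation and E0
the proton rest energy.

The chi/psi weight b^{8/3} (1-b^2)^{-3/2} is the derivative of the
model's residual-range relation: with dr/dbeta = (E0/a) b^{8/3}
(1-b^2)^{-3/2} the stopping power is proportional to beta^{-5/3} (the
five-thirds power law) and the closed forms above are exactly the
Fermi-Eyges lever-arm integrals after the depth -> beta change of
variables.  The exit speed beta_o is accordingly obtained from the
model's own range relation, G(beta_i) - G(beta_o) = a L / E0 with
G' the chi/psi weight, which keeps the lever arms self-consistent at
every energy.  The lower cutoff bc only regularizes the phi singularity
at beta = 0 and cancels exactly from all entrance-exit differences.

This module also emulates, explicitly and opt-in, two defective
behaviours observed in a commercial implementation (parameter clamping
for small spots, and discarding the RS correction after an unphysical
upstream envelope comparison), so that the comparison pipeline can
detect them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq, least_squares, minimize

from .exceptions import DegenerateDataError, StoppedBeamError
from .kinematics import (
    PROTON_MASS_MEV,
    Material,
    beta_of_energy,
    energy_at_depth,
    get_material,
)
from .phase_space import PhaseSpace, SigmaConvention, sigma_at, transport_with_scattering
from .scattering import ScatteringMoments

__all__ = [
    "DEFAULT_BETA_CUT",
    "EnvelopeCheck",
    "FitResult",
    "VEstimates",
    "VModel",
    "calibrate_alpha53",
    "check_rs_correction_validity",
    "emulate_parameter_clamp",
    "extract_v",
    "fit_phase_space",
    "five_thirds_integrals",
    "predict_with_rs",
    "vmodel_deltas",
]

#: Default integration cutoff, well below the speed of any clinical proton.
DEFAULT_BETA_CUT = 0.05


# ----------------------------------------------------------------------
# five-thirds beta integrals
# ----------------------------------------------------------------------

def _phi_weight(b: np.ndarray) -> np.ndarray:
    return b ** (-4.0 / 3.0) * (1.0 - b * b) ** (-4.0 / 3.0)


def _chi_weight(b: np.ndarray) -> np.ndarray:
    return b ** (8.0 / 3.0) * (1.0 - b * b) ** (-1.5)


def five_thirds_integrals(beta, beta_cut: float = DEFAULT_BETA_CUT):
    """Evaluate (phi, chi, psi) at one or several speeds ``beta``.

    The three nested integrals are solved together as an initial-value
    problem in beta (high-order explicit Runge-Kutta, rtol 1e-11), which
    evaluates the inner integrals exactly once regardless of nesting.
    All three vanish at ``beta == beta_cut`` and increase monotonically.
    """
    b = np.atleast_1d(np.asarray(beta, dtype=float))
    if not 0.0 < beta_cut < 1.0:
        raise ValueError("beta_cut must lie in (0, 1)")
    if np.any(b >= 1.0) or np.any(b < beta_cut):
        raise ValueError(f"beta must lie in [beta_cut={beta_cut}, 1)")

    order = np.argsort(b)
    targets = b[order]

    def rhs(t, y):
        w = _chi_weight(np.array(t))
        return [_phi_weight(np.array(t)), y[0] * w, y[1] * w]

    b_max = targets[-1]
    if b_max == beta_cut:
        vals = np.zeros((3, b.size))
    else:
        t_eval = np.unique(targets)
        sol = solve_ivp(rhs, (beta_cut, b_max), [0.0, 0.0, 0.0], t_eval=t_eval,
                        method="DOP853", rtol=1e-11, atol=1e-14)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"five-thirds integration failed: {sol.message}")
        lookup = {t: sol.y[:, i] for i, t in enumerate(sol.t)}
        vals = np.empty((3, b.size))
        for i, t in zip(order, targets):
            vals[:, i] = lookup[t]
    if np.isscalar(beta):
        return float(vals[0, 0]), float(vals[1, 0]), float(vals[2, 0])
    return vals[0], vals[1], vals[2]


def _beta_range_integral(beta: float, beta_cut: float) -> float:
    """G(beta) = int_{bc}^{beta} b'^{8/3} / (1-b'^2)^{3/2} db'.

    The model's implied residual range is r(beta) = (E0/alpha) G(beta), so
    differences of G fix the depth <-> beta change of variables.
    """
    val, _ = quad(_chi_weight, beta_cut, beta, epsabs=1e-13, epsrel=1e-12)
    return val


def _exit_beta(beta_in: float, l_wet: float, alpha: float, beta_cut: float) -> float:
    """Exit speed after ``l_wet`` cm of water per the model's range relation."""
    target = _beta_range_integral(beta_in, beta_cut) - alpha * l_wet / PROTON_MASS_MEV
    if target <= 0.0:
        raise StoppedBeamError(
            f"model range relation: beam entering at beta={beta_in:.3f} does not "
            f"exit {l_wet:.2f} cm water-equivalent (or exits below the cutoff)"
        )
    return brentq(lambda b: _beta_range_integral(b, beta_cut) - target,
                  beta_cut * (1.0 + 1e-12), beta_in, xtol=1e-13, rtol=1e-14)


def calibrate_alpha53(l_wet: float, reference_energy: float = 160.0,
                      beta_cut: float = DEFAULT_BETA_CUT,
                      water: Material | None = None) -> float:
    """Material factor alpha making the beta integrals consistent with the range law.

    Chosen so that the model's residual-range difference across the slab,
    (E0/alpha) [G(beta_in) - G(beta_out)], equals the water-equivalent
    thickness ``l_wet`` at the reference energy.  The commissioning fit of
    V absorbs the (small) residual energy dependence.
    """
    if water is None:
        water = get_material("water")
    beta_in = beta_of_energy(reference_energy)
    e_out = energy_at_depth(reference_energy, l_wet, water)
    beta_out = beta_of_energy(e_out)
    dG = _beta_range_integral(beta_in, beta_cut) - _beta_range_integral(beta_out, beta_cut)
    return PROTON_MASS_MEV * dG / l_wet


# ----------------------------------------------------------------------
# the V model
# ----------------------------------------------------------------------

@dataclass
class VModel:
    """Commissioned V-parameter model of one range-shifter slab.

    ``v`` is the scattering constant (MeV); ``l_wet`` the slab
    water-equivalent thickness (cm) and ``s_reference`` the air gap (cm)
    between the slab exit face and the commissioning reference plane.
    ``alpha_53`` is auto-calibrated from the range law when omitted.  The
    optional Lynch-Dahl multiplicative correction rescales V by the
    squared ratio of the Lynch-Dahl to the log-free Highland width for
    the full slab; because extraction and prediction share the factor it
    cancels in round trips and matters only across slab thicknesses.
    """

    v: float
    l_wet: float
    s_reference: float
    alpha_53: float | None = None
    beta_cut: float = DEFAULT_BETA_CUT
    lynch_dahl_correction: bool = False

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("V must be nonnegative")
        if self.l_wet <= 0:
            raise ValueError("l_wet must be positive")
        if self.alpha_53 is None:
            self.alpha_53 = calibrate_alpha53(self.l_wet, beta_cut=self.beta_cut)

    def lynch_dahl_factor(self) -> float:
        if not self.lynch_dahl_correction:
            return 1.0
        water = get_material("water")
        ratio = self.l_wet * water.density / water.radiation_length_mass
        return (13.6 / 14.1) ** 2 * (1.0 + 0.038 * math.log(ratio)) ** 2


def vmodel_deltas(vm: VModel, energy: float, l_wet: float | None = None,
                  S: float | None = None) -> ScatteringMoments:
    """Phase-space increments predicted by the V model for one slab pass.

    ``l_wet`` and ``S`` default to the commissioning geometry.  The exit
    speed follows from the model's own five-thirds range relation (see
    the module docstring), which keeps the closed forms self-consistent.
    Raises :class:`StoppedBeamError` when the beam does not exit.
    """
    L = vm.l_wet if l_wet is None else l_wet
    S = vm.s_reference if S is None else S
    if L < 0 or S < 0:
        raise ValueError("L and S must be nonnegative")
    if L == 0.0 or vm.v == 0.0:
        return ScatteringMoments.zero()
    beta_i = beta_of_energy(energy)
    beta_o = _exit_beta(beta_i, L, vm.alpha_53, vm.beta_cut)
    phi_i, chi_i, psi_i = five_thirds_integrals(beta_i, vm.beta_cut)
    phi_o, chi_o, psi_o = five_thirds_integrals(beta_o, vm.beta_cut)

    a = vm.alpha_53
    E0 = PROTON_MASS_MEV
    v_eff = vm.v * vm.lynch_dahl_factor()
    dA = v_eff / (a**3 * E0) * (
        a**2 * ((S + L) ** 2 * phi_i - S**2 * phi_o)
        - 2.0 * a * E0 * ((S + L) * chi_i - S * chi_o)
        + 2.0 * E0**2 * (psi_i - psi_o)
    )
    dB = v_eff / (a**2 * E0) * (
        a * ((S + L) * phi_i - S * phi_o) - E0 * (chi_i - chi_o)
    )
    dC = v_eff / (a * E0) * (phi_i - phi_o)
    return ScatteringMoments(dA, dB, dC)


@dataclass(frozen=True)
class VEstimates:
    """Per-equation V estimates (MeV) from one with/without measurement pair."""

    v_a: float
    v_b: float
    v_c: float
    energy: float

    @property
    def mean(self) -> float:
        return (self.v_a + self.v_b + self.v_c) / 3.0

    @property
    def spread(self) -> float:
        """Relative spread (max - min)/mean across the three equations."""
        vals = (self.v_a, self.v_b, self.v_c)
        m = self.mean
        return (max(vals) - min(vals)) / m if m != 0.0 else 0.0

    def as_dict(self) -> dict:
        return {"v_a": self.v_a, "v_b": self.v_b, "v_c": self.v_c,
                "mean": self.mean, "spread": self.spread, "energy": self.energy}


def extract_v(ps_open: PhaseSpace, ps_rs: PhaseSpace, vm_template: VModel,
              energy: float) -> VEstimates:
    """Solve each of the three (linear in V) model equations for V.

    ``ps_open`` and ``ps_rs`` must share the reference plane and sigma
    convention; their componentwise difference gives the measured
    (dA, dB, dC).  Identical phase spaces yield V = 0 from all equations.
    """
    if ps_open.z_ref != ps_rs.z_ref:
        raise ValueError("phase spaces must share the reference plane")
    if ps_open.convention is not ps_rs.convention:
        raise ValueError("phase spaces must share the sigma convention")
    f = ps_open.convention.factor
    dA = (ps_rs.A - ps_open.A) / f
    dB = (ps_rs.B - ps_open.B) / f
    dC = (ps_rs.C - ps_open.C) / f

    unit = vmodel_deltas(replace(vm_template, v=1.0), energy)
    for name, denom in (("A", unit.delta_A), ("B", unit.delta_B), ("C", unit.delta_C)):
        if denom == 0.0:
            raise ZeroDivisionError(
                f"equation {name}: bracketed integral combination vanishes "
                f"(E={energy} MeV, L={vm_template.l_wet}, S={vm_template.s_reference})"
            )
    # the unit deltas already carry the optional Lynch-Dahl factor, so the
    # solved V is directly the model parameter and round-trips exactly
    return VEstimates(v_a=dA / unit.delta_A, v_b=dB / unit.delta_B,
                      v_c=dC / unit.delta_C, energy=energy)


def predict_with_rs(ps_open: PhaseSpace, vm: VModel, energy: float,
                    l_wet: float | None = None, S: float | None = None) -> PhaseSpace:
    """Open-beam phase space plus the V-model increments for a slab at gap ``S``.

    At the commissioning geometry this reproduces the commissioning
    with-RS phase space exactly (round trip).  Moving the slab toward the
    reference plane (smaller S) shrinks the lever arms and hence the
    predicted spot.  A zero-thickness slab leaves the beam unchanged.
    """
    if l_wet == 0.0:
        return ps_open
    return transport_with_scattering(ps_open, vmodel_deltas(vm, energy, l_wet, S))


# ----------------------------------------------------------------------
# constrained phase-space fitting
# ----------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a constrained quadratic phase-space fit."""

    phase_space: PhaseSpace
    residuals: np.ndarray          # fitted minus measured sigma, cm, per plane
    determinant: float             # A C - B^2 of the fitted parameters
    constraint_active: bool        # unconstrained optimum had determinant < 0
    warnings: list = field(default_factory=list)


def fit_phase_space(z, sigma, convention: SigmaConvention = SigmaConvention.VARIANCE,
                    enforce_constraint: bool = True, axis: str = "x",
                    weights=None) -> FitResult:
    """Fit (A, B, C) at isocenter to spot sigmas measured at several planes.

    ``z`` are plane positions in cm from isocenter, ``sigma`` the spot
    sigmas in cm.  The model is the free-drift quadratic in the
    propagation distance d = -z:

        factor * sigma^2(d) = C d^2 + 2 B d + A.

    Noise-free quadratic data with at least three distinct planes is
    recovered exactly.  With ``enforce_constraint`` the fit is restricted
    to the physical region A, C >= 0, A C - B^2 >= 0; when the
    unconstrained optimum is unphysical the solution lands on the
    determinant-zero boundary and ``constraint_active`` is set.
    """
    z = np.asarray(z, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if z.shape != sigma.shape or z.ndim != 1:
        raise ValueError("z and sigma must be matching 1-D arrays")
    if z.size < 3:
        raise DegenerateDataError("at least 3 planes are needed to fit (A, B, C)")
    if np.unique(z).size < 3:
        raise DegenerateDataError("need >= 3 distinct plane positions")
    conv = SigmaConvention(convention)
    d = -z
    y = conv.factor * sigma**2
    X = np.column_stack([np.ones_like(d), 2.0 * d, d * d])  # columns: A, B, C
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    Xw = X * w[:, None]
    yw = y * w

    theta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    det_unconstrained = theta[0] * theta[2] - theta[1] ** 2
    warnings: list[str] = []
    active = False

    def objective(t):
        r = Xw @ t - yw
        return 0.5 * r @ r

    def gradient(t):
        return Xw.T @ (Xw @ t - yw)

    physical = theta[0] >= 0 and theta[2] >= 0 and det_unconstrained >= 0
    if enforce_constraint and not physical:
        active = det_unconstrained < 0
        scale = max(abs(theta[0]), 1e-12)
        x0 = np.array([max(theta[0], 1e-8 * scale), theta[1], max(theta[2], 1e-12)])
        clip = math.sqrt(x0[0] * x0[2])
        x0[1] = np.clip(x0[1], -clip, clip) * (1.0 - 1e-9)
        res = minimize(
            objective, x0, jac=gradient, method="SLSQP",
            constraints=[
                {"type": "ineq", "fun": lambda t: t[0]},
                {"type": "ineq", "fun": lambda t: t[2]},
                {"type": "ineq", "fun": lambda t: t[0] * t[2] - t[1] ** 2},
            ],
            options={"maxiter": 500, "ftol": 1e-14},
        )
        theta = res.x
        if not res.success or objective(theta) > objective(_boundary_fit(Xw, yw, x0)):
            theta = _boundary_fit(Xw, yw, x0)
        # snap onto the determinant-zero surface when the constraint binds
        if theta[0] * theta[2] - theta[1] ** 2 < 1e-9 * max(theta[0] * theta[2], 1e-30):
            theta[0] = max(theta[0], 0.0)
            theta[2] = max(theta[2], 0.0)
            theta[1] = math.copysign(math.sqrt(theta[0] * theta[2]), theta[1])
        warnings.append(
            "unconstrained fit is unphysical (determinant "
            f"{det_unconstrained:.3e}); projected onto the boundary"
        )
    elif not physical:
        warnings.append(
            f"fitted phase space is unphysical (determinant {det_unconstrained:.3e}) "
            "and the constraint was not enforced"
        )

    A, B, C = theta
    ps = PhaseSpace(A=max(A, 0.0), B=B, C=max(C, 0.0), z_ref=0.0,
                    axis=axis, convention=conv)
    fitted_var = np.maximum(X @ theta, 0.0) / conv.factor
    residuals = np.sqrt(fitted_var) - sigma
    return FitResult(phase_space=ps, residuals=residuals,
                     determinant=ps.A * ps.C - ps.B**2,
                     constraint_active=active, warnings=warnings)


def _boundary_fit(Xw: np.ndarray, yw: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Best fit on the determinant-zero boundary, parameterized B = s*a*c."""
    best = None
    for s in (+1.0, -1.0):
        def resid(p):
            a, c = p
            return Xw @ np.array([a * a, s * a * c, c * c]) - yw

        start = np.array([math.sqrt(max(x0[0], 1e-12)), math.sqrt(max(x0[2], 1e-14))])
        sol = least_squares(resid, start, method="lm", max_nfev=2000)
        cost = sol.cost
        if best is None or cost < best[0]:
            a, c = sol.x
            best = (cost, np.array([a * a, s * a * c, c * c]))
    return best[1]


# ----------------------------------------------------------------------
# defect emulation
# ----------------------------------------------------------------------

def emulate_parameter_clamp(energies, phase_spaces, sigma_threshold: float = 0.38):
    """Emulate the small-spot parameter clamp of a flawed TPS release.

    For entries (sorted by increasing energy) whose in-air sigma at
    isocenter falls below ``sigma_threshold`` (cm), the (A, B, C)
    parameters are replaced by those of the highest *unaffected* energy
    (constant continuation) and the entry is flagged.  Entries at or
    above the threshold are returned untouched.  A zero threshold is the
    identity.
    """
    energies = list(energies)
    phase_spaces = list(phase_spaces)
    if len(energies) != len(phase_spaces):
        raise ValueError("energies and phase_spaces must have equal length")
    if any(e2 <= e1 for e1, e2 in zip(energies, energies[1:])):
        raise ValueError("table must be sorted by strictly increasing energy")
    sig_iso = [sigma_at(ps, 0.0) for ps in phase_spaces]
    flags = [s < sigma_threshold for s in sig_iso]
    if not any(flags):
        return list(phase_spaces), flags
    unaffected = [i for i, f in enumerate(flags) if not f]
    if not unaffected:
        raise DegenerateDataError("every energy is below the clamp threshold")
    src = phase_spaces[max(unaffected)]
    out = [
        replace(ps, A=src.A, B=src.B, C=src.C) if flag else ps
        for ps, flag in zip(phase_spaces, flags)
    ]
    return out, flags


@dataclass(frozen=True)
class EnvelopeCheck:
    """Result of comparing with-RS and open-beam envelopes over a region."""

    passed: bool
    region: str
    z: np.ndarray                  # cm from isocenter
    margin_cm: np.ndarray          # sigma_RS - sigma_open at each z
    violation_z: np.ndarray        # planes where the margin is negative


def check_rs_correction_validity(ps_open: PhaseSpace, ps_rs_corrected: PhaseSpace,
                                 rs_downstream_face: float,
                                 comparison_region: str = "downstream_only",
                                 z_min: float = -50.0, z_max: float = 50.0,
                                 n_grid: int = 501, tol: float = 1e-9) -> EnvelopeCheck:
    """Check that the RS-corrected envelope is wider than the open one.

    ``downstream_only`` (the physically meaningful test) compares the two
    envelopes only on the patient side of the RS exit face, where
    scattering can only widen the beam.  ``global`` deliberately extends
    the comparison upstream of the RS face, over the full axis, which is
    the flawed comparison that can report sigma_RS < sigma_open for a
    narrow-waist beam and trigger a spurious discard of the correction.
    """
    if ps_open.z_ref != ps_rs_corrected.z_ref:
        raise ValueError("phase spaces must share the reference plane")
    if comparison_region == "downstream_only":
        z = np.linspace(z_min, min(rs_downstream_face, z_max), n_grid)
    elif comparison_region == "global":
        z = np.linspace(z_min, z_max, n_grid)
    else:
        raise ValueError("comparison_region must be 'downstream_only' or 'global'")
    margin = sigma_at(ps_rs_corrected, z) - sigma_at(ps_open, z)
    bad = margin < -tol
    return EnvelopeCheck(passed=not bool(np.any(bad)), region=comparison_region,
                         z=z, margin_cm=margin, violation_z=z[bad])
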