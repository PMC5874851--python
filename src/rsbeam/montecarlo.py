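"""Condensed-history Monte Carlo pencil-beam transport through air and a slab.

An independent desk-scale benchmark for the analytical transport: an
ensemble of protons is sampled from the bivariate Gaussian source defined
by the back-projected phase space, drifted through air, and scattered
through the range-shifter slab in short condensed-history steps.  Each
step draws correlated lateral and angular kicks with the exact
within-step Fermi-Eyges moments

    var(d_theta) = theta_s^2,  cov = theta_s^2 ds / 2,  var(dx) = theta_s^2 ds^2 / 3,

where theta_s is the log-free Highland width for the step's mass
thickness at the step's pv, so convergence is second order in the step
size.  Only the Gaussian core of multiple Coulomb scattering is
modelled: no single-scattering tails, nuclear interactions or
secondaries, matching the assumptions of the analytical reference.

Positions are cm from isocenter, positive toward the nozzle; the beam
travels toward decreasing position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.stats import norm

from .exceptions import DegenerateDataError, NonPhysicalPhaseSpaceError, StoppedBeamError
from .kinematics import RangeShifterSetup, energy_at_depth, kinematic_factor, range_of_energy
from .phase_space import PhaseSpace
from .scattering import highland_sigma

__all__ = [
    "ParticleBundle",
    "ProfileFit",
    "ProfileFit2D",
    "TallyPlane",
    "fit_profile_1d",
    "fit_profile_2d",
    "fit_profiles",
    "sample_source",
    "tally_summary",
    "transport",
]


@dataclass
class ParticleBundle:
    """Monoenergetic ensemble of protons at a common longitudinal plane."""

    x: np.ndarray          # cm
    y: np.ndarray          # cm
    theta_x: np.ndarray    # rad (dx per unit path along the beam)
    theta_y: np.ndarray    # rad
    energy: float          # MeV, common to the ensemble
    z: float               # cm from isocenter
    seed: int

    def __post_init__(self) -> None:
        for arr in (self.x, self.y, self.theta_x, self.theta_y):
            if not np.all(np.isfinite(arr)):
                raise ValueError("particle coordinates must be finite")
        if self.energy < 0:
            raise ValueError("energy must be nonnegative")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass
class TallyPlane:
    """Crossing positions of every proton at one longitudinal plane."""

    position: float          # cm from isocenter
    x: np.ndarray            # cm
    y: np.ndarray            # cm
    bin_width: float = 0.05  # cm, used when histogramming

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")

    @property
    def n(self) -> int:
        return self.x.size

    def histogram(self, axis: str = "x") -> tuple[np.ndarray, np.ndarray]:
        """(counts, bin_edges) for one axis; counts sum to n."""
        data = self.x if axis == "x" else self.y
        lo = math.floor(data.min() / self.bin_width) * self.bin_width
        hi = math.ceil(data.max() / self.bin_width) * self.bin_width
        nbin = max(int(round((hi - lo) / self.bin_width)), 1)
        return np.histogram(data, bins=nbin, range=(lo, lo + nbin * self.bin_width))


def _factor_covariance(cov: np.ndarray) -> np.ndarray:
    """Lower-triangular factor of a PSD 2x2 covariance (zero matrix allowed)."""
    if np.all(cov == 0.0):
        return np.zeros((2, 2))
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(cov)
        if np.any(vals < -1e-12 * max(vals.max(), 1.0)):
            raise NonPhysicalPhaseSpaceError(
                f"covariance not positive semidefinite: eigenvalues {vals}"
            ) from None
        return vecs @ np.diag(np.sqrt(np.maximum(vals, 0.0)))


def sample_source(ps_x: PhaseSpace, ps_y: PhaseSpace, n: int, seed: int,
                  energy: float | None = None) -> ParticleBundle:
    """Draw a proton ensemble from zero-mean bivariate Gaussians per axis.

    Both phase spaces must already be back-projected to the desired source
    plane and share ``z_ref``.  (x, theta_x) and (y, theta_y) are sampled
    independently per axis with covariance [[A, B], [B, C]] (physical
    variances; the convention factor is removed).  A negative determinant
    cannot be factored and raises; a zero phase space yields an ideal
    point source.
    """
    if ps_x.z_ref != ps_y.z_ref:
        raise ValueError("ps_x and ps_y must be defined at the same plane")
    if n < 1:
        raise ValueError("n must be positive")
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)]
    coords = []
    for ps, rng in zip((ps_x, ps_y), streams):
        if ps.emittance < -1e-30:
            raise NonPhysicalPhaseSpaceError(
                f"axis {ps.axis}: determinant {ps.emittance:.3e} < 0, cannot factor"
            )
        L = _factor_covariance(ps.covariance)
        g = rng.standard_normal((2, n))
        pos, ang = L @ g
        coords.append((pos, ang))
    (x, tx), (y, ty) = coords
    return ParticleBundle(x=x, y=y, theta_x=tx, theta_y=ty,
                          energy=float(energy) if energy is not None else 0.0,
                          z=ps_x.z_ref, seed=seed)


def transport(bundle: ParticleBundle, rs: RangeShifterSetup | None,
              tally_positions, step: float = 0.1, seed: int | None = None,
              log_correction: bool = False, bin_width: float = 0.05,
              return_final: bool = False):
    """Propagate a bundle downstream, recording crossings at the tally planes.

    Air regions are straight-line drifts; inside the slab,
    condensed-history steps of at most ``step`` cm apply correlated
    (dx, d_theta) kicks per axis with exact within-step moments, and the
    common ensemble energy is degraded through the range-energy law.  A
    beam whose residual range is below the slab thickness raises
    :class:`StoppedBeamError` (the monoenergetic ensemble stops as a
    whole).  Identical (bundle, seed, geometry) reproduce bit-identical
    tallies.  The input bundle is never mutated; with ``return_final``
    the (tallies, final bundle) pair is returned.
    """
    tallies = np.asarray(sorted(tally_positions, reverse=True), dtype=float)
    if tallies.size and tallies[0] > bundle.z:
        raise ValueError("tally planes must lie downstream of the bundle")
    if seed is None:
        seed = bundle.seed + 1
    x, y = bundle.x.copy(), bundle.y.copy()
    tx, ty = bundle.theta_x.copy(), bundle.theta_y.copy()
    z = bundle.z
    energy = bundle.energy

    has_slab = rs is not None and rs.physical_thickness > 0.0
    if has_slab:
        z_in = rs.upstream_face_position
        z_out = rs.downstream_face_position
        if z_in > bundle.z:
            raise ValueError("slab lies upstream of the bundle")
        if np.any((tallies < z_in) & (tallies > z_out)):
            raise ValueError("tally planes must lie in air, not inside the slab")
        if range_of_energy(energy, rs.material) <= rs.physical_thickness:
            raise StoppedBeamError(
                f"{energy} MeV ensemble stops inside the {rs.physical_thickness} cm "
                f"{rs.material.name} slab"
            )

    out: list[TallyPlane] = []

    def drift_and_tally(z_stop: float, planes: np.ndarray) -> float:
        nonlocal x, y
        zc = z
        for zp in planes:
            d = zc - zp
            x = x + tx * d
            y = y + ty * d
            zc = zp
            out.append(TallyPlane(position=zp, x=x.copy(), y=y.copy(),
                                  bin_width=bin_width))
        d = zc - z_stop
        x = x + tx * d
        y = y + ty * d
        return z_stop

    def finish():
        if not return_final:
            return out
        final = ParticleBundle(x=x, y=y, theta_x=tx, theta_y=ty, energy=energy,
                               z=z, seed=bundle.seed)
        return out, final

    if not has_slab:
        z = drift_and_tally(tallies[-1] if tallies.size else z, tallies)
        return finish()

    # air gap upstream of the slab
    z = drift_and_tally(z_in, tallies[tallies >= z_in])

    # condensed-history traversal of the slab
    rng_x, rng_y = (np.random.default_rng(s)
                    for s in np.random.SeedSequence(seed).spawn(2))
    t = rs.physical_thickness
    n_steps = max(int(math.ceil(t / step)), 1)
    ds = t / n_steps
    mat = rs.material
    mass_step = ds * mat.density
    for k in range(n_steps):
        e_mid = energy_at_depth(energy, (k + 0.5) * ds, mat)
        theta_s = highland_sigma(kinematic_factor(e_mid), mass_step,
                                 mat.radiation_length_mass,
                                 log_correction=log_correction)
        for arr, ang, rng in ((x, tx, rng_x), (y, ty, rng_y)):
            g1 = rng.standard_normal(arr.size)
            g2 = rng.standard_normal(arr.size)
            arr += ang * ds + theta_s * ds * (0.5 * g1 + g2 / math.sqrt(12.0))
            ang += theta_s * g1
    energy = energy_at_depth(energy, t, mat)
    z = z_out

    # air gap downstream of the slab
    below = tallies[tallies < z_in]
    z = drift_and_tally(below[-1] if below.size else z, below)
    return finish()


# ----------------------------------------------------------------------
# profile fitting
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileFit:
    """Maximum-likelihood Gaussian fit to a binned 1-D fluence profile."""

    sigma: float        # cm
    center: float       # cm
    sigma_err: float    # cm, large-n standard error sigma/sqrt(2n)
    n: int


@dataclass(frozen=True)
class ProfileFit2D:
    """Least-squares elliptical Gaussian fit to a 2-D fluence/dose image."""

    sigma_x: float      # cm
    sigma_y: float      # cm
    center: tuple       # (x, y) cm
    rss: float          # residual sum of squares


def fit_profile_1d(positions, bin_width: float = 0.05) -> ProfileFit:
    """Fit a Gaussian to binned crossing positions by maximum likelihood.

    The multinomial likelihood uses exact bin probabilities (differences
    of the normal CDF at the bin edges), so the estimate is unbiased to
    O(1/n) and free of the Sheppard binning bias.  Requires >= 100 counts
    spread over more than one bin.
    """
    data = np.asarray(positions, dtype=float)
    if data.size < 100:
        raise DegenerateDataError(f"need >= 100 counts for a stable fit, got {data.size}")
    counts, edges = TallyPlane(position=0.0, x=data, y=data,
                               bin_width=bin_width).histogram("x")
    if np.count_nonzero(counts) < 2:
        raise DegenerateDataError("all counts fall in a single bin")
    mu0 = float(data.mean())
    var0 = max(float(data.var()) - bin_width**2 / 12.0, (0.1 * bin_width) ** 2)

    def nll(params):
        mu, log_sigma = params
        s = math.exp(log_sigma)
        cdf = norm.cdf((edges - mu) / s)
        p = np.clip(np.diff(cdf), 1e-300, None)
        return -float(counts @ np.log(p))

    res = minimize(nll, x0=np.array([mu0, 0.5 * math.log(var0)]),
                   method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10})
    mu, sigma = res.x[0], math.exp(res.x[1])
    return ProfileFit(sigma=sigma, center=mu,
                      sigma_err=sigma / math.sqrt(2.0 * data.size), n=data.size)


def fit_profile_2d(image, pixel_spacing: float) -> ProfileFit2D:
    """Fit an elliptical Gaussian (amplitude, centers, sigmas, offset) to an image.

    ``pixel_spacing`` is in cm; returns sigmas in cm.  Suitable for spot
    images exported from a planning system (e.g. RT-Dose planes) or
    synthetic fluence maps.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.max() <= img.min():
        raise DegenerateDataError("image must be 2-D and non-constant")
    ny, nx = img.shape
    xs = (np.arange(nx) - (nx - 1) / 2.0) * pixel_spacing
    ys = (np.arange(ny) - (ny - 1) / 2.0) * pixel_spacing
    Xg, Yg = np.meshgrid(xs, ys)
    total = img.sum()
    mx = float((img * Xg).sum() / total)
    my = float((img * Yg).sum() / total)
    sx0 = math.sqrt(max(float((img * (Xg - mx) ** 2).sum() / total), pixel_spacing**2))
    sy0 = math.sqrt(max(float((img * (Yg - my) ** 2).sum() / total), pixel_spacing**2))

    def resid(p):
        amp, cx, cy, sx, sy, off = p
        model = amp * np.exp(-0.5 * ((Xg - cx) / sx) ** 2
                             - 0.5 * ((Yg - cy) / sy) ** 2) + off
        return (model - img).ravel()

    p0 = np.array([img.max() - img.min(), mx, my, sx0, sy0, img.min()])
    sol = least_squares(resid, p0, method="lm", max_nfev=5000)
    amp, cx, cy, sx, sy, off = sol.x
    return ProfileFit2D(sigma_x=abs(sx), sigma_y=abs(sy), center=(cx, cy),
                        rss=2.0 * sol.cost)


def fit_profiles(plane, pixel_spacing: float | None = None):
    """Gaussian spot-size extraction from a tally plane or a 2-D image.

    A :class:`TallyPlane` yields ``{"x": ProfileFit, "y": ProfileFit}``;
    a 2-D array (with ``pixel_spacing`` in cm) yields a
    :class:`ProfileFit2D`.
    """
    if isinstance(plane, TallyPlane):
        return {"x": fit_profile_1d(plane.x, plane.bin_width),
                "y": fit_profile_1d(plane.y, plane.bin_width)}
    if pixel_spacing is None:
        raise ValueError("pixel_spacing is required for image input")
    return fit_profile_2d(plane, pixel_spacing)


def tally_summary(planes: list[TallyPlane]) -> pd.DataFrame:
    """Per-plane Gaussian sigmas (cm) and standard errors as a DataFrame."""
    rows = []
    for plane in planes:
        fits = fit_profiles(plane)
        rows.append({
            "z_cm": plane.position,
            "sigma_x_cm": fits["x"].sigma, "se_x_cm": fits["x"].sigma_err,
            "sigma_y_cm": fits["y"].sigma, "se_y_cm": fits["y"].sigma_err,
            "n": plane.n,
        })
    return pd.DataFrame(rows)


def load_rtdose_plane(path):
    """Read a DICOM RT-Dose file into (image, pixel_spacing_cm).

    Multi-frame doses yield the central frame.  Requires pydicom.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    if arr.ndim == 3:
        arr = arr[arr.shape[0] // 2]
    scale = float(getattr(ds, "DoseGridScaling", 1.0))
    spacing_mm = float(ds.PixelSpacing[0])
    return arr * scale, spacing_mm / 10.0
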