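"""Synthetic spot-size datasets and benchmark scenario definitions.

Real commissioning data for pencil-beam scanning consists of in-air spot
sigmas measured with a scintillation screen at several planes around
isocenter, with and without the range shifter.  No such dataset is
publicly deposited, so this module generates one from known truth phase
spaces: sigmas follow the Fermi-Eyges model exactly, with optional
i.i.d. Gaussian measurement noise, and every dataset carries a
provenance block sufficient to regenerate it bit-identically.

The default truth table is a plausible cyclotron-beamline fixture, not a
measurement: in-air sigma at isocenter falls from ~6 mm at 105 MeV to
~3 mm at 226.7 MeV with a near-isocenter waist, so that the 3.8 mm
threshold relevant to the parameter-clamp defect is crossed between 160
and 225 MeV.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import RangeShifterSetup, get_material
from .phase_space import PhaseSpace, SigmaConvention, sigma_at, transport_with_scattering
from .scattering import rs_fermi_eyges_moments

__all__ = [
    "COMMISSIONING_ENERGIES",
    "MEASURED_PLANES",
    "RS_POSITIONS",
    "Scenario",
    "SpotDataset",
    "VALIDATION_ENERGIES",
    "benchmark_scenarios",
    "default_range_shifter",
    "default_truth",
    "make_lynx_dataset",
    "validation_scenarios",
]

#: Beam energies (MeV) of the single-spot study plans.
COMMISSIONING_ENERGIES = (105.0, 140.0, 160.0, 225.0, 226.7)
#: Downstream-face positions (cm from isocenter) studied for the slab.
RS_POSITIONS = (17.5, 26.5, 36.5)
#: The commissioning (reference) slab position.
REFERENCE_POSITION = 36.5
#: Energies of the independent experimental-validation set.
VALIDATION_ENERGIES = (120.0, 180.0, 226.7)
#: Screen positions (cm from isocenter) of the measured profiles: +-20 cm in 10 cm steps.
MEASURED_PLANES = (-20.0, -10.0, 0.0, 10.0, 20.0)

DATASET_COLUMNS = ["energy_MeV", "axis", "z_cm", "sigma_mm", "sigma_err_mm",
                   "rs_in", "rs_face_cm"]


def default_range_shifter(face_cm: float = REFERENCE_POSITION) -> RangeShifterSetup:
    """The study slab: 6.5 cm of Lexan with its exit face at ``face_cm``."""
    return RangeShifterSetup(material=get_material("lexan"), physical_thickness=6.5,
                             downstream_face_position=face_cm)


@dataclass(frozen=True)
class Scenario:
    """One benchmark condition: a beam energy and an optional slab position."""

    energy_MeV: float
    rs_face_cm: float | None = None
    commissioning: bool = False

    @property
    def open_beam(self) -> bool:
        return self.rs_face_cm is None

    @property
    def label(self) -> str:
        tag = "open" if self.open_beam else f"rs{self.rs_face_cm:g}"
        return f"E{self.energy_MeV:g}_{tag}"


def benchmark_scenarios() -> list[Scenario]:
    """Full factorial of the study: 5 energies x 3 slab positions, plus 5 open runs.

    The commissioning flag marks the reference slab position (36.5 cm).
    """
    scenarios = [Scenario(e) for e in COMMISSIONING_ENERGIES]
    scenarios += [
        Scenario(e, face, commissioning=(face == REFERENCE_POSITION))
        for e in COMMISSIONING_ENERGIES for face in RS_POSITIONS
    ]
    return scenarios


def validation_scenarios() -> list[Scenario]:
    """The measured-validation subset: three energies, open and slab at reference."""
    out = [Scenario(e) for e in VALIDATION_ENERGIES]
    out += [Scenario(e, REFERENCE_POSITION, commissioning=True)
            for e in VALIDATION_ENERGIES]
    return out


# ----------------------------------------------------------------------
# truth phase spaces
# ----------------------------------------------------------------------

#: Fixture constants of the default truth beam (not physics claims).
_TRUTH = {
    "x": {"sigma_iso_cm": 0.60, "sigma_exponent": 0.9,
          "theta0_rad": 3.2e-3, "theta_exponent": 0.45, "waist_cm": -2.0},
    "y": {"sigma_iso_cm": 0.63, "sigma_exponent": 0.9,
          "theta0_rad": 3.0e-3, "theta_exponent": 0.45, "waist_cm": -3.0},
}
_TRUTH_E_REF = 105.0


def default_truth(energies=COMMISSIONING_ENERGIES,
                  convention: SigmaConvention = SigmaConvention.VARIANCE,
                  ) -> dict[tuple[float, str], PhaseSpace]:
    """Truth open-beam phase spaces at isocenter, keyed by (energy, axis).

    sigma_iso(E) = sigma_ref (E_ref/E)**q and similarly for the angular
    spread; the waist sits a few cm downstream of isocenter.  B follows
    from the waist position: B = -C * d_waist with d_waist the drift
    distance from isocenter to the waist.
    """
    f = SigmaConvention(convention).factor
    table: dict[tuple[float, str], PhaseSpace] = {}
    for energy in energies:
        scale = _TRUTH_E_REF / energy
        for axis, p in _TRUTH.items():
            sig = p["sigma_iso_cm"] * scale ** p["sigma_exponent"]
            theta = p["theta0_rad"] * scale ** p["theta_exponent"]
            d_waist = -p["waist_cm"]  # waist downstream of isocenter
            C = theta**2
            table[(energy, axis)] = PhaseSpace(
                A=f * sig**2, B=-f * C * d_waist, C=f * C,
                z_ref=0.0, axis=axis, convention=convention,
            )
    return table


# ----------------------------------------------------------------------
# dataset container and generator
# ----------------------------------------------------------------------

@dataclass
class SpotDataset:
    """Tabular in-air spot sigmas with provenance.

    ``frame`` columns: energy_MeV, axis, z_cm, sigma_mm, sigma_err_mm,
    rs_in, rs_face_cm (NaN for open beam).  ``provenance`` records the
    truth parameters, noise model and seed of synthetic datasets.
    """

    frame: pd.DataFrame
    provenance: dict

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset is missing columns {missing}")
        if (self.frame["sigma_mm"] <= 0).any():
            raise ValueError("all sigma values must be positive")

    def slice(self, energy: float | None = None, axis: str | None = None,
              rs_in: bool | None = None) -> pd.DataFrame:
        sel = self.frame
        if energy is not None:
            sel = sel[sel["energy_MeV"] == energy]
        if axis is not None:
            sel = sel[sel["axis"] == axis]
        if rs_in is not None:
            sel = sel[sel["rs_in"] == rs_in]
        return sel

    def to_csv(self, path) -> None:
        """Write the table as CSV with a provenance sidecar JSON."""
        path = Path(path)
        self.frame.to_csv(path, index=False, float_format="%.9g")
        path.with_suffix(".provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True)
        )

    @classmethod
    def read_csv(cls, path) -> "SpotDataset":
        path = Path(path)
        frame = pd.read_csv(path)
        sidecar = path.with_suffix(".provenance.json")
        prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(frame=frame, provenance=prov)


def make_lynx_dataset(truth: dict[tuple[float, str], PhaseSpace],
                      rs: RangeShifterSetup | None = None,
                      planes=MEASURED_PLANES, noise_sd_mm: float = 0.05,
                      seed: int = 0, vmodel=None) -> SpotDataset:
    """Emulate a scintillation-screen commissioning dataset.

    For every truth (energy, axis) the open-beam sigma is the free-drift
    value at each plane; when ``rs`` is given, a second set of rows adds
    the slab's Fermi-Eyges moments before drifting.  Gaussian noise of
    standard deviation ``noise_sd_mm`` is added i.i.d. (zero gives exact
    model values).  The provenance block regenerates the dataset.

    Passing a commissioned ``vmodel`` (:class:`~rsbeam.commissioning.VModel`)
    generates the with-RS rows from the V-parameter increments instead of
    the slab's Fermi-Eyges moments — useful for exact round-trip checks of
    the extraction chain.
    """
    planes = np.asarray(planes, dtype=float)
    if planes.size < 3:
        raise ValueError("need at least 3 planes")
    if noise_sd_mm < 0:
        raise ValueError("noise_sd_mm must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []
    for (energy, axis), ps_open in sorted(truth.items()):
        sources = [(False, np.nan, ps_open)]
        if rs is not None:
            if vmodel is not None:
                from .commissioning import vmodel_deltas

                moments = vmodel_deltas(vmodel, energy, S=rs.downstream_face_position)
            else:
                moments = rs_fermi_eyges_moments(energy, rs,
                                                 S=rs.downstream_face_position)
            ps_rs = transport_with_scattering(ps_open, moments)
            sources.append((True, rs.downstream_face_position, ps_rs))
        for rs_in, face, ps in sources:
            sigma_mm = 10.0 * np.asarray(sigma_at(ps, planes))
            noisy = sigma_mm + rng.normal(0.0, noise_sd_mm, planes.size) \
                if noise_sd_mm > 0 else sigma_mm
            for z, s in zip(planes, noisy):
                rows.append({"energy_MeV": energy, "axis": axis, "z_cm": z,
                             "sigma_mm": s, "sigma_err_mm": noise_sd_mm,
                             "rs_in": rs_in, "rs_face_cm": face})
    provenance = {
        "generator": "rsbeam.synthetic.make_lynx_dataset",
        "synthetic": True,
        "seed": seed,
        "noise_sd_mm": noise_sd_mm,
        "with_rs_model": None if rs is None else
                         ("v_parameter" if vmodel is not None else "fermi_eyges"),
        "planes_cm": planes.tolist(),
        "truth": {
            f"{e}:{ax}": {"A": ps.A, "B": ps.B, "C": ps.C,
                          "convention": ps.convention.value}
            for (e, ax), ps in sorted(truth.items())
        },
        "range_shifter": None if rs is None else {
            "material": rs.material.name,
            "physical_thickness_cm": rs.physical_thickness,
            "downstream_face_cm": rs.downstream_face_position,
            "wet_cm": rs.wet,
        },
    }
    return SpotDataset(frame=pd.DataFrame(rows, columns=DATASET_COLUMNS),
                       provenance=provenance)
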