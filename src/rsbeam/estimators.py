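"""Scikit-learn style estimators for commissioning fits and V-model prediction.

Two estimators wrap the commissioning computations so they compose with
sklearn model selection and pipelines:

* :class:`PhaseSpaceFitter` - fits the free-drift quadratic to spot
  sigmas measured at several planes (one energy, one axis).
* :class:`VParameterEstimator` - full commissioning: fits open and
  with-RS phase spaces per energy and axis from a spot dataset, extracts
  the V parameter from the three model equations, and predicts spot
  sigmas for arbitrary range-shifter positions.

Both follow the fit/predict contract with trailing-underscore fitted
attributes; the module-level functions in :mod:`rsbeam.commissioning`
remain the functional surface.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .commissioning import VModel, extract_v, fit_phase_space, predict_with_rs
from .exceptions import DegenerateDataError
from .phase_space import PhaseSpace, SigmaConvention, sigma_at
from .synthetic import SpotDataset

__all__ = ["PhaseSpaceFitter", "VParameterEstimator"]


class PhaseSpaceFitter(RegressorMixin, BaseEstimator):
    """Constrained quadratic fit of (A, B, C) from sigma-vs-plane data.

    Parameters
    ----------
    convention : str
        ``"variance"`` (sigma^2 = A) or ``"eclipse_cylindrical"`` (A = 2 sigma^2).
    enforce_constraint : bool
        Restrict the fit to the physical region A C - B^2 >= 0.
    axis : str
        Transverse axis label carried into the fitted phase space.
    """

    def __init__(self, convention: str = "variance", enforce_constraint: bool = True,
                 axis: str = "x"):
        self.convention = convention
        self.enforce_constraint = enforce_constraint
        self.axis = axis

    def fit(self, X, y, sample_weight=None):
        """Fit to plane positions ``X`` (cm from isocenter) and sigmas ``y`` (cm)."""
        z = np.asarray(X, dtype=float).reshape(-1)
        result = fit_phase_space(
            z, np.asarray(y, dtype=float),
            convention=SigmaConvention(self.convention),
            enforce_constraint=self.enforce_constraint,
            axis=self.axis, weights=sample_weight,
        )
        ps = result.phase_space
        self.phase_space_ = ps
        self.A_, self.B_, self.C_ = ps.A, ps.B, ps.C
        self.determinant_ = result.determinant
        self.constraint_active_ = result.constraint_active
        self.residuals_ = result.residuals
        self.warnings_ = result.warnings
        return self

    def predict(self, X):
        """Spot sigma (cm) at plane positions ``X`` (cm from isocenter)."""
        check_is_fitted(self, "phase_space_")
        z = np.asarray(X, dtype=float).reshape(-1)
        return np.asarray(sigma_at(self.phase_space_, z))


class VParameterEstimator(RegressorMixin, BaseEstimator):
    """Commission a range-shifter V model from a spot dataset and predict sigmas.

    ``fit`` expects a :class:`~rsbeam.synthetic.SpotDataset` (or a
    DataFrame with its schema) containing open-beam rows and with-RS rows
    at the commissioning position ``s_reference``.  The V parameter is
    solved from each of the three moment equations at every commissioning
    energy (axes pooled by default) and averaged: over everything
    (``averaging="global"``, emulating the evaluated planning system) or
    per energy (``averaging="per_energy"``, isolating the model's
    geometric fidelity from its residual energy dependence).

    ``predict`` expects a DataFrame with columns ``energy_MeV``, ``axis``,
    ``z_cm`` and ``rs_face_cm`` (NaN for open beam) and returns sigmas in
    mm.
    """

    def __init__(self, l_wet: float, s_reference: float = 36.5,
                 beta_cut: float = 0.05, alpha_53: float | None = None,
                 lynch_dahl_correction: bool = False, pool_axes: bool = True,
                 averaging: str = "global", convention: str = "variance",
                 enforce_constraint: bool = True):
        self.l_wet = l_wet
        self.s_reference = s_reference
        self.beta_cut = beta_cut
        self.alpha_53 = alpha_53
        self.lynch_dahl_correction = lynch_dahl_correction
        self.pool_axes = pool_axes
        self.averaging = averaging
        self.convention = convention
        self.enforce_constraint = enforce_constraint

    # -- commissioning -----------------------------------------------------
    def fit(self, X, y=None):
        frame = X.frame if isinstance(X, SpotDataset) else pd.DataFrame(X)
        open_rows = frame[~frame["rs_in"]]
        rs_rows = frame[
            frame["rs_in"] & np.isclose(frame["rs_face_cm"], self.s_reference)
        ]
        energies = sorted(open_rows["energy_MeV"].unique())
        if not energies:
            raise DegenerateDataError("commissioning dataset has no open-beam rows")

        template = VModel(v=0.0, l_wet=self.l_wet, s_reference=self.s_reference,
                          alpha_53=self.alpha_53, beta_cut=self.beta_cut,
                          lynch_dahl_correction=self.lynch_dahl_correction)
        self.open_phase_spaces_: dict[tuple[float, str], PhaseSpace] = {}
        self.rs_phase_spaces_: dict[tuple[float, str], PhaseSpace] = {}
        self.warnings_: list[str] = []
        records = []
        missing = []
        for energy in energies:
            for axis in sorted(open_rows.loc[open_rows["energy_MeV"] == energy, "axis"].unique()):
                ps_open = self._fit_slice(open_rows, energy, axis)
                self.open_phase_spaces_[(energy, axis)] = ps_open
                sel = rs_rows[(rs_rows["energy_MeV"] == energy) & (rs_rows["axis"] == axis)]
                if len(sel) < 3:
                    missing.append((energy, axis))
                    continue
                ps_rs = self._fit_slice(rs_rows, energy, axis)
                self.rs_phase_spaces_[(energy, axis)] = ps_rs
                est = extract_v(ps_open, ps_rs, template, energy)
                records.append({"energy_MeV": energy, "axis": axis, **est.as_dict()})
        if not records:
            raise DegenerateDataError(
                "no with-RS commissioning rows at the reference position "
                f"S = {self.s_reference} cm; missing (energy, axis): {missing}"
            )
        if self.averaging not in ("global", "per_energy"):
            raise ValueError("averaging must be 'global' or 'per_energy'")
        self.v_estimates_ = pd.DataFrame.from_records(records).drop(columns="energy")
        if self.pool_axes:
            v_mean = float(self.v_estimates_[["v_a", "v_b", "v_c"]].to_numpy().mean())
            self.v_per_axis_ = {}
        else:
            self.v_per_axis_ = {
                axis: float(grp[["v_a", "v_b", "v_c"]].to_numpy().mean())
                for axis, grp in self.v_estimates_.groupby("axis")
            }
            v_mean = float(np.mean(list(self.v_per_axis_.values())))
        self.v_ = v_mean
        self.v_per_energy_ = {
            key: float(grp[["v_a", "v_b", "v_c"]].to_numpy().mean())
            for key, grp in self.v_estimates_.groupby(
                "energy_MeV" if self.pool_axes else ["energy_MeV", "axis"])
        }
        self.equation_cov_ = float(
            self.v_estimates_[["v_a", "v_b", "v_c"]].to_numpy().std()
            / self.v_estimates_[["v_a", "v_b", "v_c"]].to_numpy().mean()
        )
        self.vmodel_ = replace(template, v=self.v_)
        return self

    def _fit_slice(self, rows: pd.DataFrame, energy: float, axis: str) -> PhaseSpace:
        sel = rows[(rows["energy_MeV"] == energy) & (rows["axis"] == axis)]
        result = fit_phase_space(
            sel["z_cm"].to_numpy(), sel["sigma_mm"].to_numpy() / 10.0,
            convention=SigmaConvention(self.convention),
            enforce_constraint=self.enforce_constraint, axis=axis,
        )
        for w in result.warnings:
            self.warnings_.append(f"E={energy} MeV axis={axis}: {w}")
        return result.phase_space

    # -- prediction --------------------------------------------------------
    def _vmodel_for(self, axis: str, energy: float | None = None) -> VModel:
        if self.averaging == "per_energy" and energy is not None:
            key = energy if self.pool_axes else (energy, axis)
            if key in self.v_per_energy_:
                return replace(self.vmodel_, v=self.v_per_energy_[key])
        if self.pool_axes or not self.v_per_axis_:
            return self.vmodel_
        return replace(self.vmodel_, v=self.v_per_axis_[axis])

    def phase_space_with_rs(self, energy: float, axis: str, rs_face_cm: float) -> PhaseSpace:
        """Predicted phase space with the slab's exit face at ``rs_face_cm``."""
        check_is_fitted(self, "v_")
        ps_open = self._open_ps(energy, axis)
        return predict_with_rs(ps_open, self._vmodel_for(axis, energy), energy,
                               l_wet=self.l_wet, S=rs_face_cm)

    def _open_ps(self, energy: float, axis: str) -> PhaseSpace:
        try:
            return self.open_phase_spaces_[(energy, axis)]
        except KeyError:
            known = sorted({e for e, _ in self.open_phase_spaces_})
            raise KeyError(
                f"energy {energy} MeV / axis {axis!r} not commissioned; "
                f"available energies: {known}"
            ) from None

    def predict(self, X):
        """Spot sigmas (mm) for rows of (energy_MeV, axis, z_cm, rs_face_cm)."""
        check_is_fitted(self, "v_")
        frame = pd.DataFrame(X)
        out = np.empty(len(frame))
        for i, row in enumerate(frame.itertuples(index=False)):
            face = getattr(row, "rs_face_cm", None)
            if face is None or (isinstance(face, float) and np.isnan(face)):
                ps = self._open_ps(row.energy_MeV, row.axis)
            else:
                ps = self.phase_space_with_rs(row.energy_MeV, row.axis, face)
            out[i] = 10.0 * sigma_at(ps, row.z_cm)
        return out

    # -- reporting ---------------------------------------------------------
    def report(self) -> dict:
        """JSON-serializable commissioning report (per-energy parameters, V values)."""
        check_is_fitted(self, "v_")

        def ps_dict(ps: PhaseSpace) -> dict:
            return {"A_cm2": ps.A, "B_cm_rad": ps.B, "C_rad2": ps.C,
                    "determinant": ps.emittance}

        return {
            "v_MeV": self.v_,
            "v_per_axis_MeV": self.v_per_axis_,
            "v_per_energy_MeV": {str(k): v for k, v in self.v_per_energy_.items()},
            "averaging": self.averaging,
            "equation_cov": self.equation_cov_,
            "l_wet_cm": self.l_wet,
            "s_reference_cm": self.s_reference,
            "alpha_53": self.vmodel_.alpha_53,
            "beta_cut": self.beta_cut,
            "convention": self.convention,
            "v_estimates": self.v_estimates_.to_dict(orient="records"),
            "open_phase_spaces": {
                f"{e}:{ax}": ps_dict(ps) for (e, ax), ps in self.open_phase_spaces_.items()
            },
            "rs_phase_spaces": {
                f"{e}:{ax}": ps_dict(ps) for (e, ax), ps in self.rs_phase_spaces_.items()
            },
            "warnings": self.warnings_,
        }
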