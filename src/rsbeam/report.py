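"""Three-way comparison pipeline: analytical transport vs Monte Carlo vs V model.

Commissions the V-parameter model from a spot dataset, then evaluates
every scenario with (1) Fermi-Eyges transport using the slab's nominal
material properties, (2) the condensed-history Monte Carlo, and (3) the
commissioned V model, tabulating spot sigmas and their differences at
the standard planes around isocenter.  The defective planning-system
behaviours (parameter clamp, envelope-comparison discard) can be
switched on to reproduce their signatures; the default pipeline is
strictly correct physics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .commissioning import emulate_parameter_clamp
from .estimators import VParameterEstimator
from .exceptions import DegenerateDataError
from .kinematics import RangeShifterSetup
from .montecarlo import fit_profiles, sample_source, transport
from .phase_space import free_drift, sigma_at, transport_with_scattering
from .scattering import rs_fermi_eyges_moments
from .synthetic import Scenario, SpotDataset, default_range_shifter

__all__ = [
    "ComparisonOptions",
    "ComparisonResult",
    "STANDARD_PLANES",
    "render_report",
    "run_comparison",
]

#: Evaluation planes: -20 cm to +20 cm around isocenter in 5 cm steps.
STANDARD_PLANES = tuple(float(z) for z in range(-20, 25, 5))

#: Longitudinal position of the Monte Carlo source plane (cm from isocenter).
SOURCE_PLANE = 50.0

TABLE_COLUMNS = ["scenario", "energy_MeV", "rs_face_cm", "z_cm", "axis",
                 "sigma_fe_mm", "sigma_mc_mm", "sigma_mc_se_mm", "sigma_v_mm",
                 "diff_mc_fe_mm", "diff_v_fe_mm", "rel_v_fe_pct"]


@dataclass
class ComparisonOptions:
    """Knobs of the comparison pipeline (all deterministic given the seed)."""

    n_protons: int = 200_000
    seed: int = 12345
    planes: tuple = STANDARD_PLANES
    mc_step: float = 0.1          # cm, condensed-history step inside the slab
    mc_bin_width: float = 0.05    # cm, fluence histogram bin
    run_mc: bool = True
    pool_axes: bool = True
    averaging: str = "global"
    lynch_dahl: bool = False
    emulate_clamp: bool = False
    clamp_threshold_cm: float = 0.38


@dataclass
class ComparisonResult:
    table: pd.DataFrame
    estimator: VParameterEstimator
    rs: RangeShifterSetup
    options: ComparisonOptions
    warnings: list = field(default_factory=list)


def _scenario_seed(base: int, index: int) -> int:
    return int(np.random.SeedSequence([base, index]).generate_state(1)[0] % (2**31))


def run_comparison(scenarios: list[Scenario], commissioning_data: SpotDataset,
                   rs: RangeShifterSetup | None = None,
                   options: ComparisonOptions | None = None) -> ComparisonResult:
    """Commission from ``commissioning_data`` and evaluate every scenario.

    ``rs`` describes the slab (the default 6.5 cm Lexan setup when
    omitted); its face position is overridden per scenario.  Raises
    :class:`DegenerateDataError` listing what is absent when the dataset
    lacks open-beam or reference-position rows.
    """
    rs = rs if rs is not None else default_range_shifter()
    opt = options if options is not None else ComparisonOptions()

    est = VParameterEstimator(l_wet=rs.wet, s_reference=rs.downstream_face_position,
                              pool_axes=opt.pool_axes, averaging=opt.averaging,
                              lynch_dahl_correction=opt.lynch_dahl)
    est.fit(commissioning_data)
    warnings = list(est.warnings_)

    axes = sorted({ax for _, ax in est.open_phase_spaces_})
    missing = [(sc.energy_MeV, ax) for sc in scenarios for ax in axes
               if (sc.energy_MeV, ax) not in est.open_phase_spaces_]
    if missing:
        raise DegenerateDataError(
            f"commissioning dataset lacks open-beam fits for (energy, axis): "
            f"{sorted(set(missing))}"
        )

    clamped = {}
    if opt.emulate_clamp:
        for ax in axes:
            energies = sorted(e for e, a in est.open_phase_spaces_ if a == ax)
            table = [est.open_phase_spaces_[(e, ax)] for e in energies]
            new, flags = emulate_parameter_clamp(energies, table,
                                                 sigma_threshold=opt.clamp_threshold_cm)
            clamped.update({(e, ax): ps for e, ps, fl in zip(energies, new, flags)})
            for e, fl in zip(energies, flags):
                if fl:
                    warnings.append(
                        f"clamp emulation: E={e} MeV axis={ax} phase space "
                        "held at the highest unaffected energy"
                    )

    planes = np.asarray(opt.planes, dtype=float)
    rows = []
    for idx, sc in enumerate(scenarios):
        face = sc.rs_face_cm
        rs_here = None if face is None else rs.with_face_at(face)
        mc_sigmas = _mc_sigmas(est, sc, rs_here, planes, opt, idx) if opt.run_mc else None
        for ax in axes:
            ps_open = est.open_phase_spaces_[(sc.energy_MeV, ax)]
            if rs_here is None:
                ps_fe = ps_open
                ps_v = clamped.get((sc.energy_MeV, ax), ps_open) if opt.emulate_clamp \
                    else ps_open
            else:
                moments = rs_fermi_eyges_moments(sc.energy_MeV, rs_here, S=face)
                ps_fe = transport_with_scattering(ps_open, moments)
                base = clamped.get((sc.energy_MeV, ax), ps_open) if opt.emulate_clamp \
                    else ps_open
                vm = est._vmodel_for(ax, sc.energy_MeV)
                ps_v = transport_with_scattering(
                    base, _vmodel_moments(vm, sc.energy_MeV, face))
            sig_fe = 10.0 * np.asarray(sigma_at(ps_fe, planes))
            sig_v = 10.0 * np.asarray(sigma_at(ps_v, planes))
            for j, z in enumerate(planes):
                mc_val, mc_se = (mc_sigmas[ax][j] if mc_sigmas is not None
                                 else (np.nan, np.nan))
                rows.append({
                    "scenario": sc.label, "energy_MeV": sc.energy_MeV,
                    "rs_face_cm": np.nan if face is None else face,
                    "z_cm": z, "axis": ax,
                    "sigma_fe_mm": sig_fe[j], "sigma_mc_mm": mc_val,
                    "sigma_mc_se_mm": mc_se, "sigma_v_mm": sig_v[j],
                    "diff_mc_fe_mm": mc_val - sig_fe[j],
                    "diff_v_fe_mm": sig_v[j] - sig_fe[j],
                    "rel_v_fe_pct": 100.0 * (sig_v[j] - sig_fe[j]) / sig_fe[j],
                })
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return ComparisonResult(table=table, estimator=est, rs=rs, options=opt,
                            warnings=warnings)


def _vmodel_moments(vm, energy, face):
    from .commissioning import vmodel_deltas

    return vmodel_deltas(vm, energy, S=face)


def _mc_sigmas(est, sc: Scenario, rs_here, planes, opt: ComparisonOptions, idx: int):
    """Monte Carlo sigmas (mm) and standard errors per axis at the planes.

    Planes inside or upstream of the slab are reported as NaN: the
    additive-moment envelope is only physical downstream of the exit
    face, so only there is a fluence tally comparable to it.
    """
    mc_planes = planes if rs_here is None else \
        planes[planes <= rs_here.downstream_face_position]
    ps_x = free_drift(est.open_phase_spaces_[(sc.energy_MeV, "x")], -SOURCE_PLANE)
    ps_y = free_drift(est.open_phase_spaces_[(sc.energy_MeV, "y")], -SOURCE_PLANE)
    seed = _scenario_seed(opt.seed, idx)
    bundle = sample_source(ps_x, ps_y, opt.n_protons, seed, energy=sc.energy_MeV)
    tallies = transport(bundle, rs_here, mc_planes, step=opt.mc_step, seed=seed + 1,
                        bin_width=opt.mc_bin_width)
    by_position = {t.position: t for t in tallies}
    out = {"x": [], "y": []}
    for z in planes:
        if z not in by_position:
            for ax in ("x", "y"):
                out[ax].append((np.nan, np.nan))
            continue
        fits = fit_profiles(by_position[z])
        for ax in ("x", "y"):
            out[ax].append((10.0 * fits[ax].sigma, 10.0 * fits[ax].sigma_err))
    return out


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------

def render_report(result: ComparisonResult, outdir, formats=("csv", "json", "png")):
    """Write the comparison table, a JSON summary and per-scenario envelope plots.

    CSV and JSON output is byte-deterministic for identical inputs; the
    plots are for inspection only.  Returns a dict of written paths.
    """
    if result.table.empty:
        raise ValueError("comparison table is empty")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}

    if "csv" in formats:
        csv_path = outdir / "comparison.csv"
        result.table.to_csv(csv_path, index=False, float_format="%.9g")
        paths["csv"] = csv_path

    if "json" in formats:
        per_scenario = {}
        for label, grp in result.table.groupby("scenario", sort=True):
            entry = {
                "max_abs_diff_v_fe_mm": float(grp["diff_v_fe_mm"].abs().max()),
                "mean_abs_diff_v_fe_mm": float(grp["diff_v_fe_mm"].abs().mean()),
                "max_rel_diff_v_fe_pct": float(grp["rel_v_fe_pct"].abs().max()),
            }
            if grp["sigma_mc_mm"].notna().any():
                entry["max_abs_diff_mc_fe_mm"] = float(grp["diff_mc_fe_mm"].abs().max())
            per_scenario[label] = entry
        summary = {
            "v_MeV": result.estimator.v_,
            "equation_cov": result.estimator.equation_cov_,
            "n_protons": result.options.n_protons,
            "seed": result.options.seed,
            "scenarios": per_scenario,
            "max_rel_diff_v_fe_pct": float(result.table["rel_v_fe_pct"].abs().max()),
            "warnings": result.warnings,
        }
        json_path = outdir / "summary.json"
        json_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        paths["json"] = json_path

    if "png" in formats:
        paths["png"] = _plot_scenarios(result, outdir)
    return paths


def _plot_scenarios(result: ComparisonResult, outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for label, grp in result.table.groupby("scenario", sort=True):
        fig, axes_ = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
        for ax_plot, axis in zip(axes_, ("x", "y")):
            sub = grp[grp["axis"] == axis].sort_values("z_cm")
            ax_plot.plot(sub["z_cm"], sub["sigma_fe_mm"], ".-", label="Fermi-Eyges")
            if sub["sigma_mc_mm"].notna().any():
                ax_plot.errorbar(sub["z_cm"], sub["sigma_mc_mm"],
                                 yerr=3 * sub["sigma_mc_se_mm"], fmt="o",
                                 mfc="none", label="Monte Carlo")
            ax_plot.plot(sub["z_cm"], sub["sigma_v_mm"], "x--", label="V model")
            ax_plot.set_xlabel("plane position [cm from isocenter]")
            ax_plot.set_title(f"{label} ({axis})")
            ax_plot.invert_xaxis()  # beam travels toward negative positions
        axes_[0].set_ylabel("spot sigma [mm]")
        axes_[0].legend(fontsize=8)
        fig.tight_layout()
        path = outdir / f"envelope_{label}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written


def read_table(path) -> pd.DataFrame:
    """Read back a comparison CSV written by :func:`render_report`."""
    return pd.read_csv(path)


def max_rel_diff_from_csv(path) -> float:
    """Recompute the headline max |V-model vs FE| relative difference from a CSV."""
    table = read_table(path)
    return float((100.0 * (table["sigma_v_mm"] - table["sigma_fe_mm"])
                  / table["sigma_fe_mm"]).abs().max())
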