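"""Five-thirds integrals, V extraction/prediction, constrained fits, defect emulation."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

import rsbeam as rb
from rsbeam.commissioning import (
    VModel,
    calibrate_alpha53,
    check_rs_correction_validity,
    emulate_parameter_clamp,
    extract_v,
    fit_phase_space,
    five_thirds_integrals,
    predict_with_rs,
    vmodel_deltas,
)
from rsbeam.exceptions import DegenerateDataError, StoppedBeamError
from rsbeam.phase_space import PhaseSpace, sigma_at


def riemann_oracle(beta, beta_cut, n=400_000):
    """Brute-force cumulative-trapezoid evaluation of (phi, chi, psi)."""
    b = np.linspace(beta_cut, beta, n)
    w_phi = b ** (-4.0 / 3.0) * (1.0 - b * b) ** (-4.0 / 3.0)
    w_chi = b ** (8.0 / 3.0) * (1.0 - b * b) ** (-1.5)
    phi = cumulative_trapezoid(w_phi, b, initial=0.0)
    chi = cumulative_trapezoid(phi * w_chi, b, initial=0.0)
    psi = cumulative_trapezoid(chi * w_chi, b, initial=0.0)
    return phi[-1], chi[-1], psi[-1]


class TestFiveThirdsIntegrals:
    def test_vanish_at_cutoff(self):
        assert five_thirds_integrals(0.05, 0.05) == (0.0, 0.0, 0.0)

    def test_monotone_increasing(self):
        betas = np.linspace(0.1, 0.7, 13)
        phi, chi, psi = five_thirds_integrals(betas, 0.05)
        for arr in (phi, chi, psi):
            assert np.all(np.diff(arr) > 0)

    def test_against_riemann_oracle_20_random_pairs(self, rng):
        """Quadrature matches a brute-force Riemann sum to 1e-6 relative."""
        for _ in range(20):
            bc = rng.uniform(0.02, 0.2)
            beta = rng.uniform(bc + 0.05, 0.8)
            got = five_thirds_integrals(beta, bc)
            want = riemann_oracle(beta, bc)
            for g, w in zip(got, want):
                assert g == pytest.approx(w, rel=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            five_thirds_integrals(1.0, 0.05)
        with pytest.raises(ValueError):
            five_thirds_integrals(0.01, 0.05)


@pytest.fixture(scope="module")
def vm(rs_reference):
    return VModel(v=4.0, l_wet=rs_reference.wet, s_reference=36.5)


@pytest.fixture(scope="module")
def vm33(rs_reference):
    return VModel(v=3.3, l_wet=rs_reference.wet, s_reference=36.5)


class TestVModelDeltas:

    def test_zero_thickness_and_zero_v(self, vm):
        zero = vmodel_deltas(vm, 160.0, l_wet=0.0)
        assert (zero.delta_A, zero.delta_B, zero.delta_C) == (0.0, 0.0, 0.0)
        vm0 = replace(vm, v=0.0)
        zero = vmodel_deltas(vm0, 160.0)
        assert (zero.delta_A, zero.delta_B, zero.delta_C) == (0.0, 0.0, 0.0)

    def test_stopped_beam(self, vm):
        with pytest.raises(StoppedBeamError):
            vmodel_deltas(vm, 30.0)

    def test_beta_cut_cancels_from_differences(self, rs_reference):
        """The arbitrary cutoff cancels exactly from entrance-exit differences."""
        ref = None
        for bc in (0.02, 0.05, 0.10):
            vm = VModel(v=4.0, l_wet=rs_reference.wet, s_reference=36.5,
                        alpha_53=calibrate_alpha53(rs_reference.wet, beta_cut=bc),
                        beta_cut=bc)
            m = vmodel_deltas(vm, 140.0)
            if ref is None:
                ref = m
            else:
                assert m.delta_A == pytest.approx(ref.delta_A, rel=1e-6)
                assert m.delta_B == pytest.approx(ref.delta_B, rel=1e-6)
                assert m.delta_C == pytest.approx(ref.delta_C, rel=1e-6)

    @pytest.mark.parametrize("energy", [105.0, 140.0, 160.0])
    def test_matches_fermi_eyges_within_2pct(self, rs_reference, vm, energy):
        """With V extracted at each energy the deltas track the Highland
        Fermi-Eyges moments within 2% (the model's central fidelity claim)."""
        fe = rb.rs_fermi_eyges_moments(energy, rs_reference, 36.5)
        unit = vmodel_deltas(replace(vm, v=1.0), energy)
        v_mean = np.mean([fe.delta_A / unit.delta_A, fe.delta_B / unit.delta_B,
                          fe.delta_C / unit.delta_C])
        m = vmodel_deltas(replace(vm, v=float(v_mean)), energy)
        assert m.delta_A == pytest.approx(fe.delta_A, rel=0.02)
        assert m.delta_B == pytest.approx(fe.delta_B, rel=0.02)
        assert m.delta_C == pytest.approx(fe.delta_C, rel=0.02)


class TestExtractAndPredict:
    PS_OPEN = PhaseSpace(A=0.16, B=-2e-4, C=8e-6)

    def test_exact_round_trip(self, vm33):
        """extract_v o vmodel_deltas recovers V to 1e-9 from all equations."""
        for energy in (105.0, 160.0, 226.7):
            ps_rs = predict_with_rs(self.PS_OPEN, vm33, energy)
            est = extract_v(self.PS_OPEN, ps_rs, replace(vm33, v=0.0), energy)
            for v in (est.v_a, est.v_b, est.v_c, est.mean):
                assert v == pytest.approx(3.3, rel=1e-9)
            assert est.spread == pytest.approx(0.0, abs=1e-9)

    def test_identical_phase_spaces_give_zero(self, vm33):
        est = extract_v(self.PS_OPEN, self.PS_OPEN, vm33, 160.0)
        assert (est.v_a, est.v_b, est.v_c) == (0.0, 0.0, 0.0)

    def test_cross_model_spread_documented(self, rs_reference, vm33):
        """Against Highland Fermi-Eyges data the three equations agree to a few
        percent; the spread is recorded, not asserted tight."""
        for energy in (105.0, 140.0, 160.0):
            fe = rb.rs_fermi_eyges_moments(energy, rs_reference, 36.5)
            ps_rs = rb.transport_with_scattering(self.PS_OPEN, fe)
            est = extract_v(self.PS_OPEN, ps_rs, vm33, energy)
            assert est.spread < 0.10

    def test_predict_round_trip_at_reference(self, vm33):
        ps_rs = predict_with_rs(self.PS_OPEN, vm33, 160.0)
        again = predict_with_rs(self.PS_OPEN, vm33, 160.0,
                                l_wet=vm33.l_wet, S=vm33.s_reference)
        assert again.A == pytest.approx(ps_rs.A, rel=1e-12)

    def test_sigma_shrinks_as_slab_approaches_isocenter(self, vm33):
        """Moving the slab toward the patient shrinks the spot at isocenter."""
        sigmas = [sigma_at(predict_with_rs(self.PS_OPEN, vm33, 160.0, S=S), 0.0)
                  for S in (36.5, 26.5, 17.5, 5.0)]
        assert all(hi > lo for hi, lo in zip(sigmas, sigmas[1:]))

    def test_zero_thickness_slab_is_identity(self, vm33):
        assert predict_with_rs(self.PS_OPEN, vm33, 160.0, l_wet=0.0) is self.PS_OPEN

    def test_mismatched_reference_planes_rejected(self, vm33):
        shifted = replace(self.PS_OPEN, z_ref=10.0)
        with pytest.raises(ValueError):
            extract_v(self.PS_OPEN, shifted, vm33, 160.0)

    def test_lynch_dahl_correction_cancels_in_round_trip(self, rs_reference):
        vm33 = VModel(v=3.3, l_wet=rs_reference.wet, s_reference=36.5,
                    lynch_dahl_correction=True)
        ps_rs = predict_with_rs(self.PS_OPEN, vm33, 160.0)
        est = extract_v(self.PS_OPEN, ps_rs, replace(vm33, v=0.0), 160.0)
        assert est.mean == pytest.approx(3.3, rel=1e-9)


class TestFitPhaseSpace:
    TRUTH = (0.09, -9e-4, 1e-5)
    PLANES = np.arange(-20.0, 25.0, 5.0)

    @staticmethod
    def _sigma_from(theta, z):
        A, B, C = theta
        d = -z
        return np.sqrt(C * d * d + 2 * B * d + A)

    def test_exact_recovery_noise_free(self):
        sigma = self._sigma_from(self.TRUTH, self.PLANES)
        res = fit_phase_space(self.PLANES, sigma)
        assert res.phase_space.A == pytest.approx(self.TRUTH[0], rel=1e-10)
        assert res.phase_space.B == pytest.approx(self.TRUTH[1], rel=1e-8)
        assert res.phase_space.C == pytest.approx(self.TRUTH[2], rel=1e-8)
        assert not res.constraint_active
        assert np.max(np.abs(res.residuals)) < 1e-10
        assert res.determinant > 0

    def test_flat_profile(self):
        sigma = np.full_like(self.PLANES, 0.4)
        res = fit_phase_space(self.PLANES, sigma)
        assert res.phase_space.A == pytest.approx(0.16, rel=1e-9)
        assert res.phase_space.B == pytest.approx(0.0, abs=1e-12)
        assert res.phase_space.C == pytest.approx(0.0, abs=1e-12)

    def test_negative_determinant_data_hits_boundary(self):
        """Adversarial data with A C - B^2 < 0: the unconstrained fit reproduces
        it; the constrained fit lands on the determinant-zero boundary."""
        # sigma^2 = C (d - 25)(d - 30): real roots outside the plane range
        C = 1e-5
        truth = (750.0 * C, -27.5 * C, C)
        assert truth[0] * truth[2] - truth[1] ** 2 < 0
        sigma = self._sigma_from(truth, self.PLANES)

        free = fit_phase_space(self.PLANES, sigma, enforce_constraint=False)
        assert free.determinant < 0
        assert free.warnings
        assert free.phase_space.B == pytest.approx(truth[1], rel=1e-6)

        con = fit_phase_space(self.PLANES, sigma, enforce_constraint=True)
        assert con.constraint_active
        assert con.warnings
        scale = con.phase_space.A * con.phase_space.C
        assert abs(con.determinant) <= 1e-9 * max(scale, 1e-20)

    def test_constrained_solution_beats_boundary_grid(self):
        """Independent check: no boundary point from a coarse grid scan fits
        the adversarial data better than the constrained optimum."""
        C = 1e-5
        truth = (750.0 * C, -27.5 * C, C)
        sigma = self._sigma_from(truth, self.PLANES)
        con = fit_phase_space(self.PLANES, sigma, enforce_constraint=True)
        d = -self.PLANES
        X = np.column_stack([np.ones_like(d), 2 * d, d * d])
        y = sigma**2

        def rss(theta):
            r = X @ theta - y
            return r @ r

        best = min(
            rss(np.array([a * a, s * a * c, c * c]))
            for a in np.linspace(0.01, 0.3, 60)
            for c in np.linspace(1e-4, 6e-3, 60)
            for s in (-1.0, 1.0)
        )
        assert rss(np.array([con.phase_space.A, con.phase_space.B,
                             con.phase_space.C])) <= best * (1.0 + 1e-9)

    def test_underdetermined_and_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_phase_space(np.array([-5.0, 5.0]), np.array([0.3, 0.3]))
        with pytest.raises(DegenerateDataError):
            fit_phase_space(np.array([5.0, 5.0, 5.0]), np.array([0.3, 0.3, 0.3]))


class TestClampEmulation:
    @staticmethod
    def _table(sigmas_cm):
        energies = [100.0 + 30.0 * i for i in range(len(sigmas_cm))]
        table = [PhaseSpace(A=s**2, B=-2e-4, C=1e-5) for s in sigmas_cm]
        return energies, table

    def test_no_crossing_is_identity(self):
        energies, table = self._table([0.6, 0.5, 0.45, 0.40])
        out, flags = emulate_parameter_clamp(energies, table, 0.38)
        assert out == table
        assert flags == [False] * 4

    def test_crossing_at_fourth_of_six(self):
        """sigma_iso crosses 3.8 mm at the 4th entry: the last three are held
        constant at the 3rd entry's parameters and flagged."""
        energies, table = self._table([0.60, 0.48, 0.40, 0.36, 0.33, 0.30])
        out, flags = emulate_parameter_clamp(energies, table, 0.38)
        assert flags == [False, False, False, True, True, True]
        assert out[:3] == table[:3]
        for ps in out[3:]:
            assert (ps.A, ps.B, ps.C) == (table[2].A, table[2].B, table[2].C)

    def test_zero_threshold_is_identity(self):
        energies, table = self._table([0.60, 0.30, 0.20])
        out, flags = emulate_parameter_clamp(energies, table, 0.0)
        assert out == table and not any(flags)

    def test_unsorted_rejected(self):
        _, table = self._table([0.6, 0.5])
        with pytest.raises(ValueError):
            emulate_parameter_clamp([200.0, 100.0], table)


class TestEnvelopeCheck:
    OPEN = PhaseSpace(A=0.09, B=0.0, C=2e-6)

    def test_physical_pair_passes_downstream(self, rs_reference):
        fe = rb.rs_fermi_eyges_moments(226.7, rs_reference.with_face_at(17.5), 17.5)
        ps_rs = rb.transport_with_scattering(self.OPEN, fe)
        chk = check_rs_correction_validity(self.OPEN, ps_rs, 17.5, "downstream_only")
        assert chk.passed

    def test_identical_pair_passes_both_with_zero_margin(self):
        for region in ("downstream_only", "global"):
            chk = check_rs_correction_validity(self.OPEN, self.OPEN, 17.5, region)
            assert chk.passed
            assert np.allclose(chk.margin_cm, 0.0)

    def test_narrow_waist_fails_global_but_passes_downstream(self):
        """A corrected envelope with a narrow waist upstream of the slab face
        dips below the open envelope there: the flawed full-axis comparison
        reports a violation while the physical downstream check passes."""
        C, z_waist, sig_waist = 6e-4, 28.0, 0.2
        B = C * z_waist
        ps_rs = PhaseSpace(A=sig_waist**2 + B**2 / C, B=B, C=C)
        down = check_rs_correction_validity(self.OPEN, ps_rs, 17.5, "downstream_only")
        glob = check_rs_correction_validity(self.OPEN, ps_rs, 17.5, "global")
        assert down.passed
        assert not glob.passed
        assert np.all(glob.violation_z > 17.5)

    def test_region_validation(self):
        with pytest.raises(ValueError):
            check_rs_correction_validity(self.OPEN, self.OPEN, 17.5, "sideways")
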