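"""Source sampling, condensed-history transport and Gaussian profile extraction."""

import math

import numpy as np
import pytest

import rsbeam as rb
from rsbeam.exceptions import (
    DegenerateDataError,
    NonPhysicalPhaseSpaceError,
    StoppedBeamError,
)
from rsbeam.montecarlo import (
    fit_profile_1d,
    fit_profile_2d,
    fit_profiles,
    sample_source,
    transport,
)
from rsbeam.phase_space import PhaseSpace, free_drift

PS_X = PhaseSpace(A=0.36, B=-1e-3, C=1e-5, z_ref=50.0, axis="x")
PS_Y = PhaseSpace(A=0.40, B=-1e-3, C=9e-6, z_ref=50.0, axis="y")
PLANES = np.arange(-20.0, 25.0, 5.0)


class TestSampleSource:
    def test_sample_moments_converge(self):
        """Each second moment lands within 5 standard errors of its target."""
        n = 200_000
        b = sample_source(PS_X, PS_Y, n, seed=11)
        for vals, angs, ps in ((b.x, b.theta_x, PS_X), (b.y, b.theta_y, PS_Y)):
            for got, want in ((np.mean(vals**2), ps.A),
                              (np.mean(vals * angs), ps.B),
                              (np.mean(angs**2), ps.C)):
                se = abs(want) * math.sqrt(2.0 / n) if want != 0 else 1.0
                assert abs(got - want) < 5.0 * se + 5e-7

    def test_point_source_limit(self):
        ps0 = PhaseSpace(A=0.0, B=0.0, C=0.0, z_ref=50.0)
        b = sample_source(ps0, ps0, 1000, seed=3)
        assert np.all(b.x == 0.0) and np.all(b.theta_y == 0.0)

    def test_seed_determinism(self):
        b1 = sample_source(PS_X, PS_Y, 5000, seed=42)
        b2 = sample_source(PS_X, PS_Y, 5000, seed=42)
        assert np.array_equal(b1.x, b2.x) and np.array_equal(b1.theta_y, b2.theta_y)

    def test_negative_determinant_rejected(self):
        bad = PhaseSpace(A=0.01, B=0.1, C=0.5, z_ref=50.0)
        with pytest.raises(NonPhysicalPhaseSpaceError):
            sample_source(bad, PS_Y, 100, seed=0)

    def test_mismatched_planes_rejected(self):
        with pytest.raises(ValueError):
            sample_source(PS_X, PhaseSpace(A=0.4, B=0.0, C=1e-5, z_ref=0.0), 10, 0)


class TestTransport:
    def test_open_beam_matches_free_drift_closed_form(self):
        """Tallied sigma at 9 planes within 3 SE of sqrt(A(z)) from free drift."""
        n = 200_000
        b = sample_source(PS_X, PS_Y, n, seed=5, energy=160.0)
        tallies = transport(b, None, PLANES, seed=6)
        assert [t.position for t in tallies] == sorted(PLANES, reverse=True)
        for t in tallies:
            for data, ps in ((t.x, PS_X), (t.y, PS_Y)):
                want = rb.sigma_at(ps, t.position)
                got = float(np.std(data))
                se = want / math.sqrt(2.0 * n)
                assert abs(got - want) < 3.0 * se

    def test_slab_widens_beam_and_is_deterministic(self, rs_reference):
        n = 20_000
        b = sample_source(PS_X, PS_Y, n, seed=9, energy=160.0)
        t1 = transport(b, rs_reference, PLANES, seed=10)
        t2 = transport(sample_source(PS_X, PS_Y, n, seed=9, energy=160.0),
                       rs_reference, PLANES, seed=10)
        open_run = transport(sample_source(PS_X, PS_Y, n, seed=9, energy=160.0),
                             None, PLANES, seed=10)
        for a, c, o in zip(t1, t2, open_run):
            assert np.array_equal(a.x, c.x)            # bit-identical tallies
            assert np.std(a.x) > np.std(o.x) * 1.1     # scattering widens the spot

    def test_no_slab_consumes_no_scattering_draws(self):
        """Without a slab the transport is a pure deterministic drift."""
        b = sample_source(PS_X, PS_Y, 1000, seed=1, energy=160.0)
        t_a = transport(b, None, PLANES, seed=2)
        t_b = transport(b, None, PLANES, seed=99)   # seed irrelevant in air
        for a, c in zip(t_a, t_b):
            assert np.array_equal(a.x, c.x)

    def test_step_size_insensitivity(self, rs_reference):
        """Halving the condensed-history step leaves sigma within statistics
        of the Fermi-Eyges value (no step-size bias at the default 1 mm)."""
        n = 100_000
        fe = rb.rs_fermi_eyges_moments(160.0, rs_reference, 36.5)
        ps_rs_x = rb.transport_with_scattering(
            free_drift(PS_X, 50.0), fe)  # reference at isocenter
        for step, seed in ((0.1, 21), (0.05, 22)):
            b = sample_source(PS_X, PS_Y, n, seed=seed, energy=160.0)
            (tally,) = transport(b, rs_reference, [0.0], step=step, seed=seed + 1)
            want = rb.sigma_at(ps_rs_x, 0.0)
            se = want / math.sqrt(2.0 * n)
            assert abs(np.std(tally.x) - want) < 3.0 * se

    def test_angular_variance_gains_slab_moment(self, rs_reference):
        """After the slab the ensemble angular variance is C_open + delta_C."""
        n = 200_000
        fe = rb.rs_fermi_eyges_moments(160.0, rs_reference, 0.0)
        b = sample_source(PS_X, PS_Y, n, seed=30, energy=160.0)
        x0, tx0 = b.x.copy(), b.theta_x.copy()
        _, final = transport(b, rs_reference, [0.0], seed=31, return_final=True)
        # the input bundle is not mutated
        assert np.array_equal(b.x, x0) and np.array_equal(b.theta_x, tx0)
        for angles, ps in ((final.theta_x, PS_X), (final.theta_y, PS_Y)):
            want = ps.C + fe.delta_C
            got = float(np.mean(angles**2))
            se = want * math.sqrt(2.0 / n)
            assert abs(got - want) < 3.0 * se
        # energy degraded through the slab's water-equivalent thickness
        assert final.energy < b.energy

    def test_stopping_and_geometry_errors(self, rs_reference):
        b = sample_source(PS_X, PS_Y, 500, seed=7, energy=60.0)
        with pytest.raises(StoppedBeamError):
            transport(b, rs_reference, [0.0], seed=8)
        b2 = sample_source(PS_X, PS_Y, 500, seed=7, energy=160.0)
        with pytest.raises(ValueError):
            transport(b2, rs_reference, [40.0], seed=8)   # inside the slab


class TestProfileFits:
    def test_1d_recovery_within_half_percent(self, rng):
        """200k draws from N(0, 5 mm) binned at 0.5 mm recover sigma to 0.5%."""
        data = rng.normal(0.0, 0.5, 200_000)
        fit = fit_profile_1d(data, bin_width=0.05)
        assert fit.sigma == pytest.approx(0.5, rel=5e-3)
        assert abs(fit.center) < 5.0 * fit.sigma_err

    def test_1d_degenerate_inputs(self, rng):
        with pytest.raises(DegenerateDataError):
            fit_profile_1d(rng.normal(size=50))
        with pytest.raises(DegenerateDataError):
            fit_profile_1d(np.full(500, 0.123), bin_width=0.05)

    @staticmethod
    def _gaussian_image(sx, sy, pixel, half_extent=2.0):
        n = int(2 * half_extent / pixel) + 1
        ax = (np.arange(n) - (n - 1) / 2) * pixel
        X, Y = np.meshgrid(ax, ax)
        return np.exp(-0.5 * (X / sx) ** 2 - 0.5 * (Y / sy) ** 2)

    def test_2d_symmetric_image(self):
        img = self._gaussian_image(0.4, 0.4, 0.039)  # 0.39 mm pixels
        fit = fit_profile_2d(img, 0.039)
        assert fit.sigma_x == pytest.approx(fit.sigma_y, rel=1e-6)
        assert fit.sigma_x == pytest.approx(0.4, rel=1e-4)

    def test_2d_downsampling_stability(self):
        """Coarsening the pixel grid 2x moves sigma by well under 1%."""
        fine = fit_profile_2d(self._gaussian_image(0.35, 0.5, 0.039), 0.039)
        coarse = fit_profile_2d(self._gaussian_image(0.35, 0.5, 0.078), 0.078)
        assert coarse.sigma_x == pytest.approx(fine.sigma_x, rel=0.01)
        assert coarse.sigma_y == pytest.approx(fine.sigma_y, rel=0.01)

    def test_2d_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_profile_2d(np.ones((32, 32)), 0.039)

    def test_dispatch(self, rng):
        data = rng.normal(0.0, 0.3, 5000)
        plane = rb.TallyPlane(position=0.0, x=data, y=data)
        fits = fit_profiles(plane)
        assert set(fits) == {"x", "y"}
        with pytest.raises(ValueError):
            fit_profiles(np.ones((8, 8)))   # image without pixel spacing


class TestDicomRoundTrip:
    def test_rtdose_plane_reads_back(self, tmp_path):
        """A synthetic RT-Dose file (built in-memory) round-trips through the
        reader into a 2D Gaussian fit."""
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ImplicitVRLittleEndian, generate_uid

        pixel = 0.039  # cm
        n = 101
        ax = (np.arange(n) - (n - 1) / 2) * pixel
        X, Y = np.meshgrid(ax, ax)
        img = np.exp(-0.5 * (X / 0.45) ** 2 - 0.5 * (Y / 0.45) ** 2)
        scaling = 1e-4
        pixels = np.round(img / scaling).astype(np.uint16)

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = "1.2.840.10008.5.1.4.1.1.481.2"  # RT Dose
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ImplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "RTDOSE"
        ds.Rows, ds.Columns = pixels.shape
        ds.PixelSpacing = [pixel * 10.0, pixel * 10.0]  # mm
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.DoseGridScaling = scaling
        ds.PixelData = pixels.tobytes()
        path = tmp_path / "dose.dcm"
        ds.save_as(path, enforce_file_format=True)

        from rsbeam.montecarlo import load_rtdose_plane

        arr, spacing = load_rtdose_plane(path)
        assert spacing == pytest.approx(pixel)
        fit = fit_profile_2d(arr, spacing)
        assert fit.sigma_x == pytest.approx(0.45, rel=1e-3)
        assert fit.sigma_y == pytest.approx(0.45, rel=1e-3)
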