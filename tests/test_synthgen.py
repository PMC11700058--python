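"""Generator contracts: determinism, recorded truth, error modes."""

import numpy as np
import pytest

from osteotrack import synthgen as sg
from osteotrack.remodel import remodel_fractions


class TestTrabecularPhantom:
    def test_target_bvtv_hit(self, trabecular_phantom):
        vol, truth = trabecular_phantom
        measured = (vol.values >= 300.0).mean()
        assert abs(measured - 0.25) <= 0.02
        assert truth.true_bvtv == pytest.approx(measured)

    def test_degenerate_solid(self):
        vol, truth = sg.make_trabecular_phantom((32, 32, 32), 18.0, 1.0, seed=0)
        assert (vol.values >= 300.0).all()
        assert truth.true_bvtv == 1.0

    def test_determinism(self):
        a, _ = sg.make_trabecular_phantom((32, 32, 32), 18.0, 0.3, seed=5)
        b, _ = sg.make_trabecular_phantom((32, 32, 32), 18.0, 0.3, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_shape_and_fraction_validation(self):
        with pytest.raises(ValueError):
            sg.make_trabecular_phantom((16, 32, 32), 18.0, 0.25, seed=0)
        with pytest.raises(ValueError):
            sg.make_trabecular_phantom((32, 32, 32), 18.0, 0.0, seed=0)


class TestEvolvePhantom:
    def test_zero_remodelling_is_identity(self, trabecular_phantom):
        vol, _ = trabecular_phantom
        out, truth = sg.evolve_phantom(vol, 0.0, 0.0, seed=1)
        assert np.array_equal(out.values >= 300, vol.values >= 300)
        assert truth.formation_fraction == 0.0
        assert truth.resorption_fraction == 0.0

    def test_recorded_truth_is_exact(self, trabecular_phantom):
        vol, _ = trabecular_phantom
        out, truth = sg.evolve_phantom(vol, 0.10, 0.05, seed=3)
        res = remodel_fractions(vol.values >= 300, out.values >= 300)
        assert res.formation_fraction == pytest.approx(truth.formation_fraction, abs=0)
        assert res.resorption_fraction == pytest.approx(truth.resorption_fraction, abs=0)
        assert abs(truth.formation_fraction - 0.10) < 5e-3
        assert abs(truth.resorption_fraction - 0.05) < 5e-3

    def test_swapping_roles_exchanges_fractions(self, trabecular_phantom):
        vol, _ = trabecular_phantom
        out, truth = sg.evolve_phantom(vol, 0.10, 0.05, seed=3)
        res = remodel_fractions(out.values >= 300, vol.values >= 300)
        assert res.formation_fraction == pytest.approx(truth.resorption_fraction)
        assert res.resorption_fraction == pytest.approx(truth.formation_fraction)

    def test_formation_stays_connected(self, trabecular_phantom):
        """No connected component of the new mask consists purely of formed
        voxels: accretion always attaches to surviving structure."""
        from scipy import ndimage

        vol, _ = trabecular_phantom
        out, _ = sg.evolve_phantom(vol, 0.15, 0.10, seed=9)
        old = vol.values >= 300
        new = out.values >= 300
        labels, n = ndimage.label(new, ndimage.generate_binary_structure(3, 1))
        surviving_old = old & new
        has_old = np.zeros(n + 1, bool)
        has_old[np.unique(labels[surviving_old])] = True
        assert has_old[1:][np.unique(labels[new & ~old]) - 1].all()

    def test_determinism(self, trabecular_phantom):
        vol, _ = trabecular_phantom
        a, _ = sg.evolve_phantom(vol, 0.1, 0.1, seed=2)
        b, _ = sg.evolve_phantom(vol, 0.1, 0.1, seed=2)
        assert np.array_equal(a.values, b.values)


class TestCorticalPhantom:
    def test_closed_form_truth_recorded(self):
        _, truth = sg.make_cortical_phantom(2.0, 1.0, voxel_size_um=20.0, n_slices=2)
        assert truth.extras["ct_ar_mm2"] == pytest.approx(3 * np.pi)
        assert truth.extras["tt_ar_mm2"] == pytest.approx(4 * np.pi)
        assert truth.extras["section_modulus_mm3"] == pytest.approx(
            np.pi * 15 / 8, rel=1e-12
        )

    def test_solid_rod_has_no_marrow(self):
        vol, truth = sg.make_cortical_phantom(1.0, 0.0, voxel_size_um=20.0, n_slices=2)
        assert truth.extras["ma_ar_mm2"] == 0.0
        from scipy import ndimage

        bone = vol.values[0] >= 700
        filled = ndimage.binary_fill_holes(bone)
        assert (filled & ~bone).sum() == 0

    def test_too_small_radii_rejected(self):
        with pytest.raises(ValueError):
            sg.make_cortical_phantom(0.04, 0.01, voxel_size_um=20.0)


class TestAbdomenPhantom:
    def test_zero_adipose(self):
        vol, truth = sg.make_abdomen_phantom(0.0, seed=1)
        assert truth.adipose_fraction == 0.0

    def test_exact_cavity_fraction(self):
        _, truth = sg.make_abdomen_phantom(0.30, seed=11)
        assert truth.adipose_fraction == pytest.approx(0.30, abs=1e-4)

    def test_shell_lies_in_adipose_window(self):
        vol, _ = sg.make_abdomen_phantom(0.0, seed=1, noise_sd=0.0)
        hu = 10.0 * (vol.values - 110.0)
        # subcutaneous shell voxels fall inside the -280..-150 HU window
        assert ((hu >= -280) & (hu <= -150)).any()

    def test_standard_patches_recorded(self):
        vol, _ = sg.make_abdomen_phantom(0.1, seed=2, noise_sd=0.0)
        air, water = sg.abdomen_standard_means(vol)
        assert air == pytest.approx(10.0)
        assert water == pytest.approx(110.0)


class TestRamanSpectrum:
    def test_flat_zero_spectrum(self):
        s, _ = sg.make_raman_spectrum(
            band_amplitudes={960.0: 0.0}, pmma_scale=0.0, noise_sd=0.0, seed=0
        )
        assert np.allclose(s.intensities, 0.0)

    def test_mmr_by_construction(self, pmma_ref):
        from osteotrack.raman import compute_params

        s, truth = sg.make_raman_spectrum(
            {960.0: 8.0, 1670.0: 1.0}, pmma_scale=0.5, noise_sd=0.0, seed=0
        )
        assert truth.mmr == pytest.approx(8.0, rel=0.01)
        p = compute_params(s, pmma_ref)
        assert p.mmr == pytest.approx(8.0, rel=0.02)

    def test_determinism(self):
        a, _ = sg.make_raman_spectrum(seed=4)
        b, _ = sg.make_raman_spectrum(seed=4)
        assert np.array_equal(a.intensities, b.intensities)

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            sg.make_raman_spectrum({500.0: 1.0}, seed=0)


class TestLoadCurve:
    def test_plateau_yield_truth(self):
        _, truth = sg.make_load_curve(600.0, 120.0, 0.0, 120.0, 0.8, noise_sd=0.0, seed=1)
        assert truth["yield_load"] == pytest.approx(120.0)
        # 0.9*600 secant meets the 120 N plateau at 120/540 mm
        assert truth["yield_displacement"] == pytest.approx(120.0 / 540.0)

    def test_triangle_work(self):
        _, truth = sg.make_load_curve(200.0, 100.0, 0.0, 100.0, 0.5, noise_sd=0.0, seed=1)
        assert truth["work_to_fracture"] == pytest.approx(25.0)

    def test_inconsistent_parameters_rejected(self):
        with pytest.raises(ValueError):
            sg.make_load_curve(600.0, 200.0, 50.0, 150.0, 1.0, seed=0)
        with pytest.raises(ValueError):
            sg.make_load_curve(600.0, 100.0, 700.0, 150.0, 1.0, seed=0)

    def test_determinism(self):
        a, _ = sg.make_load_curve(seed=3)
        b, _ = sg.make_load_curve(seed=3)
        assert np.array_equal(a.load, b.load)

    def test_truth_work_matches_numeric_integration(self):
        curve, truth = sg.make_load_curve(650.0, 130.0, 60.0, 170.0, 1.2, noise_sd=0.0, seed=0)
        upto = curve.displacement <= truth["failure_displacement"]
        w = np.trapezoid(curve.load[upto], curve.displacement[upto])
        assert w == pytest.approx(truth["work_to_fracture"], rel=1e-3)
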