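"""Force-curve analysis: calibration, contact, Hertz fits, spring constants."""

import numpy as np
import pytest

from fibrilcyte import (
    ForceCurve,
    TipCalibration,
    analyze_curve,
    contact_slope_from_stiffness,
    deflection_to_force,
    estimate_spring_constant,
    find_contact_point,
    fit_hertz_cone,
    generate_force_curve,
    generate_force_map,
    hertz_cone_force,
    map_modulus,
    stiffness_from_slope,
)
from fibrilcyte.afm import (
    InsufficientContactError,
    NoContactError,
    PhysicalInconsistencyError,
)


class TestDeflectionToForce:
    def test_volt_conversion_with_calibration(self, default_calib):
        # 0.5 V * 28 nm/V * 2.0 N/m = 28 nN above a zero baseline
        z = np.linspace(0, 100, 50)
        defl = np.zeros(50)
        defl[-1] = 0.5
        curve = ForceCurve(z, defl, "V", "approach", default_calib)
        _, f = deflection_to_force(curve)
        assert f[-1] == pytest.approx(28.0)

    def test_zero_deflection_zero_force(self, default_calib):
        z = np.linspace(0, 100, 30)
        curve = ForceCurve(z, np.zeros(30), "V", "approach", default_calib)
        _, f = deflection_to_force(curve)
        assert np.allclose(f, 0.0)

    def test_length_units_bypass_sensitivity(self):
        calib1 = TipCalibration(sensitivity=1.0)
        z = np.linspace(0, 100, 30)
        d = np.concatenate([np.zeros(20), np.linspace(0, 5, 10)])
        cv = ForceCurve(z, d, "V", "approach", calib1)
        cn = ForceCurve(z, d, "nm", "approach", calib1)
        assert np.allclose(deflection_to_force(cv)[1], deflection_to_force(cn)[1])

    def test_baseline_subtracted(self, default_calib):
        z = np.linspace(0, 100, 50)
        defl = np.full(50, 0.3)  # constant offset, no contact signal
        curve = ForceCurve(z, defl, "V", "approach", default_calib)
        _, f = deflection_to_force(curve)
        assert np.allclose(f, 0.0)


class TestContactPoint:
    def test_noise_free_recovery_within_one_sample(self, default_calib):
        cyc = generate_force_curve(226e3, default_calib, contact_z_nm=200.0)
        z, f = deflection_to_force(cyc.approach)
        cp = find_contact_point(z, f)
        assert abs(cp.z_nm - 200.0) <= np.diff(z).max()

    def test_no_contact_raises(self, default_calib):
        rng = np.random.default_rng(0)
        z = np.linspace(0, 300, 200)
        f = rng.normal(0, 0.01, 200)
        with pytest.raises(NoContactError):
            find_contact_point(z, f)

    @pytest.mark.parametrize("noise_frac", [0.01, 0.05])
    def test_error_bounded_under_noise(self, default_calib, noise_frac):
        f_max = hertz_cone_force(100, 226e3, default_calib)
        errs = []
        for s in range(5):
            cyc = generate_force_curve(226e3, default_calib, contact_z_nm=200.0,
                                       noise_sd_nn=noise_frac * f_max, seed=s)
            z, f = deflection_to_force(cyc.approach)
            cp = find_contact_point(z, f)
            errs.append(abs(cp.z_nm - 200.0) / np.diff(z).max())
        assert max(errs) < 5.0


class TestHertzFit:
    @pytest.mark.parametrize("E", [10e3, 100e3, 226e3, 1e6, 10e6])
    def test_round_trip_zero_noise(self, default_calib, E):
        cyc = generate_force_curve(E, default_calib)
        fit = analyze_curve(cyc.retract)
        assert fit.E_pa == pytest.approx(E, rel=1e-3)
        assert fit.valid

    def test_retract_default_segment(self, default_calib):
        cyc = generate_force_curve(226e3, default_calib)
        assert analyze_curve(cyc.retract).segment == "retract"

    def test_poisson_ratio_rescales_modulus_exactly(self, default_calib):
        # same data fitted with nu=0 vs nu=0.5 differs by (1-nu^2)=0.75
        cyc = generate_force_curve(226e3, default_calib)
        z, f = deflection_to_force(cyc.retract)
        calib0 = TipCalibration(poisson_nu=0.0)
        f0 = fit_hertz_cone(f, z, cyc.true_contact_z_nm, calib0)
        f5 = fit_hertz_cone(f, z, cyc.true_contact_z_nm, default_calib)
        assert f5.E_pa / f0.E_pa == pytest.approx(0.75, rel=1e-12)

    def test_invariant_to_rigid_z_offset(self, default_calib):
        cyc = generate_force_curve(226e3, default_calib)
        z, f = deflection_to_force(cyc.retract)
        e1 = analyze_curve(cyc.retract).E_pa
        shifted = ForceCurve(cyc.retract.z_nm + 137.0, cyc.retract.deflection,
                             "V", "retract", default_calib)
        e2 = analyze_curve(shifted).E_pa
        assert e2 == pytest.approx(e1, rel=1e-6)

    def test_indent_cap_excludes_deep_samples(self, default_calib):
        cyc = generate_force_curve(226e3, default_calib, max_indent_nm=180.0)
        z, f = deflection_to_force(cyc.retract)
        fit = fit_hertz_cone(f, z, cyc.true_contact_z_nm, default_calib,
                             indent_cap_nm=100.0)
        assert fit.max_indent_used_nm <= 100.0

    def test_too_few_contact_samples_rejected(self, default_calib):
        z = np.linspace(0, 100, 20)
        f = np.zeros(20)
        with pytest.raises(InsufficientContactError):
            fit_hertz_cone(f, z, 99.0, default_calib)

    def test_noisy_round_trip_over_seeds(self, default_calib):
        f_max = hertz_cone_force(100, 226e3, default_calib)
        fits = [analyze_curve(generate_force_curve(
            226e3, default_calib, noise_sd_nn=0.10 * f_max, seed=s).retract).E_pa
            for s in range(10)]
        assert np.mean(fits) == pytest.approx(226e3, rel=0.10)


class TestSpringConstant:
    @pytest.mark.parametrize("k_true", [0.080, 0.24])
    def test_series_spring_round_trip_exact(self, k_true):
        # gelatin 0.080 N/m and PDMS 0.24 N/m against a 2.0 N/m tip
        m = contact_slope_from_stiffness(k_true, 2.0)
        assert m == pytest.approx(k_true / (k_true + 2.0), rel=1e-15)
        assert stiffness_from_slope(m, 2.0) == pytest.approx(k_true, rel=1e-12)

    def test_rigid_sample_slope_rejected(self):
        with pytest.raises(PhysicalInconsistencyError):
            stiffness_from_slope(1.0, 2.0)
        with pytest.raises(PhysicalInconsistencyError):
            stiffness_from_slope(-0.1, 2.0)

    def test_linear_contact_curve_recovers_stiffness(self, default_calib):
        # synthetic linear-spring sample: deflection slope m past contact
        k_true = 0.080
        m = contact_slope_from_stiffness(k_true, default_calib.k_tip)
        z = np.linspace(0, 400, 400)
        defl_nm = np.where(z > 150.0, (z - 150.0) * m, 0.0)
        curve = ForceCurve(z, defl_nm / default_calib.sensitivity, "V",
                           "approach", default_calib)
        est = estimate_spring_constant(curve, contact_z_nm=150.0)
        assert est.k_sample == pytest.approx(k_true, rel=1e-6)

    def test_hertz_curve_gives_positive_increasing_stiffness(self, default_calib):
        ks = []
        for E in (50e3, 500e3):
            cyc = generate_force_curve(E, default_calib)
            est = estimate_spring_constant(cyc.approach,
                                           contact_z_nm=cyc.true_contact_z_nm)
            ks.append(est.k_sample)
        assert 0 < ks[0] < ks[1]


class TestModulusMap:
    def test_class_means_recovered_zero_noise(self, default_calib):
        fmap = generate_force_map(grid=(10, 10), calib=default_calib, seed=0,
                                  n_samples=300)
        mm = map_modulus(fmap)
        s = mm.summary.set_index("region")
        assert s.loc["fibril_central", "mean_E_pa"] == pytest.approx(226e3, rel=0.02)
        assert s.loc["base", "mean_E_pa"] == pytest.approx(1e6, rel=0.02)

    def test_threshold_masking_matches_truth(self, default_calib):
        fmap = generate_force_map(grid=(10, 10), calib=default_calib, seed=0,
                                  n_samples=300)
        mm = map_modulus(fmap, mask_policy="threshold")
        assert np.array_equal(mm.fibril_mask, fmap.on_fibril)

    def test_uniform_map_single_class(self, default_calib):
        fmap = generate_force_map(E_fibril_pa=5e5, E_base_pa=5e5, grid=(6, 6),
                                  calib=default_calib, seed=0, n_samples=300)
        mm = map_modulus(fmap, mask_policy="threshold")
        assert not mm.fibril_mask.any()
        assert len(mm.summary) == 1

    def test_central_mask_is_eroded_fibril(self, default_calib):
        fmap = generate_force_map(grid=(12, 12), calib=default_calib, seed=0,
                                  n_samples=300)
        mm = map_modulus(fmap)
        assert mm.central_mask.sum() < mm.fibril_mask.sum()
        assert (mm.fibril_mask | ~mm.central_mask).all()
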