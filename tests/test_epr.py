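"""EPR chain: Phi, depth calibration, periodicity, distance estimation."""

import numpy as np
import pytest

from enthcg.epr import (AccessibilityProfile, calibrate_depth,
                        depth_from_phi, estimate_distance, fit_periodicity,
                        helical_wheel, phi)
from enthcg.synthetic import (gen_accessibility_profile,
                              gen_calibration_points, gen_pair_spectrum)


class TestPhi:
    def test_equal_accessibilities_zero(self):
        assert phi(0.7, 0.7) == 0.0

    def test_e_fold_unity(self):
        assert phi(np.e * 2.0, 2.0) == pytest.approx(1.0)

    def test_arithmetic(self):
        assert phi(5.0, 2.0) == pytest.approx(np.log(2.5), abs=1e-12)

    def test_log_ratio_identity(self):
        for x in (0.1, 1.0, 7.3):
            for y in (-1.0, 0.0, 2.2):
                assert phi(x * np.exp(y), x) == pytest.approx(y, abs=1e-10)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            phi(0.0, 1.0)
        with pytest.raises(ValueError):
            phi(1.0, -2.0)


class TestDepthCalibration:
    def test_two_points_exact_line(self):
        fit = calibrate_depth([(0.0, 1.0), (1.0, 4.0)])
        assert fit.a == pytest.approx(3.0)
        assert fit.b == pytest.approx(1.0)
        assert np.allclose(fit.residuals, 0.0)

    def test_paper_constants_recovered_noiseless(self):
        cal = gen_calibration_points(3.5, 0.37, np.linspace(0.1, 2.5, 5),
                                     0.0, seed=0)
        fit = calibrate_depth(cal)
        assert fit.a == pytest.approx(3.5, abs=1e-9)
        assert fit.b == pytest.approx(0.37, abs=1e-9)

    def test_noisy_slope_within_10pct(self):
        cal = gen_calibration_points(3.5, 0.37, np.linspace(0.0, 2.5, 8),
                                     0.3, seed=42)
        fit = calibrate_depth(cal)
        assert abs(fit.a / 3.5 - 1.0) < 0.10

    def test_depth_conversion_and_affinity(self):
        cal = calibrate_depth([(0.0, 0.37), (1.0, 3.87)])
        assert depth_from_phi(0.0, cal) == pytest.approx(0.37)
        assert depth_from_phi(2.18, cal) == pytest.approx(8.0, abs=0.01)
        d1, d2 = depth_from_phi(0.4, cal), depth_from_phi(1.1, cal)
        assert d1 + d2 - cal.b == pytest.approx(depth_from_phi(1.5, cal))

    def test_degenerate_phi_rejected(self):
        with pytest.raises(ValueError):
            calibrate_depth([(1.0, 2.0), (1.0, 3.0)])


class TestPeriodicity:
    def test_noiseless_period_to_3_decimals(self):
        prof = gen_accessibility_profile(11, period=3.6, phase=0.5,
                                         amplitude=1.0, noise_sd=0.0, seed=0)
        fit = fit_periodicity(prof)
        assert fit.period == pytest.approx(3.6, abs=5e-4)
        assert fit.identifiable

    def test_constant_profile_unidentifiable(self):
        fit = fit_periodicity(np.full(11, 0.4))
        assert not fit.identifiable
        assert fit.amplitude == pytest.approx(0.0, abs=1e-8)

    def test_noisy_period_within_02(self):
        prof = gen_accessibility_profile(15, period=3.6, phase=1.0,
                                         amplitude=1.0, noise_sd=0.2,
                                         seed=13)
        fit = fit_periodicity(prof)
        assert abs(fit.period - 3.6) < 0.2

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError):
            fit_periodicity(np.array([1.0, 2.0, 3.0]))


class TestHelicalWheel:
    def test_maxima_share_a_face(self):
        # phase chosen so residues 6, 10, 13 sit at local Phi maxima
        phase = -2.0 * np.pi * 6.0 / 3.6
        prof = gen_accessibility_profile(15, period=3.6, phase=phase,
                                         amplitude=1.0, noise_sd=0.0, seed=0)
        fit = fit_periodicity(prof)
        wheel = helical_wheel(prof, fit)
        faces = wheel.set_index("residue")["face"]
        assert faces[6] == faces[10] == faces[13] == "lipid"
        # residues 4 and 5 carry negative Phi: the opposite, solvent face
        assert faces[4] == faces[5] == "solvent"

    def test_phase_flip_swaps_faces(self):
        prof = gen_accessibility_profile(11, period=3.6, phase=0.0,
                                         amplitude=1.0, noise_sd=0.0, seed=0)
        fit = fit_periodicity(prof)
        wheel = helical_wheel(prof, fit)
        flipped = fit.__class__(period=fit.period, phase=fit.phase + np.pi,
                                amplitude=fit.amplitude, offset=fit.offset,
                                identifiable=True, residual=0.0)
        wheel2 = helical_wheel(prof, flipped)
        swap = {"lipid": "solvent", "solvent": "lipid"}
        assert list(wheel2["face"]) == [swap[f] for f in wheel["face"]]


class TestDistanceEstimation:
    @pytest.mark.parametrize("r_true", [9.0, 11.0, 13.0, 15.0, 21.0])
    def test_round_trip_within_1A(self, r_true):
        pair = gen_pair_spectrum(r_true, 2.0, 1.0, seed=1)
        est = estimate_distance(pair)
        assert abs(est.r_center - r_true) < 1.0

    def test_fraction_recovery(self):
        pair = gen_pair_spectrum(13.0, 2.0, 0.15, seed=1)
        est = estimate_distance(pair)
        assert 0.10 <= est.interacting_fraction <= 0.20

    def test_fraction_zero_flagged(self):
        pair = gen_pair_spectrum(13.0, 2.0, 0.0, seed=1)
        est = estimate_distance(pair)
        assert est.interacting_fraction < 0.05
        assert est.beyond_sensitivity

    def test_scale_invariance(self):
        pair = gen_pair_spectrum(13.0, 2.0, 0.6, seed=2)
        est1 = estimate_distance(pair)
        pair.full_labeled = pair.full_labeled * 37.0
        pair.spin_diluted = pair.spin_diluted * 37.0
        est2 = estimate_distance(pair)
        assert est1.r_center == pytest.approx(est2.r_center, abs=1e-6)
        assert est1.interacting_fraction == pytest.approx(
            est2.interacting_fraction, abs=1e-8)

    def test_grid_mismatch_rejected(self):
        from enthcg.spectra import SpectrumPair
        pair = gen_pair_spectrum(13.0, 2.0, 0.5, seed=1)
        with pytest.raises(ValueError):
            SpectrumPair(pair.field[:-1], pair.full_labeled,
                         pair.spin_diluted)


class TestAccessibilityProfileType:
    def test_phi_from_pi_columns(self):
        prof = AccessibilityProfile(residues=[1, 2],
                                    pi_o2=[2.0, np.e],
                                    pi_niedda=[2.0, 1.0])
        np.testing.assert_allclose(prof.phi, [0.0, 1.0])

    def test_frame_export(self):
        prof = AccessibilityProfile(residues=[3, 4], phi=[0.1, -0.2])
        df = prof.to_frame()
        assert list(df.columns) == ["residue", "phi"]
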