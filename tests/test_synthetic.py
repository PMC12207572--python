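import numpy as np
import pytest

import polorient as po
from polorient.images import LD, LO
from polorient.synthetic import _mean_moments


class TestOrientationDistribution:
    def test_delta_discretizes_to_a_point_mass(self):
        d = po.OrientationDistribution(33.0).discretize()
        assert d.angle_grid_deg.tolist() == [33.0]
        assert d.probability.tolist() == [1.0]

    def test_truncated_normal_normalizes_and_stays_in_range(self):
        d = po.OrientationDistribution(80.0, "truncated_normal", 20.0).discretize()
        assert d.probability.sum() == pytest.approx(1.0)
        assert d.angle_grid_deg.min() >= 0.0 and d.angle_grid_deg.max() <= 90.0

    def test_trig_moments_match_delta_closed_form(self):
        s2, c2 = po.OrientationDistribution(41.0).trig_moments()
        th = np.deg2rad(41.0)
        assert s2 == pytest.approx(np.sin(th) ** 2)
        assert c2 == pytest.approx(np.cos(th) ** 2)

    def test_spread_requires_concentration(self):
        with pytest.raises(ValueError, match="concentration"):
            po.OrientationDistribution(30.0, "truncated_normal")


class TestDomainMap:
    def test_realized_fraction_matches_target(self):
        for target in (0.2, 0.5):
            labels = po.generate_domain_map((256, 256), target, seed=5)
            realized = float((labels == LO).mean())
            assert abs(realized - target) <= 0.02

    def test_same_seed_is_bit_reproducible(self):
        m1 = po.generate_domain_map((64, 64), 0.3, seed=7)
        m2 = po.generate_domain_map((64, 64), 0.3, seed=7)
        assert np.array_equal(m1, m2)

    def test_fraction_equals_pixel_count_oracle(self):
        labels = po.generate_domain_map((128, 128), 0.3, seed=1)
        count = 0
        for row in labels:
            for v in row:
                count += v == LO
        assert float((labels == LO).mean()) == count / labels.size

    def test_degenerate_inputs_refused(self):
        with pytest.raises(ValueError):
            po.generate_domain_map((64, 64), 0.0)
        with pytest.raises(ValueError):
            po.generate_domain_map((4, 4), 0.3)


class TestSimulateScanImage:
    def test_zero_density_is_pure_background(self, rad_field):
        m = po.default_membrane(seed=0, shape=(64, 64), dye_surface_density_um2=0.0,
                                background_counts=5.0)
        img = po.simulate_scan_image(m, rad_field, seed=1)
        assert img.pixels.mean() == pytest.approx(5.0, abs=0.2)

    def test_axial_dipoles_invisible_to_azimuthal_beam(self, az_field):
        m = po.default_membrane(seed=0, shape=(64, 64), lo_theta_deg=0.0, ld_theta_deg=0.0,
                                background_counts=0.0)
        img = po.simulate_scan_image(m, az_field, seed=1)
        assert np.all(img.pixels == 0.0)

    def test_same_seed_gives_identical_images(self, rad_field):
        m = po.default_membrane(seed=2, shape=(64, 64))
        i1 = po.simulate_scan_image(m, rad_field, seed=9)
        i2 = po.simulate_scan_image(m, rad_field, seed=9)
        assert np.array_equal(i1.pixels, i2.pixels)

    def test_unnormalized_field_refused(self, rad_field):
        m = po.default_membrane(seed=0, shape=(64, 64))
        with pytest.raises(ValueError, match="not normalized"):
            po.simulate_scan_image(m, rad_field.scaled(2.0, tag="raw"), seed=0)

    def test_phase_ratio_matches_forward_curve_at_delta_tilt(self, az_field, rad_field, curve):
        # forward-model consistency: simulated ⟨I_A⟩/⟨I_R⟩ at θ=33° equals the
        # theoretical curve value within Monte-Carlo error at ~1e6 photons
        m = po.default_membrane(
            seed=4, shape=(128, 128), lo_theta_deg=33.0, ld_theta_deg=33.0,
            background_counts=0.0, brightness={"Lo": 0.2, "Ld": 0.2},
        )
        a = po.simulate_scan_image(m, az_field, seed=10)
        r = po.simulate_scan_image(m, rad_field, seed=11)
        n_a, n_r = a.pixels.sum(), r.pixels.sum()
        measured = (n_a / a.pixels.size) / (n_r / r.pixels.size)
        expected = float(curve.ratio_at(33.0))
        # 3σ Poisson error on the ratio of two independent totals
        sigma = expected * np.sqrt(1.0 / n_a + 1.0 / n_r)
        assert abs(measured - expected) < 3.0 * sigma


class TestSimulatePhaseSpectra:
    def test_noise_free_limit_equals_population_spectrum(self, rad_field):
        m = po.default_membrane(seed=0, shape=(64, 64), family="truncated_normal")
        spectra = po.simulate_phase_spectra(m, rad_field, peak_counts=None)
        moments = _mean_moments(rad_field)
        for phase in ("Lo", "Ld"):
            clean = po.population_spectrum(
                m.orientation(phase).discretize(), moments, phase
            )
            assert np.allclose(spectra[phase].intensity, clean.intensity)

    def test_same_seed_reproducible(self, rad_field):
        m = po.default_membrane(seed=1, shape=(64, 64))
        s1 = po.simulate_phase_spectra(m, rad_field, peak_counts=1e4, seed=3)
        s2 = po.simulate_phase_spectra(m, rad_field, peak_counts=1e4, seed=3)
        assert np.array_equal(s1["Ld"].intensity, s2["Ld"].intensity)

    def test_noisy_gp_close_to_noiseless_at_high_counts(self, rad_field):
        m = po.default_membrane(seed=1, shape=(64, 64), family="truncated_normal")
        clean = po.simulate_phase_spectra(m, rad_field, peak_counts=None)
        gp_clean = po.generalized_polarization(clean["Ld"])
        diffs = []
        for rep in range(100):
            noisy = po.simulate_phase_spectra(m, rad_field, peak_counts=1e5, seed=100 + rep)
            diffs.append(abs(po.generalized_polarization(noisy["Ld"]) - gp_clean))
        assert np.mean(diffs) < 0.01


class TestEndToEndRecovery:
    def test_identical_phase_distributions_recover_identically(self, az_field, rad_field):
        m = po.default_membrane(seed=6, shape=(128, 128), lo_theta_deg=37.0, ld_theta_deg=37.0)
        rep = po.end_to_end_recovery(m, az_field, rad_field, seed=6)
        assert abs(rep.recovered_theta_lo_deg - rep.recovered_theta_ld_deg) < 1.0

    def test_swapping_phase_distributions_swaps_the_recovery(self, az_field, rad_field):
        m1 = po.default_membrane(seed=8, shape=(128, 128), lo_theta_deg=32.0, ld_theta_deg=41.0)
        m2 = po.default_membrane(seed=8, shape=(128, 128), lo_theta_deg=41.0, ld_theta_deg=32.0)
        r1 = po.end_to_end_recovery(m1, az_field, rad_field, seed=8)
        r2 = po.end_to_end_recovery(m2, az_field, rad_field, seed=8)
        # ordering follows the truth in both direction assignments
        assert r1.recovered_theta_lo_deg < r1.recovered_theta_ld_deg
        assert r2.recovered_theta_lo_deg > r2.recovered_theta_ld_deg
        assert r1.ordering_correct and r2.ordering_correct

    def test_error_shrinks_with_photon_budget(self, az_field, rad_field):
        # forward/inverse consistency: mean |error| decreases as counts grow;
        # the ground-truth mask isolates photon statistics from segmentation
        from polorient.images import PhaseMask

        budgets = (0.002, 0.02, 0.2)  # brightness ↔ photons per pixel
        mean_abs_err = []
        for brightness in budgets:
            errs = []
            for seed in range(8):
                m = po.default_membrane(
                    seed=seed, shape=(64, 64),
                    brightness={"Lo": brightness, "Ld": brightness * 1.6},
                )
                truth_mask = PhaseMask(m.domain_map, "ground_truth")
                rep = po.end_to_end_recovery(
                    m, az_field, rad_field, seed=seed, mask=truth_mask
                )
                errs.append(abs(rep.error_lo_deg) + abs(rep.error_ld_deg))
            mean_abs_err.append(np.mean(errs))
        assert mean_abs_err[0] > mean_abs_err[1] > mean_abs_err[2]

    def test_report_round_trips_to_dict(self, az_field, rad_field):
        m = po.default_membrane(seed=0, shape=(64, 64))
        rep = po.end_to_end_recovery(m, az_field, rad_field, seed=0)
        d = rep.to_dict()
        assert d["mask_provenance"] == "otsu_single"
        assert d["error_lo_deg"] == pytest.approx(
            d["recovered_theta_lo_deg"] - d["true_theta_lo_deg"]
        )
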