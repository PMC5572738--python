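"""Synthetic-data generators: determinism, statistical calibration against
the closed-form occupancy model, and the assay's topological invariants."""

import numpy as np
import pytest

import scramfit as sf
from scramfit.errors import InvalidParameterError


class TestSampleRadii:
    def test_sigma_zero_all_equal(self):
        radii = sf.sample_radii(100, 100.6, 0.0, seed=0)
        assert np.all(radii == 100.6)

    def test_mean_within_clt_bound(self):
        n = 100_000
        radii = sf.sample_radii(n, 100.6, 31.5, seed=1)
        assert abs(radii.mean() - 100.6) < 3 * 31.5 / np.sqrt(n)

    def test_deterministic_given_seed(self):
        a = sf.sample_radii(1000, 100.6, 31.5, seed=7)
        b = sf.sample_radii(1000, 100.6, 31.5, seed=7)
        assert np.array_equal(a, b)

    def test_all_positive_even_for_wide_sigma(self):
        radii = sf.sample_radii(10_000, 10.0, 30.0, seed=2)
        assert np.all(radii > 0)


class TestAssignScramblases:
    def test_no_protein_no_scramblases(self):
        radii = sf.sample_radii(200, 100.8, 32.8, seed=3)
        pop = sf.assign_scramblases(radii, ppr=0.0, M=80_800.0, seed=4)
        assert np.all(pop.scramblase_counts == 0)

    def test_occupied_fraction_matches_closed_form(self):
        """With f=1, the simulated occupancy converges to the Gaussian-model
        probability (binomial 3-SE envelope)."""
        n, ppr = 100_000, 0.5
        radii = sf.sample_radii(n, 100.8, 32.8, seed=5)
        pop = sf.assign_scramblases(
            radii, ppr=ppr, M=80_800.0, f_reconstitutable=1.0, seed=6
        )
        params = sf.OccupancyModelParams(
            alpha=sf.mass_to_alpha(80_800.0), r_bar=100.8, sigma=32.8
        )
        p = sf.prob_occupied_gaussian(ppr, params)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(pop.occupied_fraction - p) < 3 * se

    def test_refractory_vesicles_carry_nothing(self):
        radii = sf.sample_radii(5000, 100.8, 32.8, seed=8)
        pop = sf.assign_scramblases(radii, ppr=1.0, M=80_800.0,
                                    f_reconstitutable=0.524, seed=9)
        assert np.all(pop.scramblase_counts[pop.refractory_flags] == 0)
        frac_refractory = pop.refractory_flags.mean()
        assert abs(frac_refractory - 0.476) < 3 * np.sqrt(0.476 * 0.524 / 5000)

    def test_total_count_conserves_poisson_mean(self):
        n, ppr, f = 50_000, 0.8, 0.524
        radii = sf.sample_radii(n, 100.8, 32.8, seed=10)
        pop = sf.assign_scramblases(radii, ppr=ppr, M=80_800.0,
                                    f_reconstitutable=f, seed=11)
        lam = sf.expected_scramblases(
            radii, ppr / f, sf.mass_to_alpha(80_800.0)
        )
        expected = lam[~pop.refractory_flags].sum()
        total = pop.scramblase_counts.sum()
        assert abs(total - expected) < 4 * np.sqrt(expected)


class TestDithioniteTrace:
    def test_protein_free_ideal_endpoint_is_half(self, protein_free_population,
                                                 ideal_params, t_grid):
        trace = sf.simulate_dithionite_trace(
            protein_free_population, ideal_params, t_grid, t_add=50.0, seed=0
        )
        assert sf.percent_reduction(trace).percent_reduction == pytest.approx(
            50.0, abs=1e-3
        )

    def test_fully_occupied_ideal_reduces_completely(self, ideal_params):
        radii = sf.sample_radii(300, 100.8, 32.8, seed=13)
        pop = sf.VesiclePopulation(
            radii=radii,
            scramblase_counts=np.ones(len(radii), dtype=int),
            refractory_flags=np.zeros(len(radii), dtype=bool),
            lipid_counts=np.full(len(radii), 1000),
        )
        t = np.arange(0.0, 2050.0, 1.0)
        trace = sf.simulate_dithionite_trace(pop, ideal_params, t, t_add=50.0, seed=0)
        # endpoint -> 100% as t -> infinity
        assert trace.fluorescence[-1] < 1e-8 * trace.fluorescence[0]

    def test_protected_pool_never_decreases(self, protein_free_population, t_grid):
        """Scramblase-free vesicles keep their inner-leaflet NBD: the trace
        never falls below the protected fraction of the signal."""
        params = sf.DithioniteAssayParams(noise_sd=0.0)  # F0 43, Fmax 76.2
        trace = sf.simulate_dithionite_trace(
            protein_free_population, params, t_grid, t_add=50.0, seed=0
        )
        protected = 100.0 * (1.0 - params.F0_target / 100.0)
        assert np.all(trace.fluorescence >= protected - 1e-9)
        # and the trace is non-increasing after addition (noise-free)
        post = trace.fluorescence[trace.time >= 50.0]
        assert np.all(np.diff(post) <= 1e-12)

    def test_decay_round_trip_recovers_half_life(self, t_grid):
        radii = sf.sample_radii(400, 100.8, 32.8, seed=14)
        pop = sf.assign_scramblases(radii, ppr=0.3, M=80_800.0, seed=15)
        params = sf.DithioniteAssayParams(k_red=0.0456, noise_sd=0.0)
        trace = sf.simulate_dithionite_trace(pop, params, t_grid, t_add=50.0, seed=0)
        res = sf.fit_decay(trace)
        assert res.t_half == pytest.approx(np.log(2) / 0.0456, rel=1e-3)

    def test_t_add_outside_grid_rejected(self, protein_free_population,
                                         ideal_params, t_grid):
        with pytest.raises(InvalidParameterError):
            sf.simulate_dithionite_trace(
                protein_free_population, ideal_params, t_grid, t_add=1e4, seed=0
            )


class TestPprSeries:
    def test_zero_ppr_sits_at_F0(self):
        pts = sf.generate_ppr_series([0.0], 80_800.0, 100.8, 32.8,
                                     noise_sd=0.0, seed=0)
        assert pts[0].F == pytest.approx(43.0)
        assert pts[0].P == 0.0

    def test_saturation_approaches_Fmax(self):
        # P -> 1 only algebraically (the sqrt prefactor), so approach is slow
        pts = sf.generate_ppr_series([50.0, 500.0], 80_800.0, 100.8, 32.8,
                                     noise_sd=0.0, seed=0)
        assert pts[0].F == pytest.approx(76.2, abs=0.05)
        assert 76.2 - pts[1].F < 76.2 - pts[0].F

    def test_noise_free_round_trip_recovers_alpha(self):
        ppr = np.linspace(0.05, 2.0, 20) * 0.524
        pts = sf.generate_ppr_series(ppr, 80_800.0, 100.8, 32.8,
                                     noise_sd=0.0, seed=0)
        res = sf.fit_occupancy_model(pts)
        assert res.alpha_hat == pytest.approx(sf.mass_to_alpha(80_800.0), rel=1e-6)

    def test_clipping_is_flagged(self):
        # enormous noise forces excursions outside [0, 1]
        pts = sf.generate_ppr_series(np.full(50, 1.0), 80_800.0, 100.8, 32.8,
                                     noise_sd=5.0, seed=1)
        assert any(p.clipped for p in pts)
        assert all(0.0 <= p.P <= 1.0 for p in pts)

    def test_inverted_endpoints_rejected(self):
        with pytest.raises(InvalidParameterError):
            sf.generate_ppr_series([0.1], 80_800.0, 100.8, 32.8,
                                   F0=80.0, Fmax=40.0, seed=0)


class TestDls:
    def test_histogram_counts_conserved(self):
        _, _, counts = sf.simulate_dls(5000, 100.6, 31.5, seed=0)
        assert counts.sum() == 5000

    def test_sigma_zero_single_bin(self):
        _, _, counts = sf.simulate_dls(100, 100.6, 0.0, seed=0)
        assert (counts > 0).sum() == 1

    def test_gaussian_fit_recovers_parameters(self):
        samples, _, _ = sf.simulate_dls(10_000, 100.6, 31.5, seed=21)
        fit = sf.fit_gaussian_radii(samples=samples)
        assert abs(fit.r_bar - 100.6) < 3 * fit.r_bar_se
        assert abs(fit.sigma - 31.5) < 3 * fit.sigma_se


class TestPyranine:
    def test_no_pumping_holds_initial_pH(self, linear_calibration):
        params = sf.PumpAssayParams(pH_init=7.4, pH_asymptote=6.5, k_pump=0.0,
                                    noise_sd=0.0)
        _, ph = sf.simulate_pyranine_trace(params, linear_calibration, seed=0)
        assert np.all(ph == 7.4)

    def test_pH_holds_during_dark_intervals(self, linear_calibration):
        params = sf.PUMP_PRESETS["br"]
        t = np.arange(0.0, 1201.0, 1.0)
        _, ph = sf.simulate_pyranine_trace(params, linear_calibration, t, seed=0)
        # dark interval 20-40 s: pH constant there
        dark = (t >= 21) & (t <= 39)
        assert np.ptp(ph[dark]) < 1e-12

    @pytest.mark.parametrize(
        "preset,target,tol",
        [("no_protein", 7.57, 0.2), ("br", 6.90, 0.14), ("br_valinomycin", 6.45, 0.16)],
    )
    def test_presets_hit_measured_pH20(self, preset, target, tol, linear_calibration):
        trace, _ = sf.simulate_pyranine_trace(
            sf.PUMP_PRESETS[preset], linear_calibration, seed=3
        )
        _, ph20, _ = sf.trace_to_pH(trace, linear_calibration, t_report=1200.0)
        assert ph20 == pytest.approx(target, abs=tol)

    def test_round_trip_recovers_true_pH_to_noise_level(self, linear_calibration):
        params = sf.PUMP_PRESETS["br_valinomycin"]
        trace, ph_true = sf.simulate_pyranine_trace(params, linear_calibration, seed=4)
        ph_est, _, _ = sf.trace_to_pH(trace, linear_calibration, t_report=600.0)
        noise_in_pH = params.noise_sd / abs(linear_calibration.slope_)
        assert np.sqrt(np.mean((ph_est - ph_true) ** 2)) < 2 * noise_in_pH

    def test_out_of_range_pH_is_flagged(self, linear_calibration):
        params = sf.PumpAssayParams(pH_init=8.9, pH_asymptote=5.1, k_pump=0.05,
                                    noise_sd=0.0)
        trace, _ = sf.simulate_pyranine_trace(params, linear_calibration, seed=0)
        assert "pH_outside_calibration" in trace.flags

    def test_deterministic_given_seed(self, linear_calibration):
        a, _ = sf.simulate_pyranine_trace(sf.PUMP_PRESETS["br"], linear_calibration,
                                          seed=9)
        b, _ = sf.simulate_pyranine_trace(sf.PUMP_PRESETS["br"], linear_calibration,
                                          seed=9)
        assert np.array_equal(a.fluorescence, b.fluorescence)
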