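import numpy as np
import pytest

from raftsize import (
    NoisyDomainObservations,
    fit_affinity_response,
    generate_affinity_dataset,
    generate_noisy_domain_observations,
    minimize_total_energy,
    recover_line_tension_experiment,
)
from raftsize.units import PN

BRACKET = (0.05 * PN, 4.0 * PN)


class TestDomainObservations:
    def test_noise_free_radii_all_equal_equilibrium(self, default_params, default_profile):
        obs = generate_noisy_domain_observations(
            1.0 * PN, default_params, n=8, noise_sd_log=0.0, seed=3, profile=default_profile
        )
        res = minimize_total_energy(
            default_params.with_sigma(1.0 * PN), profile=default_profile
        )
        np.testing.assert_allclose(obs.radii, res.R_star, rtol=1e-12)
        assert obs.R_star_true == pytest.approx(res.R_star, rel=1e-12)

    def test_bit_reproducible_under_seed(self, default_params, default_profile):
        a = generate_noisy_domain_observations(
            1.0 * PN, default_params, 50, 0.1, seed=9, profile=default_profile
        )
        b = generate_noisy_domain_observations(
            1.0 * PN, default_params, 50, 0.1, seed=9, profile=default_profile
        )
        np.testing.assert_array_equal(a.radii, b.radii)
        c = generate_noisy_domain_observations(
            1.0 * PN, default_params, 50, 0.1, seed=10, profile=default_profile
        )
        assert not np.array_equal(a.radii, c.radii)

    def test_geometric_mean_concentrates_at_equilibrium(self, default_params, default_profile):
        # lognormal sampling theory: log-gm is within 3·sd/sqrt(n) of log R*
        sd, n = 0.2, 10_000
        obs = generate_noisy_domain_observations(
            1.0 * PN, default_params, n, sd, seed=21, profile=default_profile
        )
        log_err = abs(np.log(obs.geometric_mean_radius) - np.log(obs.R_star_true))
        assert log_err < 3 * sd / np.sqrt(n)

    def test_invalid_arguments_rejected(self, default_params, default_profile):
        with pytest.raises(ValueError):
            generate_noisy_domain_observations(
                1.0 * PN, default_params, 0, 0.1, seed=1, profile=default_profile
            )
        with pytest.raises(ValueError):
            generate_noisy_domain_observations(
                1.0 * PN, default_params, 5, -0.1, seed=1, profile=default_profile
            )


class TestLineTensionRecovery:
    def test_noise_free_single_observation_round_trip(self, default_params, default_profile):
        obs = generate_noisy_domain_observations(
            1.2 * PN, default_params, n=1, noise_sd_log=0.0, seed=4, profile=default_profile
        )
        rec = recover_line_tension_experiment(
            obs, BRACKET, n_boot=10, profile=default_profile
        )
        assert rec.sigma_hat == pytest.approx(1.2 * PN, rel=1e-2)

    def test_interval_covers_truth_in_typical_replicate(self, default_params, default_profile):
        obs = generate_noisy_domain_observations(
            1.0 * PN, default_params, n=25, noise_sd_log=0.1, seed=123, profile=default_profile
        )
        rec = recover_line_tension_experiment(
            obs, BRACKET, n_boot=200, profile=default_profile
        )
        assert rec.ci_low < rec.ci_high
        assert rec.covers(1.0 * PN)

    def test_empty_observations_rejected(self, default_params):
        obs = NoisyDomainObservations(
            sigma_true=1.0 * PN,
            params=default_params,
            radii=np.array([]),
            noise_sd_log=0.1,
            seed=0,
            R_star_true=20e-9,
        )
        with pytest.raises(ValueError, match="empty"):
            recover_line_tension_experiment(obs, BRACKET)


class TestAffinityDataset:
    def test_noise_free_points_are_collinear(self):
        ds = generate_affinity_dataset(20, noise_sd=0.0, seed=6)
        x = np.log10(ds.kd)
        np.testing.assert_allclose(
            ds.p_tcr, ds.true_intercept_tcr + ds.true_slope_tcr * x, rtol=1e-12
        )
        np.testing.assert_allclose(
            ds.p_stat5, ds.true_intercept_stat5 + ds.true_slope_stat5 * x, rtol=1e-12
        )

    def test_default_sign_pattern(self):
        ds = generate_affinity_dataset(30, noise_sd=0.0, seed=6)
        fit = fit_affinity_response(ds)
        # phospho-TCR rises as affinity rises (Kd falls); phospho-STAT5 falls
        assert fit.slope_tcr < 0
        assert fit.slope_stat5 > 0
        assert fit.signs_match_expected

    def test_bit_reproducible_under_seed(self):
        a = generate_affinity_dataset(25, noise_sd=3.0, seed=8)
        b = generate_affinity_dataset(25, noise_sd=3.0, seed=8)
        np.testing.assert_array_equal(a.kd, b.kd)
        np.testing.assert_array_equal(a.p_tcr, b.p_tcr)
        c = generate_affinity_dataset(25, noise_sd=3.0, seed=9)
        assert not np.array_equal(a.p_tcr, c.p_tcr)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_affinity_dataset(2)
        with pytest.raises(ValueError):
            generate_affinity_dataset(10, kd_range=(1e-5, 1e-9))
        with pytest.raises(ValueError):
            generate_affinity_dataset(10, kd_range=(-1e-9, 1e-5))


class TestAffinityFit:
    def test_zero_noise_recovers_generating_slopes_exactly(self):
        ds = generate_affinity_dataset(50, noise_sd=0.0, seed=13)
        fit = fit_affinity_response(ds)
        assert fit.slope_tcr == pytest.approx(ds.true_slope_tcr, abs=1e-10)
        assert fit.slope_stat5 == pytest.approx(ds.true_slope_stat5, abs=1e-10)
        assert fit.r_squared_tcr == pytest.approx(1.0, abs=1e-12)

    def test_mean_slope_unbiased_over_replicates(self):
        # small version; the 500-replicate study is in the acceptance suite
        slopes = []
        for seed in range(50):
            ds = generate_affinity_dataset(100, noise_sd=4.8, seed=seed)
            slopes.append(fit_affinity_response(ds).slope_tcr)
        assert np.mean(slopes) == pytest.approx(-12.0, rel=0.05)

    def test_shuffled_responses_lose_the_signal(self):
        rng = np.random.default_rng(99)
        low_r2 = 0
        for seed in range(20):
            ds = generate_affinity_dataset(60, noise_sd=4.0, seed=seed)
            shuffled = generate_affinity_dataset(60, noise_sd=4.0, seed=seed)
            perm = rng.permutation(len(ds))
            shuffled = type(ds)(
                kd=ds.kd,
                p_tcr=ds.p_tcr[perm],
                p_stat5=ds.p_stat5[perm],
                true_slope_tcr=ds.true_slope_tcr,
                true_slope_stat5=ds.true_slope_stat5,
                true_intercept_tcr=ds.true_intercept_tcr,
                true_intercept_stat5=ds.true_intercept_stat5,
                noise_sd=ds.noise_sd,
                seed=ds.seed,
            )
            if fit_affinity_response(shuffled).r_squared_tcr < 0.05:
                low_r2 += 1
        assert low_r2 >= 19  # 95% of replicates

    def test_zero_kd_variance_rejected(self):
        ds = generate_affinity_dataset(10, noise_sd=1.0, seed=1)
        degenerate = type(ds)(
            kd=np.full(10, 1e-7),
            p_tcr=ds.p_tcr,
            p_stat5=ds.p_stat5,
            true_slope_tcr=ds.true_slope_tcr,
            true_slope_stat5=ds.true_slope_stat5,
            true_intercept_tcr=ds.true_intercept_tcr,
            true_intercept_stat5=ds.true_intercept_stat5,
            noise_sd=ds.noise_sd,
            seed=ds.seed,
        )
        with pytest.raises(ValueError, match="variance"):
            fit_affinity_response(degenerate)
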