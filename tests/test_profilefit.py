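"""Profile preprocessing, Nelder-Mead model fits and the bootstrap."""

import numpy as np
import pytest

import fcsgrad as fg
from fcsgrad.acf import ValidationError


@pytest.fixture(scope="module")
def sdd_truth():
    return fg.matched_sdd_params(d=8.8)


@pytest.fixture(scope="module")
def noiseless_sdd_profile(sdd_truth):
    return fg.generate_profile("sdd", sdd_truth, noise_rel=0.0, fit_time=None)


@pytest.fixture(scope="module")
def noisy_sdd_profile(sdd_truth):
    return fg.generate_profile("sdd", sdd_truth, noise_rel=0.1, n_embryos=3,
                               seed=11, fit_time=None)


class TestBackgroundCorrect:
    def test_zero_background_is_identity(self, noisy_sdd_profile):
        out = fg.background_correct(noisy_sdd_profile, "outside_embryo", 0.0)
        np.testing.assert_array_equal(out.mean, noisy_sdd_profile.mean)

    def test_scalar_subtraction(self):
        prof = fg.GradientProfile(np.arange(1.0, 6.0), np.full(5, 10.0),
                                  np.ones(5))
        out = fg.background_correct(prof, "outside_embryo", 4.0)
        np.testing.assert_array_equal(out.mean, np.full(5, 6.0))
        np.testing.assert_array_equal(out.sd, prof.sd)

    def test_paired_channel_self_subtraction_gives_zero(self):
        prof = fg.GradientProfile(np.arange(1.0, 6.0),
                                  np.array([5.0, 4.0, 3.0, 2.0, 1.0]))
        out = fg.background_correct(prof, "paired_channel", prof)
        np.testing.assert_array_equal(out.mean, np.zeros(5))

    def test_incompatible_grid_rejected(self):
        prof = fg.GradientProfile(np.arange(1.0, 6.0), np.ones(5))
        other = fg.GradientProfile(np.arange(1.0, 5.0), np.ones(4))
        with pytest.raises(ValidationError):
            fg.background_correct(prof, "paired_channel", other)


class TestResampleProfile:
    def test_zero_sd_returns_mean_exactly(self):
        prof = fg.GradientProfile(np.arange(1.0, 6.0), np.arange(5.0, 0., -1.),
                                  np.zeros(5))
        rep = fg.resample_profile(prof, 3)
        np.testing.assert_array_equal(rep.mean, prof.mean)

    def test_seed_reproducibility(self, noisy_sdd_profile):
        a = fg.resample_profile(noisy_sdd_profile, 42)
        b = fg.resample_profile(noisy_sdd_profile, 42)
        np.testing.assert_array_equal(a.mean, b.mean)

    def test_draws_match_declared_moments(self):
        prof = fg.GradientProfile(np.array([100.0]), np.array([50.0]),
                                  np.array([5.0]))
        draws = np.array([
            fg.resample_profile(prof, s).mean[0] for s in range(10000)
        ])
        assert draws.mean() == pytest.approx(50.0, rel=0.02)
        assert draws.std() == pytest.approx(5.0, rel=0.02)

    def test_missing_sd_rejected(self):
        prof = fg.GradientProfile(np.arange(1.0, 4.0), np.ones(3))
        with pytest.raises(ValidationError):
            fg.resample_profile(prof, 0)


class TestFitModelToProfile:
    def test_noiseless_self_consistency(self, sdd_truth,
                                        noiseless_sdd_profile):
        fit = fg.fit_model_to_profile(
            "sdd", noiseless_sdd_profile,
            free_params={"d": 4.0, "j": 0.5},
            fixed_params={"mu": sdd_truth.mu, "x_s": sdd_truth.x_s,
                          "l": sdd_truth.l},
            fit_time=None)
        assert fit.converged
        assert fit.params["d"] == pytest.approx(8.8, rel=0.02)
        assert fit.params["j"] == pytest.approx(1.0, rel=0.02)

    def test_degradation_rate_recovered_within_factor_two(self, sdd_truth):
        prof = fg.generate_profile("sdd", sdd_truth, noise_rel=0.1,
                                   n_embryos=3, seed=2, fit_time=None)
        fit = fg.fit_model_to_profile(
            "sdd", prof,
            free_params={"d": 6.0, "j": 0.8, "mu": 1.0 / 2000.0},
            fixed_params={"x_s": sdd_truth.x_s, "l": sdd_truth.l},
            fit_time=None)
        mu_true = 1.0 / 3000.0
        assert mu_true / 2 <= fit.params["mu"] <= mu_true * 2

    def test_two_component_fits_its_own_profile_better_than_sdd(
            self, bcd_two_comp_steady, coarse_grid):
        p2, ss = bcd_two_comp_steady
        x_data = np.arange(20.0, 500.0, 20.0)
        data = fg.GradientProfile(
            x_data, np.interp(x_data, coarse_grid, ss.rho_total[-1]))
        sdd_fit = fg.fit_model_to_profile(
            "sdd", data, free_params={"d": 8.8, "j": 1.0},
            fixed_params={"mu": p2.mu_f, "x_s": p2.x_s, "l": p2.l},
            fit_time=None)
        # two-component model refit from perturbed rates reaches a lower SSE
        two_fit = fg.fit_model_to_profile(
            "two_comp", data,
            free_params={"beta0": p2.beta0 * 1.5, "alpha": p2.alpha * 0.7},
            fixed_params={"d_f_ant": p2.d_f_ant, "d_f_post": p2.d_f_post,
                          "d_s_ant": p2.d_s_ant, "d_s_post": p2.d_s_post,
                          "rho0": p2.rho0, "mu_s": p2.mu_s, "mu_f": p2.mu_f,
                          "j": p2.j, "x_s": p2.x_s, "l": p2.l},
            fit_time=None, dx=2.0, maxiter=50)
        assert two_fit.objective < sdd_fit.objective

    def test_unknown_model_rejected(self, noiseless_sdd_profile):
        with pytest.raises(ValidationError):
            fg.fit_model_to_profile("nope", noiseless_sdd_profile, {"d": 1.0})


class TestBootstrap:
    def test_zero_sd_replicates_are_identical(self, sdd_truth,
                                              noiseless_sdd_profile):
        res = fg.bootstrap_fit(
            "sdd", noiseless_sdd_profile,
            free_params={"d": 4.0, "j": 0.5},
            fixed_params={"mu": sdd_truth.mu, "x_s": 30.0, "l": 500.0},
            n_boot=5, seed=0, fit_time=None)
        assert res.n_boot == 5 and res.n_converged == 5
        assert res.param_sd["d"] == pytest.approx(0.0, abs=1e-9)
        assert res.param_sd["j"] == pytest.approx(0.0, abs=1e-9)

    def test_master_seed_determinism(self, sdd_truth, noisy_sdd_profile):
        kwargs = dict(
            free_params={"d": 6.0, "j": 0.8},
            fixed_params={"mu": sdd_truth.mu, "x_s": 30.0, "l": 500.0},
            n_boot=8, seed=123, fit_time=None)
        a = fg.bootstrap_fit("sdd", noisy_sdd_profile, **kwargs)
        b = fg.bootstrap_fit("sdd", noisy_sdd_profile, **kwargs)
        assert a.param_mean == b.param_mean
        assert a.param_sd == b.param_sd

    def test_recovers_generating_parameters(self, sdd_truth,
                                            noisy_sdd_profile):
        res = fg.bootstrap_fit(
            "sdd", noisy_sdd_profile,
            free_params={"d": 6.0, "j": 0.8},
            fixed_params={"mu": sdd_truth.mu, "x_s": 30.0, "l": 500.0},
            n_boot=40, seed=5, fit_time=None)
        assert not res.flagged
        assert abs(res.param_mean["d"] - 8.8) <= 2 * res.param_sd["d"]
        assert abs(res.param_mean["j"] - 1.0) <= 2 * res.param_sd["j"]


class TestFitPrecision:
    def test_perfect_model_gives_zero(self, noiseless_sdd_profile):
        x, prec = fg.fit_precision_profile(noiseless_sdd_profile,
                                           noiseless_sdd_profile)
        np.testing.assert_allclose(prec, 0.0, atol=1e-15)

    def test_ten_percent_bias_everywhere(self, noiseless_sdd_profile):
        biased = fg.GradientProfile(noiseless_sdd_profile.x,
                                    1.1 * noiseless_sdd_profile.mean)
        _, prec = fg.fit_precision_profile(biased, noiseless_sdd_profile)
        np.testing.assert_allclose(prec, 0.1, rtol=1e-9)

    def test_sdd_fit_degrades_toward_posterior_on_two_component_data(
            self, bcd_two_comp_steady, coarse_grid):
        p2, ss = bcd_two_comp_steady
        x_data = np.arange(20.0, 500.0, 20.0)
        data = fg.GradientProfile(
            x_data, np.interp(x_data, coarse_grid, ss.rho_total[-1]))
        fit = fg.fit_model_to_profile(
            "sdd", data, free_params={"d": 8.8, "j": 1.0},
            fixed_params={"mu": p2.mu_f, "x_s": p2.x_s, "l": p2.l},
            fit_time=None)
        model = fg.sdd_steady_state(fg.SDDParams(**fit.params), x_data)
        x, prec = fg.fit_precision_profile(model, data)
        post = prec[x > 350]
        ant = prec[(x > 50) & (x < 250)]
        assert post.mean() > ant.mean()
        # the single-species fit underestimates the posterior concentration
        assert np.all(model.mean[x_data > 400] < data.mean[x_data > 400])


class TestExponentialDecay:
    def test_exact_decay_length_and_r2(self):
        x = np.arange(0.0, 500.0, 5.0)
        prof = fg.GradientProfile(x, 7.0 * np.exp(-x / 90.0))
        fit = fg.fit_exponential_decay(prof, (50.0, 300.0))
        assert fit.lambda_um == pytest.approx(90.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.amplitude == pytest.approx(7.0, rel=1e-9)

    def test_scale_invariance(self):
        x = np.arange(0.0, 500.0, 5.0)
        a = fg.GradientProfile(x, np.exp(-x / 85.0))
        b = fg.GradientProfile(x, 123.0 * np.exp(-x / 85.0))
        assert fg.fit_exponential_decay(a).lambda_um == pytest.approx(
            fg.fit_exponential_decay(b).lambda_um)

    def test_window_shift_equivariance(self):
        x = np.arange(0.0, 500.0, 2.0)
        prof = fg.GradientProfile(x, np.exp(-x / 95.0))
        f1 = fg.fit_exponential_decay(prof, (50.0, 250.0))
        f2 = fg.fit_exponential_decay(prof, (100.0, 300.0))
        assert f1.lambda_um == pytest.approx(f2.lambda_um, rel=1e-9)
        assert f1.amplitude == pytest.approx(f2.amplitude, rel=1e-9)

    def test_nonpositive_points_are_excluded_then_error(self):
        x = np.arange(0.0, 500.0, 50.0)
        y = np.exp(-x / 90.0)
        y[2:] = 0.0
        with pytest.raises(ValidationError):
            fg.fit_exponential_decay(fg.GradientProfile(x, y), (50.0, 300.0))
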