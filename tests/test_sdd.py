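"""SDD and two-component gradient models: solvers, steady states, metrics."""

import dataclasses

import numpy as np
import pytest

import fcsgrad as fg
from fcsgrad.acf import ValidationError
from fcsgrad.sdd import MU_DEFAULT, solve_two_component


class TestLinearDiffusionProfile:
    def test_endpoints(self):
        assert fg.linear_diffusion_profile(0.0, 13.0, 18.8, 500.0) == 13.0
        assert fg.linear_diffusion_profile(500.0, 13.0, 18.8, 500.0) == 18.8

    def test_constant_when_equal(self):
        x = np.linspace(0, 500, 11)
        np.testing.assert_array_equal(
            fg.linear_diffusion_profile(x, 5.0, 5.0, 500.0), np.full(11, 5.0))

    def test_midpoint_of_measured_values(self):
        assert fg.linear_diffusion_profile(250.0, 13.0, 18.8, 500.0) == \
            pytest.approx(15.9)

    def test_rejects_out_of_domain(self):
        with pytest.raises(ValidationError):
            fg.linear_diffusion_profile(-1.0, 13.0, 18.8, 500.0)


class TestTransitionRate:
    def test_vanishes_at_zero_concentration(self):
        assert fg.transition_rate(0.0, 0.013, 82.0) == 0.0

    def test_half_saturation(self):
        assert fg.transition_rate(82.0, 0.013, 82.0) == pytest.approx(0.013 / 2)

    def test_asymptote(self):
        assert fg.transition_rate(82.0 * 1e6, 0.013, 82.0) == pytest.approx(
            0.013, rel=1e-5)

    def test_monotone_increasing(self):
        rho = np.linspace(0, 1000, 50)
        beta = fg.transition_rate(rho, 0.013, 82.0)
        assert np.all(np.diff(beta) > 0)

    def test_rejects_negative_concentration(self):
        with pytest.raises(ValidationError):
            fg.transition_rate(-1.0, 0.013, 82.0)


class TestSteadyState:
    def test_decay_length_closed_form(self):
        p = fg.SDDParams(d=2.0, mu=1.0 / (50 * 60))
        assert p.decay_length == pytest.approx(np.sqrt(6000.0))
        assert p.decay_length == pytest.approx(77.5, abs=0.05)

    def test_linearity_in_production_rate(self, coarse_grid):
        p1 = fg.SDDParams(d=5.0, j=1.0)
        p2 = dataclasses.replace(p1, j=2.0)
        s1 = fg.sdd_steady_state(p1, coarse_grid)
        s2 = fg.sdd_steady_state(p2, coarse_grid)
        np.testing.assert_allclose(s2.mean, 2.0 * s1.mean, rtol=1e-12)

    def test_profile_monotone_nonincreasing(self, coarse_grid):
        for d in (1.0, 5.0, 13.0):
            s = fg.sdd_steady_state(fg.SDDParams(d=d), coarse_grid)
            assert np.all(np.diff(s.mean) <= 1e-12 * s.mean.max())

    def test_exponential_tail_log_slope(self, coarse_grid):
        p = fg.SDDParams(d=2.0, mu=1.0 / (50 * 60))
        fld = fg.solve_sdd(p, x_grid=coarse_grid,
                           t_out=np.array([10.0 / p.mu]))
        x = coarse_grid
        m = (x >= 150) & (x <= 300)
        slope = np.polyfit(x[m], np.log(fld.rho_f[-1][m]), 1)[0]
        assert -1.0 / slope == pytest.approx(p.decay_length, rel=0.02)


class TestSolveSDD:
    def test_starts_from_zero(self, coarse_grid):
        fld = fg.solve_sdd(fg.SDDParams(d=5.0), x_grid=coarse_grid,
                           t_out=np.array([1e-9, 60.0]))
        assert np.all(fld.rho_f[0] < 1e-6)

    def test_converges_to_analytic_steady_state(self, coarse_grid):
        p = fg.SDDParams(d=7.0)
        fld = fg.solve_sdd(p, x_grid=coarse_grid, t_out=np.array([10.0 / p.mu]))
        ss = fg.sdd_steady_state(p, coarse_grid)
        m = (coarse_grid >= 50) & (coarse_grid <= 450)
        err = np.linalg.norm(fld.rho_f[-1][m] - ss.mean[m]) / \
            np.linalg.norm(ss.mean[m])
        assert err < 0.01

    def test_grid_refinement_convergence(self):
        p = fg.SDDParams(d=7.0)
        t = np.array([90.0 * 60.0])
        coarse = fg.solve_sdd(p, fg.default_grid(500, 2.0), t).rho_f[-1]
        fine = fg.solve_sdd(p, fg.default_grid(500, 1.0), t).rho_f[-1]
        fine_on_coarse = np.interp(fg.default_grid(500, 2.0),
                                   fg.default_grid(500, 1.0), fine)
        rel = np.linalg.norm(coarse - fine_on_coarse) / \
            np.linalg.norm(fine_on_coarse)
        assert rel < 0.005

    def test_positivity(self, coarse_grid):
        fld = fg.solve_sdd(fg.SDDParams(d=7.0), coarse_grid,
                           np.linspace(60, 9000, 5))
        assert fld.rho_f.min() > -1e-10 * fld.rho_f.max()


class TestSolveTwoComponent:
    def test_reduces_to_single_species_without_exchange(self, coarse_grid):
        t = np.linspace(600, 5400, 3)
        sdd = fg.SDDParams(d=7.0)
        base = fg.solve_sdd(sdd, coarse_grid, t)
        p2 = fg.bcd_two_component_params(
            d_f_ant=7.0, d_f_post=7.0, beta0=0.0, alpha=0.0,
            diffusion_form="constant")
        two = fg.solve_two_component(p2, coarse_grid, t)
        np.testing.assert_allclose(two.rho_f, base.rho_f, rtol=1e-4,
                                   atol=1e-8 * base.rho_f.max())
        assert np.all(two.rho_s == 0)

    def test_mass_conservation_without_sources_or_sinks(self, coarse_grid):
        m = coarse_grid.size
        y0 = np.zeros(2 * m)
        y0[:m] = np.exp(-((coarse_grid - 100.0) ** 2) / 400.0)
        p = fg.bcd_two_component_params(j=1e-300, mu_s=0.0, mu_f=0.0)
        fld = solve_two_component(p, coarse_grid,
                                  np.linspace(60, 150 * 60, 6), y0=y0)
        mass = fld.total_mass()
        assert (mass.max() - mass.min()) / mass[0] < 1e-3

    def test_fields_stay_positive(self, bcd_two_comp_steady):
        _, ss = bcd_two_comp_steady
        peak = ss.rho_total.max()
        assert ss.rho_f.min() > -1e-10 * peak
        assert ss.rho_s.min() > -1e-10 * peak

    def test_steady_profile_monotone_and_fractions_match_fcs(
            self, bcd_two_comp_steady, coarse_grid):
        _, ss = bcd_two_comp_steady
        total = ss.rho_total[-1]
        assert np.all(np.diff(total) <= 1e-9 * total.max())
        frac = ss.rho_f[-1] / total
        i_ant = np.argmin(np.abs(coarse_grid - 50.0))
        i_post = np.argmin(np.abs(coarse_grid - 450.0))
        assert frac[i_ant] == pytest.approx(0.65, abs=0.02)
        assert frac[i_post] == pytest.approx(0.78, abs=0.02)


class TestMaturation:
    def test_no_maturation_observes_everything(self, coarse_grid):
        fld = fg.solve_sdd(fg.SDDParams(d=7.0), coarse_grid,
                           np.array([3600.0]))
        np.testing.assert_array_equal(fg.maturation_observe(fld, 0.0),
                                      fld.rho_total)

    def test_observed_never_exceeds_total(self, coarse_grid):
        p = fg.SDDParams(d=7.0, k_mat=1.0 / (45 * 60))
        fld = fg.solve_sdd(p, coarse_grid, np.linspace(600, 9000, 4))
        obs = fg.maturation_observe(fld, p.k_mat)
        assert np.all(obs <= fld.rho_total * (1 + 1e-9))

    def test_uniform_production_bright_fraction_closed_form(self):
        # source everywhere, no degradation/transport: with first-order
        # maturation the bright fraction at t = 1/k is 1 - (1-e^-1) = e^-1
        k = 1.0 / (45 * 60)
        p = fg.SDDParams(d=1e-6, mu=1e-12, j=1.0, x_s=499.999, l=500.0,
                         k_mat=k)
        x = fg.default_grid(500, 10.0)
        fld = fg.solve_sdd(p, x, np.array([1.0 / k]), rtol=1e-9, atol=1e-12)
        frac = fld.observed[-1] / fld.rho_total[-1]
        np.testing.assert_allclose(frac, np.exp(-1.0), rtol=1e-4)

    def test_rejects_negative_rate(self, coarse_grid):
        fld = fg.solve_sdd(fg.SDDParams(d=7.0), coarse_grid,
                           np.array([3600.0]))
        with pytest.raises(ValidationError):
            fg.maturation_observe(fld, -1.0)


class TestDistanceFromSteadyState:
    def test_limits(self, coarse_grid):
        p = fg.SDDParams(d=7.0)
        ss = fg.sdd_steady_state(p, coarse_grid)
        fld = fg.solve_sdd(p, coarse_grid,
                           np.array([1e-9, 10.0 / p.mu]))
        ratio = fg.distance_from_steady_state(fld, ss)
        assert np.nanmax(ratio[0]) < 1e-3          # t=0: nowhere near steady
        np.testing.assert_allclose(ratio[-1], 1.0, rtol=0.01)

    def test_anterior_equilibrates_first(self, coarse_grid):
        p = fg.SDDParams(d=7.0)
        ss = fg.sdd_steady_state(p, coarse_grid)
        fld = fg.solve_sdd(p, coarse_grid, np.array([60.0 * 60.0]))
        ratio = fg.distance_from_steady_state(fld, ss)[-1]
        i100 = np.argmin(np.abs(coarse_grid - 100.0))
        i450 = np.argmin(np.abs(coarse_grid - 450.0))
        assert ratio[i450] < ratio[i100]

    def test_monotone_in_time_for_single_species(self, coarse_grid):
        p = fg.SDDParams(d=7.0)
        ss = fg.sdd_steady_state(p, coarse_grid)
        fld = fg.solve_sdd(p, coarse_grid,
                           np.array([1800.0, 3600.0, 7200.0]))
        ratio = fg.distance_from_steady_state(fld, ss)
        assert np.all(np.diff(ratio, axis=0) > -1e-8)


class TestSpeedToPosterior:
    def test_two_component_reaches_posterior_faster(self, bcd_two_comp_steady,
                                                    coarse_grid):
        p2, ss2 = bcd_two_comp_steady
        t90 = np.array([90.0 * 60.0])
        two = fg.solve_two_component(p2, coarse_grid, t90)
        ratio2 = fg.distance_from_steady_state(
            two, fg.GradientProfile(coarse_grid, ss2.rho_total[-1]))
        ps = fg.matched_sdd_params(p2)
        assert ps.d == pytest.approx(8.8)
        sdd = fg.solve_sdd(ps, coarse_grid, t90)
        ratio1 = fg.distance_from_steady_state(
            sdd, fg.sdd_steady_state(ps, coarse_grid))
        i450 = np.argmin(np.abs(coarse_grid - 450.0))
        assert ratio2[-1, i450] > ratio1[-1, i450]


class TestBackOfEnvelope:
    def test_anterior_to_posterior_diffusion_time_about_two_hours(self):
        t = fg.diffusion_time(450.0, 7.0, c=4.0)
        assert t == pytest.approx(7232.0, rel=0.001)
        assert t / 3600.0 == pytest.approx(2.0, abs=0.05)

    def test_fast_mode_more_than_halves_the_time(self):
        slow = fg.diffusion_time(450.0, 7.0)
        fast = fg.diffusion_time(450.0, 18.0)
        assert fast == pytest.approx(2812.5)
        assert fast < slow / 2

    def test_quadratic_distance_scaling(self):
        assert fg.diffusion_time(900.0, 7.0) == pytest.approx(
            4.0 * fg.diffusion_time(450.0, 7.0))

    def test_survival_fraction_below_ten_percent(self):
        t = fg.diffusion_time(450.0, 7.0)
        surv = fg.survival_fraction(t, 50.0 * 60.0)
        assert surv == pytest.approx(0.0899, abs=0.0005)
        assert surv < 0.10
        assert fg.survival_fraction(t, 30.0 * 60.0) == pytest.approx(
            0.0179, abs=0.0005)

    def test_limits_and_validation(self):
        assert fg.survival_fraction(0.0, 100.0) == 1.0
        with pytest.raises(ValidationError):
            fg.diffusion_time(-1.0, 7.0)
        with pytest.raises(ValidationError):
            fg.survival_fraction(10.0, 0.0)


def test_registry_exposes_both_models():
    assert set(fg.MODEL_REGISTRY) >= {"sdd", "two_comp"}
    assert fg.MODEL_REGISTRY["sdd"]["params"] is fg.SDDParams
    assert fg.MODEL_REGISTRY["two_comp"]["params"] is fg.TwoComponentSDDParams


def test_default_degradation_rate_is_fifty_minute_lifetime():
    assert MU_DEFAULT == pytest.approx(1.0 / 3000.0)
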