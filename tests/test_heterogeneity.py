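from types import SimpleNamespace

import numpy as np
import pytest

from tmaze.errors import (DomainError, InsufficientDataError,
                          UnidentifiableError)
from tmaze.heterogeneity import (MazeHeterogeneityModel, calibrate_epsilon,
                                 choice_factor, empirical_sorting_index,
                                 fit_chi, fit_sigma, log_slope)
from tmaze.population import sample_phenotypes


class TestEpsilonCalibration:
    def test_linear_regime_value(self, hyper, linear_field, model_linear):
        eps = calibrate_epsilon(640.0, linear_field, hyper)
        expected = (640.0 * linear_field.gradient * hyper.mean_tumble_bias
                    / model_linear.gbar)
        assert eps == pytest.approx(expected, rel=1e-9)
        assert eps == pytest.approx(2.6e-3, rel=0.05)

    def test_mean_phenotype_recovers_fitted_velocity(self, model_linear,
                                                     linear_field):
        # by construction gbar * eps / tbar == chi_G * gradC
        assert model_linear.vbar_i[0] == pytest.approx(
            640.0 * linear_field.gradient, rel=1e-9)

    def test_log_regime_per_junction_decreasing(self, hyper, geom, log_field):
        eps = calibrate_epsilon(1400.0, log_field, hyper, geom)
        assert eps.shape == (4,)
        assert np.all(np.diff(eps) < 0)

    def test_nonpositive_chi_rejected(self, hyper, linear_field):
        with pytest.raises(DomainError):
            calibrate_epsilon(0.0, linear_field, hyper)


class TestSortingIndexHeterogeneous:
    def test_exceeds_one_and_increases_with_junction(self, model_linear,
                                                     model_log):
        for m in (model_linear, model_log):
            H = [m.heterogeneous_sorting_index(n) for n in range(1, 5)]
            assert np.all(np.array(H) > 1)
            assert np.all(np.diff(H) > 0)

    def test_monotone_in_heterogeneity_width(self, hyper, geom, linear_field):
        H = [MazeHeterogeneityModel(hyper.with_sigma(s), geom, linear_field)
             .heterogeneous_sorting_index(4) for s in (0.5, 4.0, 7.8)]
        assert np.all(np.diff(H) > 0)

    def test_approaches_one_as_heterogeneity_vanishes(self, hyper, geom,
                                                      linear_field):
        """H_n -> 1 when both the motor-gain spread and the cluster-size
        spread collapse (near-degenerate phenotype distribution)."""
        tight = hyper.with_sigma(0.2)
        m = MazeHeterogeneityModel(tight, geom, linear_field)
        # residual spread from the receptor-count mixture keeps H_4 above 1
        assert 1.0 < m.heterogeneous_sorting_index(4) < \
            MazeHeterogeneityModel(hyper, geom, linear_field
                                   ).heterogeneous_sorting_index(4)

    def test_linear_exceeds_log_at_last_junction(self, model_linear,
                                                 model_log):
        assert model_linear.heterogeneous_sorting_index(4) > \
            model_log.heterogeneous_sorting_index(4)

    def test_quadrature_matches_monte_carlo(self, model_linear, hyper):
        """N_B from the (g, T_B) quadrature agrees with a Monte-Carlo
        average of the navigation performance over sampled phenotypes."""
        n, t = 4, 4800.0
        df = sample_phenotypes(hyper, 100_000, seed=12345)
        w_g = model_linear.sensitivity_weight(df.g.to_numpy(), n) \
            / model_linear.sensitivity_weight(model_linear.gbar, n)
        w_T = model_linear.arrival_weight(df.T_B.to_numpy(), n, t)
        mc = model_linear.homogeneous_count(n, t) * np.mean(w_g * w_T)
        quad = model_linear.population_count(n, t)
        assert mc == pytest.approx(quad, rel=0.02)

    def test_count_decreasing_in_junction(self, model_linear):
        t = 4800.0
        N = [model_linear.population_count(n, t) for n in range(1, 5)]
        assert np.all(np.diff(N) < 0)


class TestJunctionMarginals:
    def test_tumble_bias_selected_downward(self, model_linear):
        t = 2400.0
        means = [model_linear.junction_tumble_marginal(n, t).mean
                 for n in range(0, 5)]
        assert np.all(np.diff(means[1:]) < 0)
        assert means[4] < means[0]

    def test_inlet_marginals_are_initial_distributions(self, model_linear,
                                                       hyper):
        refit = model_linear.junction_tumble_marginal(0, 2400.0)
        assert (refit.alpha, refit.beta) == (hyper.alpha, hyper.beta)
        g, pdf = model_linear.junction_gain_marginal(0)
        assert np.trapezoid(g * pdf, g) == pytest.approx(model_linear.gbar)

    @pytest.mark.parametrize("form,direction", [("transit", -1),
                                                ("growth", +1)])
    def test_gain_marginal_shifts_with_weight_sign(self, hyper, geom,
                                                   linear_field, form,
                                                   direction):
        m = MazeHeterogeneityModel(hyper, geom, linear_field,
                                   sorting_form=form)
        g, pdf = m.junction_gain_marginal(4)
        mean4 = np.trapezoid(g * pdf, g)
        assert np.sign(mean4 - m.gbar) == direction

    def test_velocity_distribution_normalized_and_shifting(self, model_linear):
        t = 2400.0
        means = []
        for n in range(1, 5):
            v, pdf = model_linear.junction_chemvel_pdf(n, t)
            assert np.trapezoid(pdf, v) == pytest.approx(1.0, abs=1e-3)
            means.append(np.trapezoid(v * pdf, v))
        assert np.all(np.diff(means) > 0)

    def test_mean_velocity_matches_distribution_mean(self, model_linear):
        n, t = 3, 2400.0
        v, pdf = model_linear.junction_chemvel_pdf(n, t)
        direct = np.trapezoid(v * pdf, v) / np.trapezoid(pdf, v)
        assert model_linear.junction_mean_velocity(n, t) == \
            pytest.approx(direct, rel=5e-3)

    def test_anchoring_rescales_junction1_mean(self, model_linear):
        t = 2400.0
        anchored = model_linear.anchor_epsilon(1.1, t)
        assert anchored.junction_mean_velocity(1, t) == pytest.approx(1.1)


class TestProfileStatistics:
    def test_log_slope_exact_on_exponential(self):
        y = np.linspace(0, 1200, 49)
        prof = SimpleNamespace(y=y, density=np.exp(0.002 * y))
        slope, se = log_slope(prof, window=(750, 1100))
        assert slope == pytest.approx(0.002, rel=1e-9)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_flat_profile_zero_slope(self):
        y = np.linspace(0, 1200, 49)
        slope, _ = log_slope(SimpleNamespace(y=y, density=np.ones_like(y)),
                             window=(750, 1100))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_counts_masked_with_warning(self):
        y = np.linspace(0, 1200, 49)
        c = np.exp(0.002 * y)
        c[32] = 0.0
        with pytest.warns(UserWarning):
            slope, _ = log_slope(SimpleNamespace(y=y, density=c),
                                 window=(750, 1100))
        assert slope == pytest.approx(0.002, rel=1e-9)

    def test_insufficient_points_rejected(self):
        y = np.linspace(0, 1200, 49)
        c = np.zeros_like(y)
        c[:3] = 1.0
        with pytest.warns(UserWarning), pytest.raises(InsufficientDataError):
            log_slope(SimpleNamespace(y=y, density=c), window=(750, 1100))

    @pytest.mark.parametrize("up,down,expected", [(100, 100, 0.0),
                                                  (200, 0, 1.0),
                                                  (75, 25, 0.5)])
    def test_choice_factor(self, up, down, expected):
        assert choice_factor(up, down) == pytest.approx(expected)

    def test_choice_factor_undefined_for_zero_total(self):
        with pytest.raises(DomainError):
            choice_factor(0, 0)

    def test_empirical_sorting_index_normalized_to_junction1(self):
        a = np.array([100, 100, 100, 100.0])
        b = np.array([100, 50, 25, 12.5])
        assert empirical_sorting_index(a, b) == \
            pytest.approx([1.0, 2.0, 4.0, 8.0])
        assert empirical_sorting_index(a, a) == pytest.approx(np.ones(4))

    def test_empirical_sorting_requires_junction1_counts(self):
        with pytest.raises(DomainError):
            empirical_sorting_index([0, 1.0], [1.0, 1.0])


class TestFits:
    def test_sigma_recovered_from_model_indices(self, model_linear, hyper,
                                                geom, linear_field):
        H = np.array([model_linear.heterogeneous_sorting_index(n)
                      for n in range(1, 5)])
        res = fit_sigma(H, hyper.with_sigma(3.0), geom, linear_field)
        assert res.value == pytest.approx(hyper.sigma, rel=0.02)

    def test_homogeneous_observations_drive_sigma_to_zero(self, hyper, geom,
                                                          linear_field):
        res = fit_sigma(np.ones(4), hyper, geom, linear_field)
        assert res.value < 0.2

    def test_single_observation_unidentifiable(self, hyper, geom,
                                               linear_field):
        with pytest.raises(UnidentifiableError):
            fit_sigma(np.array([2.0]), hyper, geom, linear_field)

    def test_flat_profile_cannot_constrain_chi(self, geom, linear_field):
        prof = SimpleNamespace(y=np.linspace(0, 1200, 40),
                               density=np.ones(40), time=2400.0)
        with pytest.raises(UnidentifiableError):
            fit_chi(prof, geom, linear_field)
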