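"""ACF model evaluation, fitting and bootstrap uncertainty."""

import numpy as np
import pytest

from nucleodyn.fcs_fit import (
    AcfModelFitter,
    bootstrap_se,
    evaluate_acf_model,
    fit_acf,
)
from nucleodyn.synthetic import generate_acf_curves
from nucleodyn.types import CorrelationCurve, FcsParams


def _single_population(which: str, n: float = 1.0, **times) -> FcsParams:
    fracs = {"f_diff": 0.0, "f_short": 0.0, "f_long": 0.0}
    fracs[which] = 1.0
    defaults = dict(tau_diff=1e-3, tau_short=1e-2, tau_long=2.0, omega=5.0)
    defaults.update(times)
    return FcsParams(n_molecules=n, **fracs, **defaults)


class TestEvaluateAcfModel:
    def test_zero_lag_amplitude_is_geometric_factor_over_n(self):
        # all lag-dependent factors equal 1 at tau = 0
        p = _single_population("f_diff")
        assert evaluate_acf_model(p, [0.0])[0] == pytest.approx(2.0**-1.5, rel=1e-12)

    def test_single_exponential_at_its_residence_time(self):
        # hand evaluation: G(tau_long) = e^-1 / 2^{3/2} for a pure
        # long-bound population with N = 1
        p = _single_population("f_long", tau_long=2.0)
        assert evaluate_acf_model(p, [2.0])[0] == pytest.approx(
            np.exp(-1.0) / 2.0**1.5, rel=1e-12
        )

    def test_vanishes_at_long_lag(self, two_population_params):
        assert evaluate_acf_model(two_population_params, [1e6])[0] < 1e-12

    def test_doubling_n_halves_g_everywhere(self, two_population_params, lag_grid):
        g1 = evaluate_acf_model(two_population_params, lag_grid)
        g2 = evaluate_acf_model(
            two_population_params.replace(n_molecules=4.0), lag_grid
        )
        np.testing.assert_allclose(g1, 2.0 * g2, rtol=1e-12)

    def test_strictly_decreasing_and_positive(self, two_population_params, lag_grid):
        g = evaluate_acf_model(two_population_params, lag_grid)
        assert np.all(g > 0)
        assert np.all(np.diff(g) < 0)

    def test_rejects_negative_lags(self, two_population_params):
        with pytest.raises(ValueError):
            evaluate_acf_model(two_population_params, [-1.0])


class TestFcsParamsInvariants:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_molecules=0.0),
            dict(omega=-1.0),
            dict(tau_diff=0.0),
            dict(f_diff=0.7),  # breaks the simplex sum
            dict(tau_short=2.0, tau_long=1.5),  # ordering violated
        ],
    )
    def test_invalid_parameters_rejected(self, two_population_params, kw):
        with pytest.raises(ValueError):
            two_population_params.replace(**kw)

    def test_k_off_is_exact_reciprocal(self, two_population_params):
        p = two_population_params
        assert p.k_off_short == 1.0 / p.tau_short
        assert p.k_off_long == 1.0 / p.tau_long


class TestFitAcf:
    def test_noiseless_round_trip_to_machine_precision(
        self, two_population_params, lag_grid
    ):
        curve = generate_acf_curves(two_population_params, lag_grid, 0.0, 1, seed=0)[0]
        res = fit_acf(curve, omega=5.0)
        assert res.converged
        for name in (
            "n_molecules",
            "f_diff",
            "f_short",
            "f_long",
            "tau_diff",
            "tau_short",
            "tau_long",
        ):
            true = getattr(two_population_params, name)
            fitted = getattr(res.params, name)
            assert fitted == pytest.approx(true, rel=1e-6), name

    def test_fractions_satisfy_simplex_constraint(
        self, two_population_params, lag_grid
    ):
        curve = generate_acf_curves(
            two_population_params,
            lag_grid,
            0.05 * evaluate_acf_model(two_population_params, lag_grid),
            1,
            seed=3,
        )[0]
        p = fit_acf(curve, omega=5.0).params
        assert p.f_diff + p.f_short + p.f_long == pytest.approx(1.0, abs=1e-9)

    def test_swapped_time_seeds_yield_same_ordered_optimum(
        self, two_population_params, lag_grid
    ):
        # label switching: seeding the optimizer with tau_short and
        # tau_long grids exchanged must reach the same ordered solution
        curve = generate_acf_curves(two_population_params, lag_grid, 0.0, 1, 0)[0]
        a = AcfModelFitter(omega=5.0).fit(curve)
        b = AcfModelFitter(
            omega=5.0,
            tau_short_grid=(1e-1, 1.0, 10.0),
            tau_long_grid=(1e-3, 1e-2, 1e-1),
        ).fit(curve)
        assert a.params_.tau_short < a.params_.tau_long
        assert b.params_.tau_long == pytest.approx(a.params_.tau_long, rel=1e-4)
        assert b.params_.f_long == pytest.approx(a.params_.f_long, rel=1e-3)

    def test_refit_of_fitted_model_is_a_fixed_point(
        self, two_population_params, lag_grid
    ):
        noisy = generate_acf_curves(
            two_population_params,
            lag_grid,
            0.05 * evaluate_acf_model(two_population_params, lag_grid),
            1,
            seed=9,
        )[0]
        first = fit_acf(noisy, omega=5.0).params
        regenerated = generate_acf_curves(first, lag_grid, 0.0, 1, 0)[0]
        second = fit_acf(regenerated, omega=5.0).params
        assert second.tau_long == pytest.approx(first.tau_long, rel=1e-5)
        assert second.f_long == pytest.approx(first.f_long, rel=1e-4, abs=1e-7)

    def test_rejects_degenerate_curves(self, two_population_params):
        short = generate_acf_curves(
            two_population_params, np.geomspace(1e-4, 1e-3, 5), 0.0, 1, 0
        )[0]
        with pytest.raises(ValueError):
            fit_acf(short, omega=5.0)
        lags = np.geomspace(1e-5, 10, 40)
        negative = CorrelationCurve(lags=lags, g=-np.ones(40))
        with pytest.raises(ValueError):
            fit_acf(negative, omega=5.0)

    def test_sklearn_param_interface(self):
        fitter = AcfModelFitter(omega=3.0)
        assert fitter.get_params()["omega"] == 3.0
        fitter.set_params(omega=5.0, weights="uniform")
        assert fitter.omega == 5.0


class TestBootstrapSe:
    def test_constant_sample_has_zero_se(self):
        se, var = bootstrap_se(np.full(50, 3.14), np.median, 200, seed=0)
        assert se == 0.0 and var == 0.0

    def test_median_se_matches_asymptotic_formula(self):
        # SE of the sample median of n standard normals ~ 1.2533 / sqrt(n)
        rng = np.random.default_rng(5)
        sample = rng.standard_normal(400)
        se, var = bootstrap_se(sample, np.median, 2000, seed=1)
        assert se == pytest.approx(1.2533 / 20.0, rel=0.15)
        assert var == pytest.approx(se**2, rel=1e-12)

    def test_seeded_reproducibility(self):
        x = np.random.default_rng(2).standard_normal(60)
        assert bootstrap_se(x, np.median, 500, seed=7) == bootstrap_se(
            x, np.median, 500, seed=7
        )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bootstrap_se([], np.median, 100, 0)
        with pytest.raises(ValueError):
            bootstrap_se([1.0, 2.0], np.median, 1, 0)

    def test_non_vectorizable_statistic_falls_back_to_loop(self):
        x = np.random.default_rng(3).standard_normal(80)
        trimmed = lambda v: float(np.mean(np.sort(v)[5:-5]))  # noqa: E731
        se, _ = bootstrap_se(x, trimmed, 300, seed=4)
        assert 0.05 < se < 0.3
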