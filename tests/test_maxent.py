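"""Maximum-entropy moment fitting against closed-form densities."""

import logging

import numpy as np
import pytest

from dcemaxent.maxent import (
    KnownFunction,
    MaxEntSolveError,
    MomentConstraints,
    SolverSettings,
    Support,
    const,
    empirical_moments,
    evaluate_density,
    fit_aif_density,
    identity,
    log_fn,
    power,
    solve_maxent,
)
from dcemaxent.metrics import density_entropy, kl_divergence
from dcemaxent.synthetic_data import ConcentrationTimeSeries
from dcemaxent.weibull import WeibullParams, weibull_distribution

SOLVERS = ["dual_descent", "tlbo"]


class TestKnownFunction:
    def test_parse_round_trip(self):
        for text, expected in [
            ("const", const()),
            ("log", log_fn()),
            ("power:3", power(3.0)),
            ("power(2.5)", power(2.5)),
            ("identity", identity()),
        ]:
            assert KnownFunction.parse(text) == expected

    def test_power_requires_exponent(self):
        with pytest.raises(ValueError, match="exponent"):
            KnownFunction("power")

    def test_xlogx_zero_limit(self):
        fn = KnownFunction("xlogx")
        assert fn(np.array([0.0, 1.0, np.e]))[0] == 0.0
        assert fn(np.array([np.e]))[0] == pytest.approx(np.e)


class TestEmpiricalMoments:
    def test_identity_mean(self):
        mc = empirical_moments([1, 2, 3], [const(), identity()])
        assert mc.values[1] == pytest.approx(2.0)
        assert mc.values[0] == 1.0

    def test_log_of_ones(self):
        mc = empirical_moments([1, 1, 1], [const(), log_fn()])
        assert mc.values[1] == pytest.approx(0.0)

    def test_power_three(self):
        mc = empirical_moments([1, 2], [const(), power(3)])
        assert mc.values[1] == pytest.approx(4.5)

    def test_log_of_nonpositive_names_index(self):
        with pytest.raises(ValueError, match="index 1"):
            empirical_moments([1.0, -2.0, 3.0], [const(), log_fn()])


@pytest.mark.parametrize("solver", SOLVERS)
class TestClosedFormSolutions:
    def test_mean_constraint_gives_exponential(self, solver):
        # max-entropy with E[x]=2 on [0, 60] is Exp(rate 1/2):
        # lambda_1 = 0.5, lambda_0 = ln 2
        constraints = MomentConstraints([const(), identity()], [1.0, 2.0])
        density = solve_maxent(constraints, Support(0.0, 60.0), solver=solver)
        assert density.lambdas[1] == pytest.approx(0.5, abs=1e-4)
        assert density.lambdas[0] == pytest.approx(np.log(2.0), abs=1e-4)
        x = np.linspace(0, 60, 1501)
        assert np.max(np.abs(density.pdf(x) - 0.5 * np.exp(-0.5 * x))) < 1e-3
        assert evaluate_density(density, 0.0) == pytest.approx(0.5, abs=1e-3)

    def test_first_two_moments_give_standard_normal(self, solver):
        # E[x]=0, E[x^2]=1 on [-8, 8]: lambda = (0.5 ln 2pi, 0, 0.5)
        constraints = MomentConstraints([const(), identity(), power(2)], [1.0, 0.0, 1.0])
        density = solve_maxent(constraints, Support(-8.0, 8.0), solver=solver)
        assert density.lambdas[0] == pytest.approx(0.5 * np.log(2 * np.pi), abs=1e-4)
        assert density.lambdas[1] == pytest.approx(0.0, abs=1e-4)
        assert density.lambdas[2] == pytest.approx(0.5, abs=1e-4)
        x = np.linspace(-8, 8, 1501)
        target = np.exp(-0.5 * x**2) / np.sqrt(2 * np.pi)
        assert np.max(np.abs(density.pdf(x) - target)) < 1e-3

    def test_residuals_within_tolerance(self, solver):
        cfg = SolverSettings(tolerance=1e-6)
        constraints = MomentConstraints([const(), identity()], [1.0, 2.0])
        density = solve_maxent(constraints, Support(0.0, 60.0), solver=solver, solver_cfg=cfg)
        assert np.max(np.abs(density.diagnostics["residuals"])) <= 1e-6


def test_no_constraints_gives_uniform():
    density = solve_maxent(MomentConstraints([const()], [1.0]), Support(0.0, 1.0))
    assert evaluate_density(density, 0.5) == pytest.approx(1.0, abs=1e-9)
    assert evaluate_density(density, np.array([-0.1, 1.1])).tolist() == [0.0, 0.0]


def test_every_fitted_density_is_normalized():
    cases = [
        (MomentConstraints([const(), identity()], [1.0, 2.0]), Support(0.0, 60.0)),
        (MomentConstraints([const(), identity(), power(2)], [1.0, 0.0, 1.0]), Support(-8.0, 8.0)),
        (MomentConstraints([const(), log_fn(), power(3)], [1.0, 0.3, 4.0]), Support(1e-6, 5.0)),
    ]
    for constraints, support in cases:
        density = solve_maxent(constraints, support, solver="dual_descent")
        x = support.grid()
        h = x[1] - x[0]
        w = np.ones(x.size)
        w[1:-1:2], w[2:-1:2] = 4.0, 2.0
        assert float(density.pdf(x) @ w) * h / 3.0 == pytest.approx(1.0, abs=1e-6)


def test_entropy_never_increases_with_added_constraints():
    # nested constraint sets on the same sample and support
    rng = np.random.default_rng(5)
    samples = rng.gamma(3.0, 0.5, size=2000)
    support = Support(1e-6, 1.5 * samples.max())
    sets = [
        [const()],
        [const(), identity()],
        [const(), identity(), log_fn()],
        [const(), identity(), log_fn(), power(2)],
    ]
    entropies = []
    for functions in sets:
        density = solve_maxent(empirical_moments(samples, functions), support, solver="dual_descent")
        entropies.append(density_entropy(density.pdf, support))
    assert all(a >= b - 1e-9 for a, b in zip(entropies, entropies[1:]))


def test_infeasible_constraints_fail_with_residuals():
    # E[x] = 100 is unattainable on [0, 1]
    constraints = MomentConstraints([const(), identity()], [1.0, 100.0])
    cfg = SolverSettings(max_iterations=100, newton_max_iterations=50)
    with pytest.raises(MaxEntSolveError) as err:
        solve_maxent(constraints, Support(0.0, 1.0), solver="dual_descent", solver_cfg=cfg)
    assert err.value.residuals.shape == (1,)
    assert np.max(np.abs(err.value.residuals)) > 1.0
    assert err.value.density is not None


def test_log_function_requires_positive_support():
    constraints = MomentConstraints([const(), log_fn()], [1.0, 0.0])
    with pytest.raises(ValueError, match="positive support"):
        solve_maxent(constraints, Support(-1.0, 1.0))


class TestFitAIFDensity:
    def test_value_density_recovers_generating_weibull(self):
        # i.i.d. Weibull(2.6, 1.738) values under {const, log, x^3}:
        # the fitted exponential-family density should be KL-close to truth
        truth = weibull_distribution(WeibullParams(2.6, 1.738))
        samples = truth.sample(2000, seed=1)
        curve = ConcentrationTimeSeries("p", np.arange(samples.size) * 0.01, samples)
        density, estimate = fit_aif_density(curve, solver="dual_descent")
        assert kl_divergence(density.pdf, truth.pdf, density.support) < 0.05
        assert len(estimate) == len(curve)

    def test_constant_curve_time_density_is_flat(self):
        curve = ConcentrationTimeSeries("p", np.linspace(0, 9, 46), np.full(46, 2.0))
        density, estimate = fit_aif_density(curve, functions=[const()], mode="time_density")
        assert np.ptp(estimate.values) < 1e-3 * np.mean(estimate.values)

    def test_zero_values_excluded_under_log(self, caplog):
        values = np.r_[0.0, np.linspace(0.5, 2.0, 30)]
        curve = ConcentrationTimeSeries("p", np.arange(values.size) * 0.2, values)
        with caplog.at_level(logging.INFO):
            density, _ = fit_aif_density(curve, solver="dual_descent")
        assert density.diagnostics["n_excluded_zero"] >= 1
        assert any("excluded" in message for message in caplog.messages)

    def test_estimate_rescaled_to_curve_area(self, default_aif_curve):
        _, estimate = fit_aif_density(default_aif_curve, solver="dual_descent")
        area_in = np.trapezoid(default_aif_curve.values, default_aif_curve.times)
        area_out = np.trapezoid(estimate.values, estimate.times)
        assert area_out == pytest.approx(area_in, rel=1e-9)

    def test_density_serializes_to_json(self, default_aif_curve):
        density, _ = fit_aif_density(default_aif_curve, solver="dual_descent")
        import json

        payload = json.loads(density.to_json())
        assert payload["functions"] == ["const", "log", "power(3)"]
        assert len(payload["lambdas"]) == 3
        assert "residuals" in payload["diagnostics"]
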