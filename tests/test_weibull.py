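"""Weibull distribution utilities and the six parameter-estimation routes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcemaxent.weibull import (
    BinnedSample,
    WeibullParams,
    bin_samples,
    estimate_all,
    fit_empirical,
    fit_mle,
    fit_mmle,
    fit_moments,
    fit_nlsm,
    weibull_distribution,
    weibull_from_lambdas,
    weibull_lambda_map,
)

TRUTH = WeibullParams(k=2.0, c=1.0)


class TestDistribution:
    def test_exponential_special_case_mean(self):
        assert weibull_distribution(WeibullParams(1.0, 2.0)).mean == pytest.approx(2.0)

    def test_pdf_value(self):
        dist = weibull_distribution(WeibullParams(2.0, 1.0))
        assert dist.pdf(1.0) == pytest.approx(2.0 * math.exp(-1.0))

    @pytest.mark.parametrize("k", [0.7, 1.0, 2.0, 3.5])
    def test_cdf_at_scale_is_universal(self, k):
        dist = weibull_distribution(WeibullParams(k, 1.3))
        assert dist.cdf(1.3) == pytest.approx(1.0 - math.exp(-1.0))

    def test_entropy_of_unit_exponential(self):
        assert weibull_distribution(WeibullParams(1.0, 1.0)).entropy == pytest.approx(1.0)

    def test_seeded_sampling_reproducible(self):
        dist = weibull_distribution(TRUTH)
        assert np.array_equal(dist.sample(100, seed=3), dist.sample(100, seed=3))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            WeibullParams(-1.0, 1.0)
        with pytest.raises(ValueError):
            WeibullParams(1.0, 0.0)


class TestEmpiricalMethod:
    def test_unit_cv_gives_shape_one(self):
        # two-point sample {1, 3 + 2 sqrt 2} has sd/mean = 1 exactly
        params = fit_empirical(np.array([1.0, 3.0 + 2.0 * math.sqrt(2.0)]))
        assert params.k == pytest.approx(1.0, abs=1e-12)
        assert params.c == pytest.approx(2.0 + math.sqrt(2.0), abs=1e-10)

    def test_one_two_three(self):
        params = fit_empirical(np.array([1.0, 2.0, 3.0]))
        assert params.k == pytest.approx(2.1230, abs=2e-4)
        assert params.c == pytest.approx(2.2582, abs=2e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_empirical(np.array([2.0, 2.0, 2.0]))


class TestMethodOfMoments:
    def test_analytic_moments_round_trip(self):
        dist = weibull_distribution(WeibullParams(3.0, 2.0))
        params = fit_moments(mean=dist.mean, sd=dist.sd)
        assert params.k == pytest.approx(3.0, abs=1e-8)
        assert params.c == pytest.approx(2.0, abs=1e-8)

    def test_unit_cv_gives_shape_one(self):
        params = fit_moments(mean=1.0, sd=1.0)
        assert params.k == pytest.approx(1.0, abs=1e-9)

    def test_sampling_recovery(self):
        samples = weibull_distribution(WeibullParams(2.6, 1.738)).sample(10_000, seed=0)
        params = fit_moments(samples)
        assert params.k == pytest.approx(2.6, rel=0.05)
        assert params.c == pytest.approx(1.738, rel=0.05)

    def test_unattainable_cv_rejected(self):
        with pytest.raises(ValueError, match="attainable"):
            fit_moments(mean=1.0, sd=1e4)


class TestMLE:
    def test_sampling_recovery(self):
        samples = weibull_distribution(TRUTH).sample(10_000, seed=1)
        params = fit_mle(samples)
        assert 1.9 <= params.k <= 2.1
        assert params.c == pytest.approx(1.0, rel=0.05)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_mle(np.full(10, 3.0))

    def test_agrees_with_moments_at_large_n(self):
        samples = weibull_distribution(TRUTH).sample(20_000, seed=2)
        mle = fit_mle(samples)
        mom = fit_moments(samples)
        assert mle.k == pytest.approx(mom.k, rel=0.05)
        assert mle.c == pytest.approx(mom.c, rel=0.02)


class TestMMLE:
    def test_binned_recovery(self):
        samples = weibull_distribution(TRUTH).sample(20_000, seed=3)
        params = fit_mmle(bin_samples(samples, 50))
        assert params.k == pytest.approx(2.0, rel=0.10)
        assert params.c == pytest.approx(1.0, rel=0.10)

    def test_binned_close_to_unbinned_mle(self):
        samples = weibull_distribution(TRUTH).sample(20_000, seed=4)
        binned = fit_mmle(bin_samples(samples, 50))
        unbinned = fit_mle(samples)
        assert abs(binned.k - unbinned.k) / unbinned.k < 0.05
        assert abs(binned.c - unbinned.c) / unbinned.c < 0.05

    def test_frequency_rescaling_invariance(self):
        samples = weibull_distribution(TRUTH).sample(2_000, seed=5)
        binned = bin_samples(samples, 30)
        doubled = BinnedSample(
            binned.bin_centers, 2.0 * binned.frequencies, 2.0 * binned.p_nonneg
        )
        a, b = fit_mmle(binned), fit_mmle(doubled)
        assert a.k == pytest.approx(b.k, rel=1e-12)
        assert a.c == pytest.approx(b.c, rel=1e-12)

    def test_single_effective_bin_rejected(self):
        binned = BinnedSample(np.array([1.0, 2.0]), np.array([1.0, 0.0]), 1.0)
        with pytest.raises(ValueError, match="2 bins"):
            fit_mmle(binned)


class TestNLSM:
    def test_exact_plotting_position_points_recovered(self):
        # samples placed exactly at the CDF inverse of the Benard positions
        # make the least-squares residual vanish at the true parameters
        truth = weibull_distribution(WeibullParams(2.5, 1.2))
        n = 200
        prob = (np.arange(1, n + 1) - 0.3) / (n + 0.4)
        x = truth._frozen.ppf(prob)
        params = fit_nlsm(x)
        assert params.k == pytest.approx(2.5, abs=1e-6)
        assert params.c == pytest.approx(1.2, abs=1e-6)

    def test_sampling_recovery(self):
        samples = weibull_distribution(TRUTH).sample(10_000, seed=6)
        params = fit_nlsm(samples)
        assert params.k == pytest.approx(2.0, rel=0.10)
        assert params.c == pytest.approx(1.0, rel=0.10)

    def test_permutation_invariance(self):
        samples = weibull_distribution(TRUTH).sample(500, seed=7)
        shuffled = samples[np.random.default_rng(0).permutation(samples.size)]
        a, b = fit_nlsm(samples), fit_nlsm(shuffled)
        assert a.k == b.k and a.c == b.c


class TestLambdaMap:
    def test_worked_example_multipliers(self):
        lam0, lam1, lam2 = weibull_lambda_map(WeibullParams(3.0, 1.8498))
        assert lam0 == pytest.approx(0.7466, abs=5e-5)
        assert lam1 == pytest.approx(-2.0)
        assert lam2 == pytest.approx(0.1580, abs=5e-5)

    def test_unit_exponential(self):
        assert weibull_lambda_map(WeibullParams(1.0, 1.0)) == pytest.approx((0.0, 0.0, 1.0))

    @settings(deadline=None, derandomize=True)
    @given(
        k=st.floats(0.3, 8.0, allow_nan=False),
        c=st.floats(0.1, 10.0, allow_nan=False),
    )
    def test_round_trip_is_identity(self, k, c):
        params = WeibullParams(k, c)
        _, lam1, lam2 = weibull_lambda_map(params)
        back = weibull_from_lambdas(lam1, lam2)
        assert back.k == pytest.approx(k, rel=1e-12)
        assert back.c == pytest.approx(c, rel=1e-12)

    def test_mapped_density_equals_weibull_pdf(self):
        params = WeibullParams(3.0, 1.8498)
        lam0, lam1, lam2 = weibull_lambda_map(params)
        x = np.linspace(0.01, 10.0, 5001)
        mapped = np.exp(-lam0 - lam1 * np.log(x) - lam2 * x**params.k)
        assert np.max(np.abs(mapped - weibull_distribution(params).pdf(x))) < 1e-12

    def test_inverse_rejects_inadmissible_multipliers(self):
        with pytest.raises(ValueError, match="shape"):
            weibull_from_lambdas(1.5, 1.0)
        with pytest.raises(ValueError, match="lambda2"):
            weibull_from_lambdas(-1.0, -0.2)


@pytest.mark.parametrize("scale", [0.25, 4.0])
def test_all_estimators_scale_equivariant(scale):
    samples = weibull_distribution(TRUTH).sample(4_000, seed=8)
    routes = [
        fit_empirical,
        fit_moments,
        fit_mle,
        lambda s: fit_mmle(bin_samples(s, 40)),
        fit_nlsm,
    ]
    for route in routes:
        base = route(samples)
        scaled = route(samples * scale)
        assert scaled.k == pytest.approx(base.k, rel=1e-6)
        assert scaled.c == pytest.approx(base.c * scale, rel=1e-6)


def test_estimate_all_produces_comparison_rows():
    samples = weibull_distribution(TRUTH).sample(2_000, seed=9)
    rows = estimate_all(samples)
    assert [r["method"] for r in rows] == ["EM", "MOM", "MLE", "MMLE", "NLSM"]
    assert all(np.isfinite(r["k"]) and np.isfinite(r["c"]) for r in rows)
    assert all(r["n"] == 2000 for r in rows)
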