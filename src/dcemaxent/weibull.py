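"""Weibull distribution utilities and parameter estimators.

The two-parameter Weibull pdf with shape k and scale c is

    f(x) = (k / c**k) x**(k-1) exp(-(x/c)**k),  x > 0.

Six estimation routes are provided, as commonly compared in wind-speed and
reliability work: the empirical (power-law) method, method of moments,
maximum likelihood (MLE), modified maximum likelihood for binned data
(MMLE), nonlinear least squares on the CDF (NLSM), and — specific to the
maximum-entropy route — the exact algebraic mapping between (k, c) and the
Lagrange multipliers of the exponential-family form

    f(x) = exp(-lambda0 - lambda1 * log x - lambda2 * x**k),

with lambda0 = -log(k c**-k), lambda1 = -(k-1), lambda2 = c**-k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.special import gamma as gamma_fn
from scipy.stats import weibull_min

__all__ = [
    "WeibullParams",
    "BinnedSample",
    "WeibullDistribution",
    "weibull_distribution",
    "fit_empirical",
    "fit_moments",
    "fit_mle",
    "fit_mmle",
    "fit_nlsm",
    "bin_samples",
    "weibull_lambda_map",
    "weibull_from_lambdas",
    "estimate_all",
]

EULER_GAMMA = 0.5772156649015329


@dataclass(frozen=True)
class WeibullParams:
    """Shape k (dimensionless) and scale c (units of the variable)."""

    k: float
    c: float

    def __post_init__(self) -> None:
        if self.k <= 0 or self.c <= 0:
            raise ValueError(f"Weibull parameters must be positive, got {self}")


@dataclass
class BinnedSample:
    """Frequency-distribution form of a sample.

    ``frequencies`` are the probability masses of the bin centers;
    ``p_nonneg`` is the total mass at non-negative values, P(x >= 0). The
    MMLE equations depend only on frequency *ratios*, so any common positive
    rescaling of (frequencies, p_nonneg) is equivalent.
    """

    bin_centers: np.ndarray
    frequencies: np.ndarray
    p_nonneg: float

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.bin_centers.size != self.frequencies.size:
            raise ValueError("bin_centers and frequencies must have equal length")
        if np.any(self.frequencies < 0):
            raise ValueError("frequencies must be non-negative")
        if self.p_nonneg <= 0:
            raise ValueError("p_nonneg must be positive")


class WeibullDistribution:
    """Weibull(k, c) with pdf/cdf, moments, entropy and seeded sampling."""

    def __init__(self, params: WeibullParams):
        self.params = params
        self._frozen = weibull_min(params.k, scale=params.c)

    def pdf(self, x):
        return self._frozen.pdf(x)

    def cdf(self, x):
        return self._frozen.cdf(x)

    @property
    def mean(self) -> float:
        return self.params.c * gamma_fn(1.0 + 1.0 / self.params.k)

    @property
    def sd(self) -> float:
        k, c = self.params.k, self.params.c
        return c * math.sqrt(gamma_fn(1.0 + 2.0 / k) - gamma_fn(1.0 + 1.0 / k) ** 2)

    @property
    def entropy(self) -> float:
        """Differential entropy in nats: gamma*(1 - 1/k) + ln(c/k) + 1."""
        k, c = self.params.k, self.params.c
        return EULER_GAMMA * (1.0 - 1.0 / k) + math.log(c / k) + 1.0

    def sample(self, n: int, seed: int = 0) -> np.ndarray:
        return self._frozen.rvs(size=n, random_state=np.random.default_rng(seed))


def weibull_distribution(params: WeibullParams) -> WeibullDistribution:
    return WeibullDistribution(params)


def _check_samples(samples: np.ndarray, min_n: int = 2) -> np.ndarray:
    samples = np.asarray(samples, dtype=float)
    if samples.size < min_n:
        raise ValueError(f"need at least {min_n} samples")
    if np.any(samples <= 0):
        raise ValueError("Weibull samples must be strictly positive")
    return samples


def fit_empirical(samples: np.ndarray) -> WeibullParams:
    """Empirical (power-law) method: k = (sigma/mean)**-1.086, then c from the mean.

    Uses the n-1 sample standard deviation.
    """
    samples = _check_samples(samples)
    mean = float(np.mean(samples))
    sd = float(np.std(samples, ddof=1))
    if sd == 0:
        raise ValueError("zero sample variance: shape parameter undefined")
    k = (sd / mean) ** (-1.086)
    return WeibullParams(k=k, c=mean / gamma_fn(1.0 + 1.0 / k))


def _cv_of_shape(k: float) -> float:
    """Coefficient of variation of Weibull with shape k (scale-free)."""
    g1 = gamma_fn(1.0 + 1.0 / k)
    g2 = gamma_fn(1.0 + 2.0 / k)
    return math.sqrt(max(g2 - g1 * g1, 0.0)) / g1


def fit_moments(
    samples: np.ndarray | None = None,
    mean: float | None = None,
    sd: float | None = None,
) -> WeibullParams:
    """Method of moments: solve the exact CV equation for k, then c from the mean.

    Either pass a sample or the (mean, sd) pair directly. The shape is found
    by bracketed root-finding of CV(k) = sd/mean on k in [0.1, 50].
    """
    if samples is not None:
        samples = _check_samples(samples)
        mean = float(np.mean(samples))
        sd = float(np.std(samples, ddof=1))
    if mean is None or sd is None:
        raise ValueError("provide either samples or both mean and sd")
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    cv = sd / mean
    lo, hi = 0.1, 50.0
    cv_lo, cv_hi = _cv_of_shape(lo), _cv_of_shape(hi)
    if not (cv_hi <= cv <= cv_lo):
        raise ValueError(
            f"coefficient of variation {cv:.4g} outside the attainable range "
            f"[{cv_hi:.4g}, {cv_lo:.4g}] for shape in [{lo}, {hi}]"
        )
    k = brentq(lambda kk: _cv_of_shape(kk) - cv, lo, hi, xtol=1e-12)
    return WeibullParams(k=k, c=mean / gamma_fn(1.0 + 1.0 / k))


def fit_mle(samples: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> WeibullParams:
    """Maximum likelihood by fixed-point iteration on the profile equation

        1/k = sum(x^k ln x)/sum(x^k) - mean(ln x),

    then c = (mean(x^k))**(1/k). Raises on non-convergence, reporting the
    last iterate.
    """
    samples = _check_samples(samples)
    if float(np.max(samples)) == float(np.min(samples)):
        raise ValueError("degenerate sample (all values equal): likelihood unbounded")
    log_x = np.log(samples)
    mean_log = float(np.mean(log_x))
    k = fit_empirical(samples).k  # moment-style starting value
    for _ in range(max_iter):
        xk = samples**k
        denom = float(np.sum(xk * log_x) / np.sum(xk)) - mean_log
        if denom <= 0:
            raise ValueError(f"MLE iteration left the admissible region at k={k:.4g}")
        k_new = 1.0 / denom
        if abs(k_new - k) < tol:
            k = k_new
            break
        k = k_new
    else:
        raise RuntimeError(f"MLE did not converge within {max_iter} iterations; last k={k:.6g}")
    c = float(np.mean(samples**k)) ** (1.0 / k)
    return WeibullParams(k=k, c=c)


def fit_mmle(binned: BinnedSample, tol: float = 1e-10, max_iter: int = 500) -> WeibullParams:
    """Modified maximum likelihood for frequency data.

    Iterates 1/k = sum(x^k ln x P)/sum(x^k P) - sum(ln x P)/P(x>=0) over the
    positive-frequency bins, then c = (sum(x^k P)/P(x>=0))**(1/k). Invariant
    to a common rescaling of frequencies and p_nonneg.
    """
    mask = binned.frequencies > 0
    x = binned.bin_centers[mask]
    p = binned.frequencies[mask]
    if x.size < 2:
        raise ValueError("need at least 2 bins with positive frequency")
    if np.any(x <= 0):
        raise ValueError("bin centers must be strictly positive")
    log_x = np.log(x)
    weighted_mean_log = float(np.sum(log_x * p)) / binned.p_nonneg
    k = 2.0
    for _ in range(max_iter):
        xk = x**k
        denom = float(np.sum(xk * log_x * p) / np.sum(xk * p)) - weighted_mean_log
        if denom <= 0:
            raise ValueError(f"MMLE iteration left the admissible region at k={k:.4g}")
        k_new = 1.0 / denom
        if abs(k_new - k) < tol:
            k = k_new
            break
        k = k_new
    else:
        raise RuntimeError(f"MMLE did not converge within {max_iter} iterations; last k={k:.6g}")
    c = (float(np.sum(x**k * p)) / binned.p_nonneg) ** (1.0 / k)
    return WeibullParams(k=k, c=c)


def bin_samples(samples: np.ndarray, n_bins: int = 50) -> BinnedSample:
    """Histogram a positive sample into the frequency form used by MMLE."""
    samples = _check_samples(samples)
    counts, edges = np.histogram(samples, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    frequencies = counts / samples.size
    return BinnedSample(bin_centers=centers, frequencies=frequencies, p_nonneg=float(frequencies.sum()))


def fit_nlsm(samples: np.ndarray) -> WeibullParams:
    """Nonlinear least squares on the CDF against plotting positions.

    Samples are sorted ascending and paired with Benard's median-rank
    failure probabilities F_i = (i - 0.3)/(n + 0.4); the Weibull CDF is then
    fitted by damped Gauss-Newton (Levenberg-Marquardt) in log-parameters,
    which keeps (k, c) positive.
    """
    samples = _check_samples(samples, min_n=3)
    x = np.sort(samples)
    n = x.size
    prob = (np.arange(1, n + 1) - 0.3) / (n + 0.4)
    start = fit_empirical(x)

    def residual(theta: np.ndarray) -> np.ndarray:
        k, c = np.exp(theta)
        return weibull_min.cdf(x, k, scale=c) - prob

    result = least_squares(residual, x0=np.log([start.k, start.c]), method="lm", xtol=1e-14, ftol=1e-14)
    if not result.success:
        raise RuntimeError(f"Gauss-Newton did not converge: {result.message}; cost history final {result.cost:.3e}")
    k, c = np.exp(result.x)
    return WeibullParams(k=float(k), c=float(c))


def weibull_lambda_map(params: WeibullParams) -> tuple[float, float, float]:
    """Map (k, c) to the maximum-entropy multipliers (lambda0, lambda1, lambda2).

    With the constraint functions {1, log x, x**k}:
    lambda0 = -log(k c**-k), lambda1 = -(k - 1), lambda2 = c**-k.
    """
    k, c = params.k, params.c
    return (-math.log(k) + k * math.log(c), -(k - 1.0), c ** (-k))


def weibull_from_lambdas(lambda1: float, lambda2: float) -> WeibullParams:
    """Inverse mapping: k = 1 - lambda1, c = lambda2**(-1/k).

    (lambda0 is redundant — it is pinned by normalization.)
    """
    k = 1.0 - lambda1
    if k <= 0:
        raise ValueError(f"lambda1 = {lambda1} implies non-positive shape k = {k}")
    if lambda2 <= 0:
        raise ValueError(f"lambda2 must be positive, got {lambda2}")
    return WeibullParams(k=k, c=lambda2 ** (-1.0 / k))


def estimate_all(samples: np.ndarray, n_bins: int = 50) -> list[dict]:
    """Run every data-driven estimator on one sample; comparison-table rows.

    Returns one record per method with keys {method, k, c, n}; individual
    failures are reported in an ``error`` field rather than aborting the
    comparison.
    """
    samples = np.asarray(samples, dtype=float)
    routes = {
        "EM": lambda s: fit_empirical(s),
        "MOM": lambda s: fit_moments(s),
        "MLE": lambda s: fit_mle(s),
        "MMLE": lambda s: fit_mmle(bin_samples(s, n_bins)),
        "NLSM": lambda s: fit_nlsm(s),
    }
    rows = []
    for method, route in routes.items():
        row = {"method": method, "n": int(samples.size)}
        try:
            params = route(samples)
            row.update(k=params.k, c=params.c)
        except (ValueError, RuntimeError) as exc:
            row.update(k=math.nan, c=math.nan, error=str(exc))
        rows.append(row)
    return rows
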