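"""Goodness-of-fit metrics for fitted densities and curves.

Covers the Kullback-Leibler divergence between densities, curve-level error
metrics (MAE, RMSE, reduced chi-square, R^2, adjusted R^2), and the
differential Shannon entropy of a density. All logarithms are natural, so
entropy and KL values are in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .maxent import Support

__all__ = ["FitReport", "kl_divergence", "fit_metrics", "density_entropy"]

_QUAD_POINTS = 2001


def _simpson_weights(x: np.ndarray) -> np.ndarray:
    h = x[1] - x[0]
    w = np.ones(x.size)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * (h / 3.0)


@dataclass
class FitReport:
    """Bundle of fit metrics; entries that are undefined for the input are None."""

    mae: float
    rmse: float
    chi_square: float | None
    r2: float
    adj_r2: float | None
    kl_divergence: float | None = None
    entropy: float | None = None

    def as_dict(self) -> dict:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "chi_square": self.chi_square,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "kl_divergence": self.kl_divergence,
            "entropy": self.entropy,
        }


def kl_divergence(
    f: Callable[[np.ndarray], np.ndarray],
    g: Callable[[np.ndarray], np.ndarray],
    support: Support,
    n_points: int = _QUAD_POINTS,
) -> float:
    """D_KL(f || g) = integral f log(f/g) over the support, by Simpson quadrature.

    Points where f = 0 contribute nothing; if g = 0 (below quadrature
    resolution) where f > 0 the divergence is reported as +inf. Small
    negative quadrature results (within 1e-8) are clamped to 0.
    """
    x = support.grid(n_points)
    w = _simpson_weights(x)
    fx = np.asarray(f(x), dtype=float)
    gx = np.asarray(g(x), dtype=float)
    active = fx > 0
    if np.any(gx[active] <= 0):
        return math.inf
    integrand = np.zeros_like(fx)
    integrand[active] = fx[active] * np.log(fx[active] / gx[active])
    value = float(integrand @ w)
    if value < 0:
        if value > -1e-8:
            return 0.0
    return value


def fit_metrics(predicted: np.ndarray, observed: np.ndarray, n_params: int = 0) -> FitReport:
    """Error metrics between predicted and observed vectors.

    RMSE = sqrt(mean squared error); chi^2 = SSE / (m - n_params) (the
    reduced form); R^2 = 1 - SSE/SST; adjusted R^2 applies the
    (m-1)/(m-n_params-1) correction. chi^2 and adjusted R^2 are None when
    m <= n_params (respectively m <= n_params + 1).
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.size != observed.size:
        raise ValueError("predicted and observed must have equal length")
    m = observed.size
    if m == 0:
        raise ValueError("empty input")
    residuals = observed - predicted
    sse = float(residuals @ residuals)
    mae = float(np.mean(np.abs(residuals)))
    rmse = math.sqrt(sse / m)
    sst = float(np.sum((observed - observed.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -math.inf)
    chi_square = sse / (m - n_params) if m > n_params else None
    adj_r2 = (
        1.0 - (1.0 - r2) * (m - 1) / (m - n_params - 1) if m > n_params + 1 else None
    )
    return FitReport(mae=mae, rmse=rmse, chi_square=chi_square, r2=r2, adj_r2=adj_r2)


def density_entropy(
    d: Callable[[np.ndarray], np.ndarray], support: Support, n_points: int = _QUAD_POINTS
) -> float:
    """Differential Shannon entropy -integral d log d (nats) by quadrature.

    Rejects densities that do not integrate to 1 within 1e-4 on the support.
    """
    x = support.grid(n_points)
    w = _simpson_weights(x)
    dx = np.asarray(d(x), dtype=float)
    total = float(dx @ w)
    if abs(total - 1.0) > 1e-4:
        raise ValueError(f"density integrates to {total:.6f} on the support, not 1")
    active = dx > 0
    integrand = np.zeros_like(dx)
    integrand[active] = dx[active] * np.log(dx[active])
    return -float(integrand @ w)
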