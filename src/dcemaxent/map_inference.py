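"""Bayesian MAP estimation of the kinetic rate constants.

For the linearized kinetic system y = A K + eps with white Gaussian noise of
variance sigma^2, the negative log posterior (up to constants) is

    T(K) + alpha * S(K),
    T(K) = ||y - A K||^2 / sigma^2,
    S(K) = sum_j K_j log K_j     (negative entropy; 0 log 0 := 0),

i.e. a Gaussian likelihood with a maximum-entropy regularizer on the
non-negative rates — the classic entropy prior of regularized image
reconstruction. alpha = 0 reduces the MAP point to the (non-negative,
bounded) least-squares solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import minimize

from .kinetics import DesignMatrix, KineticParams, llsq_fit
from .tlbo import TLBOConfig, tlbo_minimize

__all__ = ["MAPConfig", "MAPFit", "neg_log_posterior", "map_fit", "estimate_sigma2"]

_LOG_FLOOR = 1e-300  # argument floor inside x log x gradients


@dataclass
class MAPConfig:
    """Settings for the MAP fit.

    ``sigma2`` is the noise variance in mM^2, or ``"estimate"`` to take it
    from the residuals of an initial LLSQ pass. ``alpha`` weights the
    entropy prior (0 = pure least squares). ``bounds`` is the admissible box
    for (K1, K2) in 1/min.
    """

    sigma2: float | Literal["estimate"] = "estimate"
    alpha: float = 0.01
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 10.0), (0.0, 10.0))
    optimizer: Literal["bounded_quasi_newton", "tlbo"] = "bounded_quasi_newton"
    seed: int = 0
    tlbo_population: int = 30
    tlbo_iterations: int = 300

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        for lo, hi in self.bounds:
            if lo < 0 or lo >= hi:
                raise ValueError("bounds must satisfy 0 <= lower < upper")
        if self.sigma2 != "estimate" and float(self.sigma2) <= 0:
            raise ValueError("sigma2 must be positive")


@dataclass
class MAPFit:
    """MAP point estimate with fit diagnostics."""

    params: KineticParams
    posterior: float
    sigma2: float
    alpha: float
    converged: bool
    optimizer: str
    llsq_k: tuple[float, float]


def _neg_entropy(k: np.ndarray) -> float:
    """S(K) = sum K_j log K_j with the 0 log 0 = 0 convention."""
    k = np.asarray(k, dtype=float)
    return float(np.sum(np.where(k > 0, k * np.log(np.maximum(k, _LOG_FLOOR)), 0.0)))


def neg_log_posterior(
    k: KineticParams | np.ndarray,
    design: DesignMatrix,
    y: np.ndarray,
    cfg: MAPConfig,
    sigma2: float | None = None,
) -> float:
    """T(K) + alpha * S(K); ``sigma2`` must be numeric here (pass it when
    cfg.sigma2 = "estimate")."""
    vec = np.array([k.k1, k.k2]) if isinstance(k, KineticParams) else np.asarray(k, dtype=float)
    s2 = sigma2 if sigma2 is not None else cfg.sigma2
    if s2 == "estimate":
        raise ValueError("sigma2 = 'estimate' must be resolved to a number before evaluation")
    s2 = float(s2)
    if s2 <= 0:
        raise ValueError("sigma2 must be positive")
    residual = np.asarray(y, dtype=float) - design.rows @ vec
    return float(residual @ residual) / s2 + cfg.alpha * _neg_entropy(vec)


def estimate_sigma2(design: DesignMatrix, y: np.ndarray) -> float:
    """Noise-variance estimate from LLSQ residuals: RSS / (m - 2)."""
    fit = llsq_fit(design, y)
    m = len(np.asarray(y))
    return max(fit.residual_norm**2 / max(m - 2, 1), 1e-12)


def map_fit(design: DesignMatrix, y: np.ndarray, cfg: MAPConfig | None = None) -> MAPFit:
    """Minimize the negative log posterior over the non-negative box.

    Deterministic given ``cfg`` (and its seed when the TLBO optimizer is
    chosen). The quasi-Newton route starts from the LLSQ solution projected
    into the bounds and uses the analytic gradient.
    """
    cfg = cfg or MAPConfig()
    y = np.asarray(y, dtype=float)
    llsq = llsq_fit(design, y)
    sigma2 = estimate_sigma2(design, y) if cfg.sigma2 == "estimate" else float(cfg.sigma2)
    a = design.rows
    ata = a.T @ a
    aty = a.T @ y
    lower = np.array([b[0] for b in cfg.bounds])
    upper = np.array([b[1] for b in cfg.bounds])

    def objective(vec: np.ndarray) -> float:
        residual = y - a @ vec
        return float(residual @ residual) / sigma2 + cfg.alpha * _neg_entropy(vec)

    def gradient(vec: np.ndarray) -> np.ndarray:
        grad = 2.0 * (ata @ vec - aty) / sigma2
        if cfg.alpha > 0:
            grad = grad + cfg.alpha * (np.log(np.maximum(vec, _LOG_FLOOR)) + 1.0)
        return grad

    if cfg.optimizer == "bounded_quasi_newton":
        start = np.clip([llsq.k1, llsq.k2], lower, upper)
        result = minimize(
            objective,
            start,
            jac=gradient,
            method="L-BFGS-B",
            bounds=cfg.bounds,
            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
        )
        solution, converged = result.x, bool(result.success)
    elif cfg.optimizer == "tlbo":
        tlbo_cfg = TLBOConfig(
            bounds=cfg.bounds,
            population_size=cfg.tlbo_population,
            max_iterations=cfg.tlbo_iterations,
            seed=cfg.seed,
        )
        tlbo_result = tlbo_minimize(objective, tlbo_cfg)
        # local polish inside the box from the TLBO incumbent
        result = minimize(
            objective, tlbo_result.best_solution, jac=gradient, method="L-BFGS-B",
            bounds=cfg.bounds, options={"ftol": 1e-15, "gtol": 1e-12},
        )
        solution, converged = result.x, bool(result.success)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")

    solution = np.clip(solution, lower, upper)
    return MAPFit(
        params=KineticParams(k1=float(solution[0]), k2=float(solution[1])),
        posterior=objective(solution),
        sigma2=sigma2,
        alpha=cfg.alpha,
        converged=converged,
        optimizer=cfg.optimizer,
        llsq_k=(llsq.k1, llsq.k2),
    )
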