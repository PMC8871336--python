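"""Two-compartment contrast-agent kinetics.

The tissue concentration Ctis(t) follows the exchange model

    dCtis/dt = K1 * Cp(t) - K2 * Ctis(t),    Ctis(0) = 0,

whose solution is the exponential convolution
Ctis(t) = K1 * integral_0^t Cp(u) exp(-K2 (t - u)) du. K1 and K2 (1/min) are
the transfer rate constants between plasma and the extravascular-
extracellular space.

Integrating the ODE once turns it into a relation that is *linear* in
(K1, K2) — the Murase formulation:

    Ctis(t_i) = K1 * int_0^{t_i} Cp - K2 * int_0^{t_i} Ctis,

so stacking the cumulative (trapezoid-rule) integrals row-wise gives a
design matrix A with C = A [K1, K2]', solvable by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .synthetic_data import ConcentrationTimeSeries

__all__ = [
    "KineticParams",
    "DesignMatrix",
    "LLSQResult",
    "exp_convolve_linear",
    "tissue_response",
    "murase_design_matrix",
    "llsq_fit",
]


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the two-compartment model, in 1/min."""

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError(f"rate constants must be non-negative, got {self}")


@dataclass
class DesignMatrix:
    """n x 2 matrix of cumulative integrals for the linearized kinetic model.

    Column 1 holds the running trapezoid integral of Cp, column 2 minus the
    running integral of Ctis; the first row is zero when integration starts
    at the first sample.
    """

    rows: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[1] != 2:
            raise ValueError("design matrix must be n x 2")
        if self.rows.shape[0] != self.times.size:
            raise ValueError("one row per time point required")


def exp_convolve_linear(times: np.ndarray, values: np.ndarray, rate: float) -> np.ndarray:
    """integral_0^t values(u) * exp(-rate (t-u)) du for piecewise-linear values.

    Exact for a piecewise-linear integrand, via the O(n) recursion
    y_{i+1} = y_i * exp(-rate*dt) + (segment integral in closed form); stable
    for any rate >= 0, with the rate -> 0 limit handled analytically.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    out = np.zeros_like(values)
    for i in range(times.size - 1):
        dt = times[i + 1] - times[i]
        c0, c1 = values[i], values[i + 1]
        slope = (c1 - c0) / dt
        if rate > 0:
            decay = np.exp(-rate * dt)
            j0 = (1.0 - decay) / rate
            j1 = (dt - j0) / rate  # integral of v * exp(-rate(dt - v)) dv on [0, dt]
            segment = c0 * j0 + slope * j1
        else:
            decay = 1.0
            segment = c0 * dt + slope * dt * dt / 2.0
        out[i + 1] = out[i] * decay + segment
    return out


def tissue_response(cp: ConcentrationTimeSeries, k: KineticParams) -> ConcentrationTimeSeries:
    """Noiseless tissue curve K1 * (Cp conv exp(-K2 t)) on the grid of ``cp``."""
    values = k.k1 * exp_convolve_linear(cp.times, cp.values, k.k2)
    return ConcentrationTimeSeries(patient_id=cp.patient_id, times=cp.times.copy(), values=values)


def murase_design_matrix(
    cp: ConcentrationTimeSeries, ctis: ConcentrationTimeSeries
) -> DesignMatrix:
    """Design matrix of the linearized model, by the trapezoidal rule."""
    if cp.times.size != ctis.times.size or not np.allclose(cp.times, ctis.times):
        raise ValueError("Cp and Ctis must be sampled on the same time grid")
    cum_cp = cumulative_trapezoid(cp.values, cp.times, initial=0.0)
    cum_ct = cumulative_trapezoid(ctis.values, ctis.times, initial=0.0)
    return DesignMatrix(rows=np.column_stack([cum_cp, -cum_ct]), times=cp.times.copy())


@dataclass
class LLSQResult:
    """Unconstrained least-squares solution of C = A K.

    ``k1``/``k2`` may be negative (the fit is unconstrained); ``nonnegative``
    flags whether both are admissible rate constants.
    """

    k1: float
    k2: float
    residual_norm: float
    nonnegative: bool

    @property
    def params(self) -> KineticParams:
        """Clip-to-zero projection onto admissible rate constants."""
        return KineticParams(max(self.k1, 0.0), max(self.k2, 0.0))


def llsq_fit(design: DesignMatrix, y: np.ndarray) -> LLSQResult:
    """Ordinary least squares for the linearized kinetic system."""
    y = np.asarray(y, dtype=float)
    if y.size != design.rows.shape[0]:
        raise ValueError("observation vector length must match the design matrix")
    if y.size < 3:
        raise ValueError("need at least 3 samples to fit two rate constants")
    solution, _, rank, singular_values = np.linalg.lstsq(design.rows, y, rcond=None)
    if rank < 2:
        cond = float(singular_values[0] / singular_values[-1]) if singular_values[-1] > 0 else np.inf
        raise np.linalg.LinAlgError(
            f"rank-deficient design matrix (rank {rank}, condition {cond:.3e}): "
            "Cp and Ctis integrals are collinear"
        )
    k1, k2 = (float(v) for v in solution)
    residual = float(np.linalg.norm(design.rows @ solution - y))
    return LLSQResult(k1=k1, k2=k2, residual_norm=residual, nonnegative=k1 >= 0 and k2 >= 0)
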