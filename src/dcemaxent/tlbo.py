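"""Teaching-learning-based optimization (TLBO).

TLBO is a population metaheuristic for bounded minimization with two
alternating phases per iteration. In the *teacher phase* every learner is
pulled toward the best solution of the population (the teacher), offset by a
randomly weighted multiple of the population mean. In the *learner phase*
each learner is paired with a random classmate and steps along the direction
from the worse to the better of the pair. Both phases use greedy acceptance:
a proposal replaces the incumbent only on strict improvement, so the
best-so-far objective is monotone non-increasing.

Used here as the solver for maximum-entropy Lagrange multipliers, but exposed
as a generic bounded minimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["TLBOConfig", "TLBOResult", "teacher_phase", "learner_phase", "tlbo_minimize"]

Objective = Callable[[np.ndarray], float]


@dataclass
class TLBOConfig:
    """Settings for :func:`tlbo_minimize`.

    Parameters
    ----------
    population_size:
        Number of learners (>= 2).
    max_iterations:
        Maximum number of teacher+learner iterations.
    bounds:
        Per-dimension ``(lower, upper)`` finite intervals; proposals are
        clipped to this box.
    seed:
        Seed for the internal generator; fixed seed gives identical runs.
    tolerance:
        Stall tolerance: stop once the best objective improved by less than
        this over the last ``stall_window`` iterations. ``0.0`` disables the
        stall check and the run uses the full iteration budget (or the
        ``objective_target``).
    stall_window:
        Window length (iterations) for the stall check.
    objective_target:
        Optional early-exit threshold: stop as soon as the best objective is
        at or below this value.
    """

    bounds: Sequence[tuple[float, float]]
    population_size: int = 30
    max_iterations: int = 200
    seed: int = 0
    tolerance: float = 0.0
    stall_window: int = 20
    objective_target: float | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        lo, hi = self.bounds_arrays()
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            raise ValueError("bounds must be finite")
        if np.any(lo >= hi):
            raise ValueError("each bound must satisfy lower < upper")

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        b = np.asarray(self.bounds, dtype=float)
        if b.ndim != 2 or b.shape[1] != 2:
            raise ValueError("bounds must be a sequence of (lower, upper) pairs")
        return b[:, 0], b[:, 1]


@dataclass
class TLBOResult:
    """Outcome of a TLBO run.

    ``trace[i]`` is the best objective seen after iteration ``i``; it is
    non-increasing by construction of the greedy acceptance rule.
    """

    best_solution: np.ndarray
    best_objective: float
    trace: np.ndarray
    evaluations: int
    converged: bool = True


def _safe_objective(objective: Objective, x: np.ndarray) -> float:
    """Evaluate the objective, mapping non-finite values to +inf."""
    value = float(objective(x))
    return value if math.isfinite(value) else math.inf


def teacher_phase(
    population: np.ndarray,
    objectives: np.ndarray,
    objective: Objective,
    lower: np.ndarray,
    upper: np.ndarray,
    rng: np.random.Generator,
) -> int:
    """One teacher phase, in place. Returns the number of evaluations.

    Each learner proposes ``x + r * (teacher - Tf * mean)`` with ``r ~ U(0,1)``
    per learner and teaching factor ``Tf`` drawn from {1, 2} equiprobably.
    Teacher and mean are those at phase entry.
    """
    n = population.shape[0]
    teacher = population[int(np.argmin(objectives))].copy()
    mean = population.mean(axis=0)
    r = rng.random(n)
    tf = rng.integers(1, 3, size=n)
    evaluations = 0
    for i in range(n):
        proposal = population[i] + r[i] * (teacher - tf[i] * mean)
        np.clip(proposal, lower, upper, out=proposal)
        value = _safe_objective(objective, proposal)
        evaluations += 1
        if value < objectives[i]:
            population[i] = proposal
            objectives[i] = value
    return evaluations


def learner_phase(
    population: np.ndarray,
    objectives: np.ndarray,
    objective: Objective,
    lower: np.ndarray,
    upper: np.ndarray,
    rng: np.random.Generator,
) -> int:
    """One learner phase, in place. Returns the number of evaluations.

    Learner ``i`` is paired with a random distinct partner and steps by
    ``r * (x_better - x_worse)`` for the better/worse member of the pair.
    (Phrasing the step as "toward the better of the pair" or as a sign flip
    on the mover's own rank gives the same update, so there is a single rule.)
    Partners are the incumbents at phase entry.
    """
    n = population.shape[0]
    snapshot = population.copy()
    snapshot_obj = objectives.copy()
    r = rng.random(n)
    partners = np.empty(n, dtype=int)
    for i in range(n):
        p = int(rng.integers(0, n - 1))
        partners[i] = p if p < i else p + 1
    evaluations = 0
    for i in range(n):
        p = partners[i]
        if snapshot_obj[p] < snapshot_obj[i]:
            step = snapshot[p] - snapshot[i]
        else:
            step = snapshot[i] - snapshot[p]
        proposal = population[i] + r[i] * step
        np.clip(proposal, lower, upper, out=proposal)
        value = _safe_objective(objective, proposal)
        evaluations += 1
        if value < objectives[i]:
            population[i] = proposal
            objectives[i] = value
    return evaluations


def tlbo_minimize(objective: Objective, cfg: TLBOConfig) -> TLBOResult:
    """Minimize ``objective`` over the bounded box in ``cfg``.

    Starts from a uniform-random population inside the bounds and alternates
    teacher and learner phases. Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lower, upper = cfg.bounds_arrays()
    dim = lower.size

    population = rng.uniform(lower, upper, size=(cfg.population_size, dim))
    objectives = np.array([_safe_objective(objective, x) for x in population])
    evaluations = cfg.population_size

    trace = []
    best = float(objectives.min())
    for _ in range(cfg.max_iterations):
        evaluations += teacher_phase(population, objectives, objective, lower, upper, rng)
        evaluations += learner_phase(population, objectives, objective, lower, upper, rng)
        best = min(best, float(objectives.min()))
        trace.append(best)
        if cfg.objective_target is not None and best <= cfg.objective_target:
            break
        if (
            cfg.tolerance > 0.0
            and len(trace) > cfg.stall_window
            and trace[-1 - cfg.stall_window] - trace[-1] < cfg.tolerance
        ):
            break

    i_best = int(np.argmin(objectives))
    return TLBOResult(
        best_solution=population[i_best].copy(),
        best_objective=float(objectives[i_best]),
        trace=np.asarray(trace),
        evaluations=evaluations,
    )
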