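"""Particle swarm minimizer over box-constrained difficulty vectors.

A swarm of candidate difficulty vectors moves under inertia plus attraction
toward each particle's own best position and the best position among its
informers.  Hyperparameters follow the widely used standard-PSO-2007
conventions: inertia ``1/(2 ln 2)``, cognitive = social = ``0.5 + ln 2``,
and a random informer topology in which each particle informs any other
with a fixed probability, regenerated after every iteration that fails to
improve the global best.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .criteria import CriterionSpec, GrowthDesign, build_case_objective

__all__ = ["PSOConfig", "OptimResult", "pso_minimize", "optimize_continuous_design"]


@dataclass(frozen=True)
class PSOConfig:
    """Swarm hyperparameters and stopping rule.

    Defaults mirror the study setup: swarm of 200 particles, informer
    probability 0.2, convergence tolerance 1e-10, search box [-6, 6].
    Convergence is declared when the global best improves by less than
    ``convergence_tol`` over a ``patience`` window of iterations.
    """

    swarm_size: int = 200
    proportion_informed: float = 0.2
    convergence_tol: float = 1e-10
    max_iterations: int = 5000
    patience: int = 50
    lower_bound: float = -6.0
    upper_bound: float = 6.0
    inertia: float = 1.0 / (2.0 * math.log(2.0))
    cognitive_coef: float = 0.5 + math.log(2.0)
    social_coef: float = 0.5 + math.log(2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if not (0.0 < self.proportion_informed <= 1.0):
            raise ValueError("proportion_informed must be in (0, 1]")
        if self.lower_bound >= self.upper_bound:
            raise ValueError("lower_bound must be < upper_bound")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")


@dataclass
class OptimResult:
    """Outcome of one swarm run; ``best_value == objective(best_vector)``."""

    best_vector: np.ndarray
    best_value: float
    iterations_used: int
    converged: bool
    seed: int
    trace: np.ndarray = field(repr=False, default=None)


def _as_batch_objective(objective: Callable, dim: int) -> Callable:
    """Wrap a scalar objective so it maps (m, dim) -> (m,) when needed."""
    m = dim + 1  # probe size != dim so a row-wise batch return is unambiguous
    probe = np.zeros((m, dim))
    try:
        out = np.asarray(objective(probe))
        if out.shape == (m,):
            return objective
    except Exception:
        pass

    def batched(x: np.ndarray) -> np.ndarray:
        return np.array([float(objective(row)) for row in np.atleast_2d(x)])

    return batched


def pso_minimize(objective: Callable, dim: int, config: PSOConfig) -> OptimResult:
    """Minimize ``objective`` over ``[lower_bound, upper_bound]^dim``.

    ``objective`` may map a single vector to a float, or a ``(m, dim)``
    batch to ``(m,)`` values (the batch form is detected and preferred —
    it evaluates the whole swarm per iteration in one call).

    Positions are clamped to the box with the offending velocity component
    zeroed.  Fully reproducible given ``config.seed``.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(config.seed)
    f = _as_batch_objective(objective, dim)
    lb, ub = config.lower_bound, config.upper_bound
    span = ub - lb
    S = config.swarm_size

    x = rng.uniform(lb, ub, size=(S, dim))
    v = rng.uniform(-span / 2.0, span / 2.0, size=(S, dim))
    fx = np.asarray(f(x), dtype=float)
    if not np.all(np.isfinite(fx)):
        bad = x[np.argmax(~np.isfinite(fx))]
        raise FloatingPointError(f"objective returned a non-finite value at {bad}")

    pbest = x.copy()
    pbest_val = fx.copy()
    g = int(np.argmin(pbest_val))
    gbest = pbest[g].copy()
    gbest_val = float(pbest_val[g])

    def make_links() -> np.ndarray:
        # links[j, i]: particle j informs particle i; every particle
        # informs itself.
        links = rng.random((S, S)) < config.proportion_informed
        np.fill_diagonal(links, True)
        return links

    links = make_links()
    trace = [gbest_val]
    window_best = gbest_val
    window_start = 0
    converged = False
    it = 0

    for it in range(1, config.max_iterations + 1):
        # Best informer position for each particle.
        masked = np.where(links, pbest_val[:, None], np.inf)
        lbest_idx = np.argmin(masked, axis=0)
        lbest = pbest[lbest_idx]

        r1 = rng.uniform(0.0, config.cognitive_coef, size=(S, dim))
        r2 = rng.uniform(0.0, config.social_coef, size=(S, dim))
        v = config.inertia * v + r1 * (pbest - x) + r2 * (lbest - x)
        x = x + v
        out_low = x < lb
        out_high = x > ub
        x = np.clip(x, lb, ub)
        v[out_low | out_high] = 0.0

        fx = np.asarray(f(x), dtype=float)
        if not np.all(np.isfinite(fx)):
            bad = x[np.argmax(~np.isfinite(fx))]
            raise FloatingPointError(f"objective returned a non-finite value at {bad}")

        improved = fx < pbest_val
        pbest[improved] = x[improved]
        pbest_val[improved] = fx[improved]
        g = int(np.argmin(pbest_val))
        if pbest_val[g] < gbest_val:
            gbest_val = float(pbest_val[g])
            gbest = pbest[g].copy()
        else:
            links = make_links()
        trace.append(gbest_val)

        if it - window_start >= config.patience:
            if window_best - gbest_val < config.convergence_tol:
                converged = True
                break
            window_best = gbest_val
            window_start = it

    return OptimResult(
        best_vector=gbest,
        best_value=gbest_val,
        iterations_used=it,
        converged=converged,
        seed=config.seed,
        trace=np.asarray(trace),
    )


@dataclass
class SolutionRecord:
    """An optimized continuous design with its provenance."""

    case_id: int
    spec: CriterionSpec
    design: GrowthDesign
    criterion_value: float
    sorted_difficulties: dict[str, np.ndarray]
    seed: int
    iterations_used: int
    converged: bool

    @property
    def b_vector(self) -> np.ndarray:
        return np.array(
            [it.b for it in self.design.unique1 + self.design.common + self.design.unique2]
        )


def optimize_continuous_design(
    case_id: int, spec: CriterionSpec, config: PSOConfig
) -> SolutionRecord:
    """Run the swarm on a case objective and unpack the optimal design.

    Reported difficulties are sorted ascending within each item role
    (Test 1 unique, common, Test 2 unique), matching how optimized designs
    are usually displayed.
    """
    objective = build_case_objective(case_id, spec)
    result = pso_minimize(objective, objective.dim, config)
    design = objective.unpack(result.best_vector)
    n1, nc = spec.n1, spec.nc
    b = result.best_vector
    sorted_b = {
        "unique1": np.sort(b[:n1]),
        "common": np.sort(b[n1 : n1 + nc]),
        "unique2": np.sort(b[n1 + nc :]),
    }
    return SolutionRecord(
        case_id=case_id,
        spec=spec,
        design=design,
        criterion_value=result.best_value,
        sorted_difficulties=sorted_b,
        seed=config.seed,
        iterations_used=result.iterations_used,
        converged=result.converged,
    )
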