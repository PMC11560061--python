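"""Design criteria: weighted asymptotic-variance objectives for ability growth.

A growth study administers two NEAT test forms (non-equivalent groups with
anchor test): Form 1 = its unique items plus the common (anchor) items,
Form 2 = the anchor items plus its own unique items.  The asymptotic
variance of the estimated mean-ability growth ``d = mu_2 - mu_1`` is a sum
of reciprocal test-information terms over examinee abilities; replacing
each population's ability distribution by a discrete (theta, W) grid turns
design optimization into minimizing the multi-objective weighted sum

    Psi_d(b) = sum_j w_j1 / I_form1(theta_j1) + sum_j w_j2 / I_form2(theta_j2)

over the item difficulties ``b``.  Percentile-growth and multi-group
variants are weighted sums of the same shape, so combined objectives just
concatenate (and restandardize) the weight schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .irt import Item, batch_test_information, items_to_arrays, test_information
from .weights import (
    AbilityGrid,
    WeightedPoints,
    make_normal_grid,
    make_percentile_grid,
)

__all__ = [
    "GrowthDesign",
    "CriterionSpec",
    "crit_mean",
    "crit_growth",
    "crit_percentile",
    "build_case_objective",
    "growth_objective",
    "WeightedVarianceObjective",
    "asymptotic_var_growth",
    "asymptotic_var_percentile",
]


@dataclass(frozen=True)
class GrowthDesign:
    """Two NEAT test forms: unique items of each form plus shared anchors."""

    unique1: tuple[Item, ...]
    common: tuple[Item, ...]
    unique2: tuple[Item, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "unique1", tuple(self.unique1))
        object.__setattr__(self, "common", tuple(self.common))
        object.__setattr__(self, "unique2", tuple(self.unique2))
        if len(self.form1) < 1 or len(self.form2) < 1:
            raise ValueError("both forms must contain at least one item")

    @property
    def form1(self) -> tuple[Item, ...]:
        return self.unique1 + self.common

    @property
    def form2(self) -> tuple[Item, ...]:
        return self.common + self.unique2

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.unique1), len(self.common), len(self.unique2)

    @classmethod
    def from_vectors(cls, a, b, n1: int, nc: int, n2: int) -> "GrowthDesign":
        """Unpack parameter vectors packed as (unique1, common, unique2)."""
        a = np.broadcast_to(np.asarray(a, dtype=float), (n1 + nc + n2,))
        b = np.asarray(b, dtype=float)
        if b.shape != (n1 + nc + n2,):
            raise ValueError(f"expected b of length {n1 + nc + n2}, got {b.shape}")
        items = [Item(float(ai), float(bi)) for ai, bi in zip(a, b)]
        return cls(
            tuple(items[:n1]), tuple(items[n1 : n1 + nc]), tuple(items[n1 + nc :])
        )


@dataclass(frozen=True)
class CriterionSpec:
    """Scenario parameters for one design case.

    ``d`` is the mean-ability growth between the two administrations; the
    populations are taken as N(-d/2, 1) and N(+d/2, 1).  ``a_level`` is the
    constant discrimination used when difficulties are free (a per-item
    array is also accepted).  ``group_shift`` is the ability offset of the
    second examinee group in the two-group case.  ``N1``/``N2`` enter only
    the asymptotic-variance expressions, never the criteria (sample sizes
    rescale a criterion by a constant and cannot move its argmin).
    """

    d: float = 1.0
    a_level: float | np.ndarray = 1.0
    n1: int = 30
    nc: int = 15
    n2: int = 30
    l: int = 100
    half_width: float = 4.0
    percentiles: tuple[float, ...] | None = None
    group_shift: float | None = None
    N1: int = 1
    N2: int = 1

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("growth distance d must be >= 0")
        if self.n1 + self.nc < 1 or self.n2 + self.nc < 1:
            raise ValueError("both forms must be non-empty")
        if self.N1 < 1 or self.N2 < 1:
            raise ValueError("sample sizes must be >= 1")

    @property
    def n_items(self) -> int:
        return self.n1 + self.nc + self.n2

    def a_vector(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.a_level, dtype=float), (self.n_items,)
        ).copy()


def _grid_arrays(grid: AbilityGrid | WeightedPoints) -> tuple[np.ndarray, np.ndarray]:
    return np.asarray(grid.points, float), np.asarray(grid.weights, float)


def crit_mean(items: Sequence[Item], grid: AbilityGrid | WeightedPoints) -> float:
    """Weighted-sum variance criterion for a single estimated mean."""
    pts, w = _grid_arrays(grid)
    tif = test_information(items, pts)
    return float(np.sum(w / tif))


def crit_growth(
    design: GrowthDesign,
    grid1: AbilityGrid | WeightedPoints,
    grid2: AbilityGrid | WeightedPoints,
) -> float:
    """Mean-growth criterion: Form 1 evaluated on the first population's
    grid plus Form 2 on the second's.  Anchor items contribute to both
    terms, which is what makes them efficient."""
    p1, w1 = _grid_arrays(grid1)
    p2, w2 = _grid_arrays(grid2)
    return float(
        np.sum(w1 / test_information(design.form1, p1))
        + np.sum(w2 / test_information(design.form2, p2))
    )


def crit_percentile(
    design: GrowthDesign,
    pct_grid1: AbilityGrid | WeightedPoints,
    pct_grid2: AbilityGrid | WeightedPoints,
) -> float:
    """Percentile-growth criterion with weights standardized across both
    populations (total mass one, split evenly between the two grids)."""
    p1, w1 = _grid_arrays(pct_grid1)
    p2, w2 = _grid_arrays(pct_grid2)
    return float(
        0.5 * np.sum(w1 / test_information(design.form1, p1))
        + 0.5 * np.sum(w2 / test_information(design.form2, p2))
    )


class WeightedVarianceObjective:
    """Vectorized weighted-variance objective over packed difficulty vectors.

    The objective is a mass-weighted average of component criteria, each a
    (grid1, grid2) pair evaluated against Form 1 and Form 2.  All component
    grids for a form are concatenated up front, so evaluating a swarm of
    candidate vectors costs two batched test-information calls.

    Call with a difficulty vector of shape ``(n,)`` for a scalar value or
    ``(m, n)`` for ``m`` values.
    """

    def __init__(
        self,
        a: np.ndarray | float,
        n1: int,
        nc: int,
        n2: int,
        components: Sequence[
            tuple[AbilityGrid | WeightedPoints, AbilityGrid | WeightedPoints, float]
        ],
        component_scales: Sequence[float] | None = None,
    ) -> None:
        if not components:
            raise ValueError("objective needs at least one component criterion")
        self.n1, self.nc, self.n2 = n1, nc, n2
        self.n_items = n1 + nc + n2
        self.a = np.broadcast_to(np.asarray(a, dtype=float), (self.n_items,)).copy()
        masses = np.array([m for _, _, m in components], dtype=float)
        if np.any(masses <= 0):
            raise ValueError("component masses must be positive")
        masses = masses / masses.sum()
        # Per-grid scale within a component: the mean-growth criterion gives
        # each population's grid full unit mass; the percentile criterion
        # standardizes across both grids (0.5 each).
        if component_scales is None:
            component_scales = [1.0] * len(components)
        t1, t2, v1, v2 = [], [], [], []
        for (g1, g2, _), mass, scale in zip(components, masses, component_scales):
            p1, w1 = _grid_arrays(g1)
            p2, w2 = _grid_arrays(g2)
            t1.append(p1)
            v1.append(mass * scale * w1)
            t2.append(p2)
            v2.append(mass * scale * w2)
        self.theta1 = np.concatenate(t1)
        self.w1 = np.concatenate(v1)
        self.theta2 = np.concatenate(t2)
        self.w2 = np.concatenate(v2)
        self.components = list(components)

    @property
    def dim(self) -> int:
        return self.n_items

    def unpack(self, b: np.ndarray) -> GrowthDesign:
        return GrowthDesign.from_vectors(self.a, b, self.n1, self.nc, self.n2)

    def __call__(self, b: np.ndarray):
        b = np.asarray(b, dtype=float)
        scalar = b.ndim == 1
        b2d = np.atleast_2d(b)
        if b2d.shape[-1] != self.n_items:
            raise ValueError(
                f"expected difficulty vectors of length {self.n_items}, "
                f"got {b2d.shape[-1]}"
            )
        k1 = self.n1 + self.nc
        tif1 = batch_test_information(self.a[:k1], b2d[:, :k1], self.theta1)
        tif2 = batch_test_information(self.a[self.n1 :], b2d[:, self.n1 :], self.theta2)
        vals = (self.w1 / tif1).sum(axis=-1) + (self.w2 / tif2).sum(axis=-1)
        return float(vals[0]) if scalar else vals


def growth_objective(
    a,
    n1: int,
    nc: int,
    n2: int,
    grid1: AbilityGrid | WeightedPoints,
    grid2: AbilityGrid | WeightedPoints,
) -> WeightedVarianceObjective:
    """Plain mean-growth objective (one component) for arbitrary grids."""
    return WeightedVarianceObjective(a, n1, nc, n2, [(grid1, grid2, 1.0)])


def build_case_objective(
    case_id: int, spec: CriterionSpec, pct_mass: float = 1.0
) -> WeightedVarianceObjective:
    """Objective for one of the four study cases.

    Case 1  minimize the variance of the estimated mean growth;
    Case 2  case 1 combined with the 25th/75th percentile growth;
    Case 3  percentile growth only, percentiles 25/50/75;
    Case 4  mean growth for two examinee groups whose abilities differ by
            ``group_shift`` (default 0.25).

    Component criteria enter a combined objective with equal prior mass
    (``pct_mass`` rescales the percentile component in case 2).  The
    returned objective maps a packed difficulty vector (unique1, common,
    unique2) to the combined, standardized criterion value.
    """
    d = spec.d
    hw = spec.half_width
    mu1, mu2 = -d / 2.0, d / 2.0

    def growth_grids(shift: float = 0.0):
        return (
            make_normal_grid(mu1 + shift, 1.0, spec.l, hw),
            make_normal_grid(mu2 + shift, 1.0, spec.l, hw),
        )

    def pct_grids(percentiles):
        return (
            make_percentile_grid(percentiles, mu1, 1.0),
            make_percentile_grid(percentiles, mu2, 1.0),
        )

    if case_id == 1:
        g1, g2 = growth_grids()
        comps = [(g1, g2, 1.0)]
        scales = [1.0]
    elif case_id == 2:
        pct = spec.percentiles if spec.percentiles is not None else (25.0, 75.0)
        g1, g2 = growth_grids()
        q1, q2 = pct_grids(pct)
        comps = [(g1, g2, 1.0), (q1, q2, float(pct_mass))]
        scales = [1.0, 0.5]
    elif case_id == 3:
        pct = spec.percentiles if spec.percentiles is not None else (25.0, 50.0, 75.0)
        q1, q2 = pct_grids(pct)
        comps = [(q1, q2, 1.0)]
        scales = [0.5]
    elif case_id == 4:
        shift = spec.group_shift if spec.group_shift is not None else 0.25
        gA1, gA2 = growth_grids(0.0)
        gB1, gB2 = growth_grids(shift)
        comps = [(gA1, gA2, 1.0), (gB1, gB2, 1.0)]
        scales = [1.0, 1.0]
    else:
        raise ValueError(f"case_id must be 1..4, got {case_id}")

    return WeightedVarianceObjective(
        spec.a_level, spec.n1, spec.nc, spec.n2, comps, component_scales=scales
    )


def asymptotic_var_growth(
    design: GrowthDesign,
    abilities1: Sequence[float],
    abilities2: Sequence[float],
    N1: int | None = None,
    N2: int | None = None,
) -> float:
    """Asymptotic variance of the estimated mean growth at known abilities.

    ``(1/N1^2) sum_j 1/I_form1(theta_j1) + (1/N2^2) sum_j 1/I_form2(theta_j2)``.
    An empty ``abilities2`` omits the second term, reducing to the variance
    of a single estimated mean.
    """
    th1 = np.asarray(abilities1, dtype=float)
    th2 = np.asarray(abilities2, dtype=float)
    if N1 is None:
        N1 = th1.size
    if N2 is None:
        N2 = th2.size
    if th1.size != N1 or th2.size != N2:
        raise ValueError("ability lists must have lengths N1 and N2")
    if N1 < 1:
        raise ValueError("need at least one examinee in the first sample")
    out = np.sum(1.0 / test_information(design.form1, th1)) / N1**2
    if N2 > 0:
        out = out + np.sum(1.0 / test_information(design.form2, th2)) / N2**2
    return float(out)


def asymptotic_var_percentile(
    design: GrowthDesign, theta1p: float, theta2p: float
) -> float:
    """Asymptotic variance of an estimated percentile growth:
    ``1/I_form1(theta_1p) + 1/I_form2(theta_2p)``."""
    return float(
        1.0 / test_information(design.form1, theta1p)
        + 1.0 / test_information(design.form2, theta2p)
    )
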