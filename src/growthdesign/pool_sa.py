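"""Discrete test assembly from a calibrated item pool.

When items come from an operational pool, discrimination and difficulty are
paired within each item, so the design problem becomes combinatorial:
select ``n1 + nc + n2`` items and assign them to the Test-1-unique, common
(anchor) and Test-2-unique roles so that a growth criterion is minimized.
Simulated annealing with a one-item-swap neighborhood does the global
search; a greedy pass that accepts only strict improvements verifies that
no single swap improves the final solution.  An exhaustive enumerator
serves as an oracle on tiny pools.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .criteria import GrowthDesign
from .irt import Item
from .weights import AbilityGrid, WeightedPoints

__all__ = [
    "ItemPool",
    "SAConfig",
    "PoolSolution",
    "PoolGrowthObjective",
    "generate_synthetic_pool",
    "center_difficulties",
    "sa_select",
    "greedy_refine",
    "exhaustive_select",
    "read_pool",
    "write_pool",
]


@dataclass(frozen=True)
class ItemPool:
    """Calibrated 2PL items with stable unique identifiers."""

    ids: tuple[str, ...]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if len(self.ids) != self.a.size or self.a.size != self.b.size:
            raise ValueError("ids, a and b must have equal lengths")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("item identifiers must be unique")
        if np.any(self.a <= 0) or not np.all(np.isfinite(self.a)):
            raise ValueError("all discriminations must be finite and > 0")
        if not np.all(np.isfinite(self.b)):
            raise ValueError("all difficulties must be finite")

    def __len__(self) -> int:
        return len(self.ids)

    def item(self, idx: int) -> Item:
        return Item(float(self.a[idx]), float(self.b[idx]))

    def items(self, idx: Sequence[int]) -> tuple[Item, ...]:
        return tuple(self.item(i) for i in idx)


@dataclass(frozen=True)
class SAConfig:
    """Annealing schedule.  Defaults: t0 = 100 (acceptance probability of
    early uphill moves close to 1), geometric cooling t <- 0.8 t, 5000
    moves per epoch, 100 epochs, then a 100,000-move greedy pass."""

    t0: float = 100.0
    alpha: float = 0.8
    nrep: int = 5000
    epochs: int = 100
    greedy_iterations: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError("t0 must be > 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.nrep < 1 or self.epochs < 1:
            raise ValueError("nrep and epochs must be >= 1")


@dataclass
class PoolSolution:
    """A role-assigned selection from a pool with its criterion value."""

    unique1: list[str]
    common: list[str]
    unique2: list[str]
    criterion_value: float
    energy_trace: np.ndarray = field(default=None, repr=False)

    @property
    def all_ids(self) -> list[str]:
        return list(self.unique1) + list(self.common) + list(self.unique2)

    def design(self, pool: ItemPool) -> GrowthDesign:
        lookup = {iid: k for k, iid in enumerate(pool.ids)}
        idx = lambda ids: [lookup[i] for i in ids]
        return GrowthDesign(
            pool.items(idx(self.unique1)),
            pool.items(idx(self.common)),
            pool.items(idx(self.unique2)),
        )


class PoolGrowthObjective:
    """Mean-growth criterion over (theta, W) grids, with a precomputed
    per-pool-item information table enabling O(grid) swap updates."""

    def __init__(
        self,
        grid1: AbilityGrid | WeightedPoints,
        grid2: AbilityGrid | WeightedPoints,
    ) -> None:
        self.theta1 = np.asarray(grid1.points, float)
        self.w1 = np.asarray(grid1.weights, float)
        self.theta2 = np.asarray(grid2.points, float)
        self.w2 = np.asarray(grid2.weights, float)

    def __call__(self, design: GrowthDesign) -> float:
        from .irt import test_information

        return float(
            np.sum(self.w1 / test_information(design.form1, self.theta1))
            + np.sum(self.w2 / test_information(design.form2, self.theta2))
        )

    # --- fast path used by the annealer ---

    def item_information_tables(self, pool: ItemPool) -> tuple[np.ndarray, np.ndarray]:
        """Per-item information at each grid point: (P, l1) and (P, l2)."""

        def table(theta: np.ndarray) -> np.ndarray:
            x = np.clip(pool.a[:, None] * (theta[None, :] - pool.b[:, None]), -60, 60)
            w = np.exp(x)
            return pool.a[:, None] ** 2 * w / (1.0 + w) ** 2

        return table(self.theta1), table(self.theta2)

    def value_from_tif(self, tif1: np.ndarray, tif2: np.ndarray) -> float:
        return float(self.w1 @ (1.0 / tif1) + self.w2 @ (1.0 / tif2))


# Lognormal shape for synthetic discriminations; chosen once so that after
# truncation to the default range the long-run mean sits near 1.14,
# emulating a large operational 2PL pool for grade-8 mathematics.
_A_LOGNORM_MEAN = 0.09
_A_LOGNORM_SD = 0.33


def generate_synthetic_pool(
    n_items: int,
    seed: int,
    a_range: tuple[float, float] = (0.40, 1.90),
    b_range: tuple[float, float] = (-1.56, 1.60),
) -> ItemPool:
    """Synthetic calibrated pool emulating an operational item bank.

    Discriminations follow a lognormal shape truncated to ``a_range`` (so
    most mass sits near 1 with a right skew); difficulties are drawn from a
    symmetric truncated normal on ``b_range`` and then mean-centered, as
    operational difficulty scales are typically anchored at zero.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    a_lo, a_hi = a_range
    b_lo, b_hi = b_range
    if not (a_lo < a_hi and b_lo < b_hi) or a_lo <= 0:
        raise ValueError("invalid parameter ranges")
    rng = np.random.default_rng(seed)

    a = np.empty(0)
    while a.size < n_items:
        draw = rng.lognormal(_A_LOGNORM_MEAN, _A_LOGNORM_SD, size=4 * n_items)
        a = np.concatenate([a, draw[(draw >= a_lo) & (draw <= a_hi)]])
    a = a[:n_items]

    b_mid = 0.5 * (b_lo + b_hi)
    b_sd = (b_hi - b_lo) / 4.0
    b = np.empty(0)
    while b.size < n_items:
        draw = rng.normal(b_mid, b_sd, size=4 * n_items)
        b = np.concatenate([b, draw[(draw >= b_lo) & (draw <= b_hi)]])
    b = b[:n_items]
    b = b - b.mean()

    ids = tuple(f"item{k + 1:04d}" for k in range(n_items))
    return ItemPool(ids, a, b)


def center_difficulties(pool: ItemPool) -> ItemPool:
    """Subtract the pool-mean difficulty so that mean(b) = 0 exactly."""
    return ItemPool(pool.ids, pool.a.copy(), pool.b - pool.b.mean())


def _check_sizes(pool: ItemPool, sizes: tuple[int, int, int]) -> int:
    n1, nc, n2 = sizes
    if min(n1, nc, n2) < 0 or n1 + nc < 1 or n2 + nc < 1:
        raise ValueError("invalid role sizes")
    total = n1 + nc + n2
    if len(pool) <= total:
        raise ValueError(
            f"pool of {len(pool)} items cannot fill {total} slots with spares"
        )
    return total


class _SwapState:
    """Incremental criterion evaluation under the one-item-swap move.

    Slots carry fixed roles; the state tracks each form's test information
    on its grid so a swap costs two O(l) vector updates instead of a full
    criterion evaluation.  Falls back to whole-design evaluation for
    objectives without information tables.
    """

    def __init__(self, pool, sizes, objective, selection: np.ndarray):
        self.pool = pool
        self.n1, self.nc, self.n2 = sizes
        self.total = self.n1 + self.nc + self.n2
        self.objective = objective
        self.sel = np.asarray(selection, dtype=int).copy()
        self.fast = hasattr(objective, "item_information_tables")
        if self.fast:
            self.i1, self.i2 = objective.item_information_tables(pool)
            f1 = self.sel[: self.n1 + self.nc]
            f2 = self.sel[self.n1 :]
            self.tif1 = self.i1[f1].sum(axis=0)
            self.tif2 = self.i2[f2].sum(axis=0)

    def value(self) -> float:
        if self.fast:
            return self.objective.value_from_tif(self.tif1, self.tif2)
        return self.objective(self._design(self.sel))

    def _design(self, sel) -> GrowthDesign:
        p = self.pool
        return GrowthDesign(
            p.items(sel[: self.n1]),
            p.items(sel[self.n1 : self.n1 + self.nc]),
            p.items(sel[self.n1 + self.nc :]),
        )

    def delta_tifs(self, slot: int, new_item: int):
        old_item = int(self.sel[slot])
        in_form1 = slot < self.n1 + self.nc
        in_form2 = slot >= self.n1
        t1 = self.tif1 + (self.i1[new_item] - self.i1[old_item]) if in_form1 else self.tif1
        t2 = self.tif2 + (self.i2[new_item] - self.i2[old_item]) if in_form2 else self.tif2
        return t1, t2

    def trial_value(self, slot: int, new_item: int) -> float:
        if self.fast:
            t1, t2 = self.delta_tifs(slot, new_item)
            return self.objective.value_from_tif(t1, t2)
        trial = self.sel.copy()
        trial[slot] = new_item
        return self.objective(self._design(trial))

    def commit(self, slot: int, new_item: int) -> None:
        if self.fast:
            self.tif1, self.tif2 = self.delta_tifs(slot, new_item)
        self.sel[slot] = new_item


def _solution_from_state(state: _SwapState, sel, value, trace) -> PoolSolution:
    ids = [state.pool.ids[i] for i in sel]
    n1, nc = state.n1, state.nc
    # Re-evaluate from scratch: half a million incremental O(l) updates can
    # drift the tracked information sums by a few ulps.
    fresh = _SwapState(state.pool, (state.n1, state.nc, state.n2), state.objective, sel)
    return PoolSolution(
        unique1=ids[:n1],
        common=ids[n1 : n1 + nc],
        unique2=ids[n1 + nc :],
        criterion_value=float(fresh.value()),
        energy_trace=np.asarray(trace) if trace is not None else None,
    )


def sa_select(
    pool: ItemPool,
    sizes: tuple[int, int, int],
    objective: Callable[[GrowthDesign], float],
    config: SAConfig,
) -> PoolSolution:
    """Simulated annealing over role-assigned selections.

    Starts from a uniform random selection; each move swaps the occupant of
    one uniformly chosen slot (role preserved) with a uniformly chosen
    unselected pool item, accepted if it does not worsen the criterion and
    otherwise with probability ``exp(-delta / t)``.  The temperature drops
    by the factor ``alpha`` after every ``nrep`` moves; the best-ever
    solution is returned together with the per-epoch best-energy trace.
    """
    total = _check_sizes(pool, sizes)
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(pool))
    state = _SwapState(pool, sizes, objective, perm[:total])
    unselected = perm[total:].copy()

    current = state.value()
    best_sel = state.sel.copy()
    best_val = current
    trace = []
    t = config.t0
    for _ in range(config.epochs):
        for _ in range(config.nrep):
            slot = int(rng.integers(total))
            k = int(rng.integers(unselected.size))
            cand = int(unselected[k])
            trial = state.trial_value(slot, cand)
            delta = trial - current
            if delta <= 0 or rng.random() < np.exp(-delta / t):
                old = int(state.sel[slot])
                state.commit(slot, cand)
                unselected[k] = old
                current = trial
                if current < best_val:
                    best_val = current
                    best_sel = state.sel.copy()
        trace.append(best_val)
        t *= config.alpha
    return _solution_from_state(state, best_sel, best_val, trace)


def greedy_refine(
    pool: ItemPool,
    start: PoolSolution,
    objective: Callable[[GrowthDesign], float],
    iterations: int = 100_000,
    seed: int = 0,
) -> PoolSolution:
    """Hill-climbing pass over the same swap neighborhood, accepting only
    strict improvements.  The returned criterion is <= the start's."""
    sizes = (len(start.unique1), len(start.common), len(start.unique2))
    _check_sizes(pool, sizes)
    lookup = {iid: k for k, iid in enumerate(pool.ids)}
    sel = np.array([lookup[i] for i in start.all_ids], dtype=int)
    state = _SwapState(pool, sizes, objective, sel)
    member = np.zeros(len(pool), dtype=bool)
    member[sel] = True
    unselected = np.flatnonzero(~member)

    rng = np.random.default_rng(seed)
    current = state.value()
    total = sizes[0] + sizes[1] + sizes[2]
    for _ in range(iterations):
        slot = int(rng.integers(total))
        k = int(rng.integers(unselected.size))
        cand = int(unselected[k])
        trial = state.trial_value(slot, cand)
        if trial < current:
            old = int(state.sel[slot])
            state.commit(slot, cand)
            unselected[k] = old
            current = trial
    return _solution_from_state(state, state.sel, current, None)


_EXHAUSTIVE_GUARD = 1_000_000


def exhaustive_select(
    pool: ItemPool,
    sizes: tuple[int, int, int],
    objective: Callable[[GrowthDesign], float],
) -> PoolSolution:
    """Enumerate every role-assigned selection; oracle for tiny pools.

    Ties in the criterion are broken by the lexicographically smallest
    tuple of item identifiers (unique1, common, unique2).
    """
    n1, nc, n2 = sizes
    P = len(pool)
    if min(sizes) < 0 or n1 + nc + n2 > P:
        raise ValueError("sizes incompatible with pool")
    from math import comb

    n_combos = comb(P, n1) * comb(P - n1, nc) * comb(P - n1 - nc, n2)
    if n_combos > _EXHAUSTIVE_GUARD:
        raise ValueError(f"{n_combos} role assignments exceed the exhaustive guard")

    all_idx = range(P)
    best = None
    for u1 in itertools.combinations(all_idx, n1):
        rest1 = [i for i in all_idx if i not in set(u1)]
        for c in itertools.combinations(rest1, nc):
            rest2 = [i for i in rest1 if i not in set(c)]
            for u2 in itertools.combinations(rest2, n2):
                design = GrowthDesign(pool.items(u1), pool.items(c), pool.items(u2))
                val = float(objective(design))
                key = (
                    tuple(pool.ids[i] for i in u1),
                    tuple(pool.ids[i] for i in c),
                    tuple(pool.ids[i] for i in u2),
                )
                if best is None or (val, key) < best[:2]:
                    best = (val, key, (u1, c, u2))
    val, key, (u1, c, u2) = best
    return PoolSolution(
        unique1=[pool.ids[i] for i in u1],
        common=[pool.ids[i] for i in c],
        unique2=[pool.ids[i] for i in u2],
        criterion_value=val,
        energy_trace=None,
    )


def write_pool(pool: ItemPool, path) -> None:
    """Write a pool as delimited text with header ``item_id,a,b`` at 12
    significant digits (round-trip exact at that precision)."""
    df = pd.DataFrame({"item_id": pool.ids, "a": pool.a, "b": pool.b})
    df.to_csv(path, index=False, float_format="%.12g")


def read_pool(path) -> ItemPool:
    """Read a delimited ``item_id,a,b`` pool file."""
    df = pd.read_csv(path)
    required = {"item_id", "a", "b"}
    if not required.issubset(df.columns):
        raise ValueError(f"pool file must have columns {sorted(required)}")
    if df["item_id"].duplicated().any():
        dups = df.loc[df["item_id"].duplicated(), "item_id"].tolist()
        raise ValueError(f"duplicate item_id values: {dups}")
    return ItemPool(
        tuple(df["item_id"].astype(str)), df["a"].to_numpy(), df["b"].to_numpy()
    )
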