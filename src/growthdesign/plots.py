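"""Figure helpers mirroring the standard displays for growth designs:
sorted-difficulty dot plots per item role, pool scatter plots with the
selected items highlighted, ratio boxplots, and stability mean/SD plots."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .experiments import RatioTable, StabilityResult
from .pool_sa import ItemPool, PoolSolution

_ROLE_COLORS = {"unique1": "tab:red", "common": "gold", "unique2": "tab:blue"}
_ROLE_LABELS = {"unique1": "Test 1", "common": "common", "unique2": "Test 2"}


def plot_sorted_difficulties(sorted_difficulties: dict[str, np.ndarray], ax=None, title=None):
    """Dot plot of sorted difficulties, one color per item role."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    offset = 0
    for role in ("unique1", "common", "unique2"):
        vals = np.asarray(sorted_difficulties[role])
        ax.plot(
            np.arange(offset, offset + vals.size), vals, "o", ms=4,
            color=_ROLE_COLORS[role], label=_ROLE_LABELS[role],
        )
        offset += vals.size
    ax.set_xlabel("sorted item index")
    ax.set_ylabel("item difficulty b")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax


def plot_pool_selection(pool: ItemPool, solution: PoolSolution, ax=None, title=None):
    """Pool (a, b) scatter with selected items colored by role."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    lookup = {iid: k for k, iid in enumerate(pool.ids)}
    chosen = set(solution.all_ids)
    rest = [k for k, iid in enumerate(pool.ids) if iid not in chosen]
    ax.plot(pool.b[rest], pool.a[rest], "k.", ms=3, alpha=0.4, label="pool")
    for role in ("unique1", "common", "unique2"):
        idx = [lookup[i] for i in getattr(solution, role)]
        ax.plot(
            pool.b[idx], pool.a[idx], "o", ms=5,
            color=_ROLE_COLORS[role], label=_ROLE_LABELS[role],
        )
    ax.set_xlabel("difficulty b")
    ax.set_ylabel("discrimination a")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax


def plot_ratio_boxplots(table: RatioTable, ax=None):
    """Boxplots of the sigma_O / sigma_A ratios per true distance."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(table.ratios, tick_labels=[f"{d:g}" for d in table.true_d])
    ax.axhline(1.0, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("true distance d")
    ax.set_ylabel(r"ratio $\sigma_O / \sigma_A$")
    return ax


def plot_stability(result: StabilityResult, axes=None):
    """Side-by-side component means and standard deviations."""
    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    ax_m, ax_s = axes
    for role, sl in result.role_slices.items():
        idx = np.arange(sl.start, sl.stop)
        ax_m.plot(idx, result.means[sl], "o", ms=4, color=_ROLE_COLORS[role],
                  label=_ROLE_LABELS[role])
        ax_s.plot(idx, result.sds[sl], "o", ms=4, color=_ROLE_COLORS[role])
    ax_m.set_xlabel("sorted component")
    ax_m.set_ylabel("mean difficulty")
    ax_m.legend(fontsize=8)
    ax_s.set_xlabel("sorted component")
    ax_s.set_ylabel("standard deviation")
    return axes


def save(fig_or_ax, path) -> None:
    ax = fig_or_ax[0] if isinstance(fig_or_ax, (list, tuple, np.ndarray)) else fig_or_ax
    fig = ax.figure if hasattr(ax, "figure") else ax
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
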