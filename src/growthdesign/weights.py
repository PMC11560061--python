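"""Discrete (theta, W) representations of ability distributions.

Design criteria for ability growth are weighted sums over target ability
points; the weights discretize the examinee ability distribution.  Three
constructors cover the designs used in practice:

* :func:`make_normal_grid` — equidistant points with N(mu, sigma^2)
  density-proportional weights (the ordinary weighting scheme);
* :func:`make_in_average_grid` — optimum-in-average weights that integrate
  the N(., 1) ability density over a normal prior on the unknown population
  mean, yielding heavier-tailed N(mu, 1 + sigma_prior^2) weights;
* :func:`make_percentile_grid` — points at distribution percentiles with
  density-proportional weights, for percentile-growth criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AbilityGrid",
    "make_normal_grid",
    "make_in_average_grid",
    "make_percentile_grid",
    "combine_schemes",
]

_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class AbilityGrid:
    """Target ability points with normalized non-negative weights.

    Invariants: equal lengths, weights sum to one (1e-12), points strictly
    increasing.  Constructed via the module's factory functions; combined
    schemes (which may duplicate points) use :class:`WeightedPoints`.
    """

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.points.ndim != 1 or self.points.shape != self.weights.shape:
            raise ValueError("points and weights must be 1-D of equal length")
        if self.points.size < 1:
            raise ValueError("grid needs at least one point")
        if np.any(np.diff(self.points) <= 0):
            raise ValueError("points must be strictly increasing")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError("weights must sum to 1")

    @property
    def l(self) -> int:  # noqa: E743 - matches the (theta, W) grid-size symbol
        return self.points.size


@dataclass(frozen=True)
class WeightedPoints:
    """Like :class:`AbilityGrid` but allowing unordered/duplicate points.

    Produced by :func:`combine_schemes`, where several weighting schemes are
    concatenated and restandardized.
    """

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.points.shape != self.weights.shape or self.points.ndim != 1:
            raise ValueError("points and weights must be 1-D of equal length")
        if abs(self.weights.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError("weights must sum to 1")


def _equidistant(mu: float, l: int, half_width: float) -> np.ndarray:
    if l < 1:
        raise ValueError("l must be >= 1")
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    if l == 1:
        return np.array([float(mu)])
    return np.linspace(mu - half_width, mu + half_width, l)


def _normalize(w: np.ndarray) -> np.ndarray:
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero; grid span leaves no density mass")
    return w / total


def make_normal_grid(
    mu: float, sigma: float, l: int, half_width: float = 4.0
) -> AbilityGrid:
    """Equidistant grid on [mu - half_width, mu + half_width] with
    N(mu, sigma^2) density-proportional weights.

    The default half-width of 4 ability units covers > 0.9999 of an
    N(mu, 1) distribution's mass.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    pts = _equidistant(mu, l, half_width)
    w = _normalize(stats.norm.pdf(pts, loc=mu, scale=sigma))
    return AbilityGrid(pts, w)


def in_average_density(theta, mu_prior: float, sigma_prior: float):
    """Unnormalized optimum-in-average weight density.

    The defining integral  ``int f(theta | x, 1) f(x | mu, sigma^2) dx``
    is a convolution of two normal densities and equals the
    N(mu_prior, 1 + sigma_prior^2) density at ``theta`` in closed form.
    """
    return stats.norm.pdf(theta, loc=mu_prior, scale=np.sqrt(1.0 + sigma_prior**2))


def make_in_average_grid(
    mu_prior: float, sigma_prior: float, l: int, half_width: float = 4.0
) -> AbilityGrid:
    """Equidistant grid weighted by the prior-integrated (in-average) density.

    ``sigma_prior`` is the standard deviation of the normal prior on the
    unknown population mean; ``sigma_prior = 0`` reduces exactly to
    :func:`make_normal_grid` with unit sigma.  The integrated weights have
    heavier tails than the ordinary N(mu, 1) weights, which is what makes
    the resulting design robust to misspecified growth.
    """
    if sigma_prior < 0:
        raise ValueError("sigma_prior must be >= 0")
    pts = _equidistant(mu_prior, l, half_width)
    w = _normalize(in_average_density(pts, mu_prior, sigma_prior))
    return AbilityGrid(pts, w)


def make_percentile_grid(
    percentiles: Sequence[float], mu: float = 0.0, sigma: float = 1.0
) -> AbilityGrid:
    """Grid at N(mu, sigma^2) percentile points, density-weighted.

    ``percentiles`` are in percent, strictly increasing, each in (0, 100).
    For a symmetric set of percentiles the weights are symmetric as well;
    for a single percentile the weight is 1.
    """
    pct = np.asarray(percentiles, dtype=float)
    if pct.size < 1:
        raise ValueError("need at least one percentile")
    if np.any(pct <= 0) or np.any(pct >= 100):
        raise ValueError("percentiles must lie strictly between 0 and 100")
    if np.any(np.diff(pct) <= 0):
        raise ValueError("percentiles must be strictly increasing")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    pts = stats.norm.ppf(pct / 100.0, loc=mu, scale=sigma)
    w = _normalize(stats.norm.pdf(pts, loc=mu, scale=sigma))
    return AbilityGrid(pts, w)


def combine_schemes(
    schemes: Sequence[tuple[AbilityGrid | WeightedPoints, float]]
) -> WeightedPoints:
    """Concatenate weighting schemes with prior masses and restandardize.

    Each entry is ``(grid, mass)``; the combined weights are
    ``mass_k * w_kj`` renormalized so the total is one.  Duplicate points
    are kept as-is (the criterion evaluation is a plain weighted sum).
    """
    if len(schemes) == 0:
        raise ValueError("combine_schemes needs at least one scheme")
    pts, wts = [], []
    for grid, mass in schemes:
        if mass <= 0:
            raise ValueError("scheme masses must be positive")
        pts.append(np.asarray(grid.points, dtype=float))
        wts.append(mass * np.asarray(grid.weights, dtype=float))
    points = np.concatenate(pts)
    weights = np.concatenate(wts)
    return WeightedPoints(points, weights / weights.sum())
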