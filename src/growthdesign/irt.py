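"""Two-parameter logistic (2PL) IRT primitives.

The 2PL model gives the probability of a correct response to item *i* as

    p_i(theta) = 1 / (1 + exp(-a_i * (theta - b_i)))

where ``a_i > 0`` is the item discrimination and ``b_i`` the item difficulty
on the latent logit scale.  The Fisher information an item contributes about
an examinee of ability ``theta`` is ``a_i^2 * p_i * (1 - p_i)``; a test's
information is the sum over its items, and its inverse is the asymptotic
variance of the maximum-likelihood ability estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "Item",
    "prob_correct",
    "item_information",
    "test_information",
    "items_to_arrays",
]


@dataclass(frozen=True)
class Item:
    """One calibrated 2PL item.

    Parameters
    ----------
    a : float
        Discrimination, dimensionless, strictly positive.
    b : float
        Difficulty on the logit (ability) scale.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValueError(f"discrimination a must be finite and > 0, got {self.a}")
        if not np.isfinite(self.b):
            raise ValueError(f"difficulty b must be finite, got {self.b}")


def _check_theta(theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    return theta


def prob_correct(item: Item, theta):
    """Probability of a correct response under the 2PL model.

    ``expit`` evaluates the logistic in a numerically stable way (branching
    on the sign of the exponent), so extreme ``a * (theta - b)`` neither
    overflows nor underflows to an invalid probability.
    """
    theta = _check_theta(theta)
    out = expit(item.a * (theta - item.b))
    return out if out.ndim else float(out)


def item_information(item: Item, theta):
    """Fisher information ``a^2 p (1-p)`` of one item at ``theta``.

    The information is maximized at ``theta == b`` with value ``a^2 / 4``.
    """
    theta = _check_theta(theta)
    p = expit(item.a * (theta - item.b))
    out = item.a**2 * p * (1.0 - p)
    return out if out.ndim else float(out)


def test_information(items: Sequence[Item] | Iterable[Item], theta):
    """Test information function: sum of item information over ``items``."""
    items = list(items)
    if not items:
        raise ValueError("test_information requires at least one item")
    theta = _check_theta(theta)
    total = sum(item_information(it, theta) for it in items)
    return total if np.ndim(total) else float(total)


def items_to_arrays(items: Sequence[Item]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a sequence of items into ``(a, b)`` parameter arrays."""
    a = np.array([it.a for it in items], dtype=float)
    b = np.array([it.b for it in items], dtype=float)
    return a, b


# Exponent clip for the factored batch path.  Within the design box
# (|theta|, |b| <= ~8, a <= 2) each factor's exponent stays below ~20; items
# whose true exponent exceeds 60 contribute information < 1e-25, i.e. zero
# to working precision, so clipping is exact there and keeps (1+w)^2 finite.
_EXP_CLIP = 60.0


def batch_test_information(
    a: np.ndarray, b: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """Test information for a batch of difficulty vectors on an ability grid.

    Parameters
    ----------
    a : (n,) array
        Item discriminations.
    b : (..., n) array
        One or more difficulty vectors.
    theta : (l,) array
        Ability grid points.

    Returns
    -------
    (..., l) array of test information values.

    Notes
    -----
    Writing ``exp(a(theta - b)) = exp(a * theta) * exp(-a * b)`` lets the
    ``l``-sized factor be precomputed once per call, so the large
    ``(..., n, l)`` intermediate needs only cheap elementwise arithmetic:
    with ``w = exp(a(theta-b))``, ``p(1-p) = w / (1+w)^2``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    theta = np.asarray(theta, dtype=float)
    u = np.exp(np.clip(a[:, None] * theta[None, :], -_EXP_CLIP, _EXP_CLIP))  # (n, l)
    v = np.exp(np.clip(-a * b, -_EXP_CLIP, _EXP_CLIP))  # (..., n)
    w = v[..., :, None] * u  # (..., n, l)
    info = (a[:, None] ** 2) * (w / (1.0 + w) ** 2)
    return info.sum(axis=-2)
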