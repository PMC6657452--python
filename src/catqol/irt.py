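"""Rasch partial credit model (PCM) primitives.

The partial credit model (Masters 1982) describes an ordered polytomous
item with categories ``0..m`` through ``m`` step thresholds ``b_1..b_m``
on the same logit scale as the latent trait ``theta``:

    P(X = k | theta)  ∝  exp( sum_{j<=k} (theta - b_j) )

with the empty sum for ``k = 0``.  Everything the adaptive engine needs —
category probabilities, Fisher information and maximum-likelihood trait
estimation with a standard error — lives here.  Item parameters are
inputs (read from CSV/JSON banks); this module does not calibrate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "PcmItem",
    "ItemBank",
    "ThetaEstimate",
    "pcm_category_probs",
    "pcm_expected_score",
    "pcm_item_information",
    "pcm_log_likelihood",
    "estimate_theta_mle",
    "DEFAULT_THETA_BOUNDS",
]

#: Trait estimation interval in logits.  Extreme (all-min / all-max)
#: response patterns have an infinite MLE; clamping keeps the standard
#: error finite so downstream scoring and feedback stay computable.
DEFAULT_THETA_BOUNDS: tuple[float, float] = (-4.0, 4.0)


@dataclass(frozen=True)
class PcmItem:
    """A polytomous item under the partial credit model.

    Parameters
    ----------
    item_id
        Unique identifier within its bank.
    domain_id
        The QoL domain the item measures (physical, psychological, ...).
    thresholds
        Ordered step parameters ``b_1..b_m`` in logits.  The item has
        ``m + 1`` response categories ``0..m``.
    """

    item_id: str
    domain_id: str
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        thr = tuple(float(b) for b in self.thresholds)
        if len(thr) == 0:
            raise ValueError(f"item {self.item_id!r}: thresholds must be non-empty")
        if not np.all(np.isfinite(thr)):
            raise ValueError(f"item {self.item_id!r}: thresholds must be finite")
        object.__setattr__(self, "thresholds", thr)

    @property
    def max_category(self) -> int:
        return len(self.thresholds)

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


@dataclass(frozen=True)
class ThetaEstimate:
    """Latent-trait point estimate with its standard error.

    ``se`` is ``1 / sqrt(total information)`` at the estimate and drives
    the CAT stopping rule.  ``converged`` is False when the likelihood is
    monotone (all responses at a floor or ceiling) and theta was clamped
    to an estimation bound.
    """

    theta: float
    se: float
    n_items_used: int
    converged: bool

    def __post_init__(self) -> None:
        if not self.se > 0:  # +inf allowed
            raise ValueError("standard error must be positive")
        if self.n_items_used < 0:
            raise ValueError("n_items_used must be non-negative")


@dataclass(frozen=True)
class ItemBank:
    """A collection of PCM items grouped by domain."""

    items: tuple[PcmItem, ...]

    def __post_init__(self) -> None:
        items = tuple(self.items)
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item_id in bank")
        object.__setattr__(self, "items", items)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def domains(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for it in self.items:
            seen.setdefault(it.domain_id, None)
        return tuple(seen)

    def for_domain(self, domain_id: str) -> tuple[PcmItem, ...]:
        return tuple(it for it in self.items if it.domain_id == domain_id)

    def get(self, item_id: str) -> PcmItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)


def _check_theta(theta: float) -> float:
    theta = float(theta)
    if not np.isfinite(theta):
        raise ValueError(f"theta must be finite, got {theta}")
    return theta


def pcm_category_probs(item: PcmItem, theta: float) -> np.ndarray:
    """Category probability vector ``P(X = k | theta)`` for ``k = 0..m``.

    Computed in log space (max-shifted) so extreme thetas cannot
    overflow.  The returned vector sums to 1 and every entry is strictly
    positive.
    """
    theta = _check_theta(theta)
    b = np.asarray(item.thresholds, dtype=float)
    # cumulative logits: 0, (theta-b1), (theta-b1)+(theta-b2), ...
    cum = np.concatenate(([0.0], np.cumsum(theta - b)))
    cum -= cum.max()
    w = np.exp(cum)
    return w / w.sum()


def pcm_expected_score(item: PcmItem, theta: float) -> float:
    """Expected category ``E[X | theta]``; strictly increasing in theta."""
    p = pcm_category_probs(item, theta)
    return float(np.arange(p.size) @ p)


def pcm_item_information(item: PcmItem, theta: float) -> float:
    """Fisher information of one item at ``theta``.

    For the Rasch family observed and expected information coincide and
    equal the category variance ``Var(X | theta)``, which is also the
    derivative of the expected score with respect to theta.
    """
    p = pcm_category_probs(item, theta)
    k = np.arange(p.size)
    mean = k @ p
    return float((k - mean) ** 2 @ p)


def pcm_log_likelihood(
    responses: Sequence[tuple[PcmItem, int]], theta: float
) -> float:
    """Joint PCM log-likelihood of independent item responses at ``theta``."""
    ll = 0.0
    for item, k in responses:
        p = pcm_category_probs(item, theta)
        ll += float(np.log(p[k]))
    return ll


def _validate_responses(responses: Sequence[tuple[PcmItem, int]]) -> None:
    if len(responses) == 0:
        raise ValueError("at least one response is required to estimate theta")
    for item, k in responses:
        if not (isinstance(k, (int, np.integer)) and 0 <= k <= item.max_category):
            raise ValueError(
                f"response {k!r} out of range 0..{item.max_category} "
                f"for item {item.item_id!r}"
            )


def estimate_theta_mle(
    responses: Sequence[tuple[PcmItem, int]],
    bounds: tuple[float, float] = DEFAULT_THETA_BOUNDS,
) -> ThetaEstimate:
    """Bounded maximum-likelihood trait estimate with standard error.

    The PCM log-likelihood is strictly concave in theta, so the bounded
    1-D maximisation (tolerance 1e-6) finds the unique maximiser.  For
    all-minimum or all-maximum response patterns the likelihood is
    monotone: theta is clamped to the corresponding bound and
    ``converged`` is False.  ``se = 1 / sqrt(sum of item informations)``
    evaluated at the estimate.
    """
    _validate_responses(responses)
    lo, hi = float(bounds[0]), float(bounds[1])
    if not lo < hi:
        raise ValueError("bounds must satisfy lower < upper")

    cats = np.array([k for _, k in responses])
    maxima = np.array([item.max_category for item, _ in responses])

    if np.all(cats == 0):
        theta, converged = lo, False
    elif np.all(cats == maxima):
        theta, converged = hi, False
    else:
        res = minimize_scalar(
            lambda t: -pcm_log_likelihood(responses, t),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        theta, converged = float(res.x), bool(res.success)

    info = sum(pcm_item_information(item, theta) for item, _ in responses)
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    return ThetaEstimate(theta=theta, se=se, n_items_used=len(responses), converged=converged)
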