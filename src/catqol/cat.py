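"""Adaptive test administration and norm-referenced 0-100 scoring.

One CAT session administers items from a single domain's bank: estimate
the trait, pick the unadministered item with maximum Fisher information
at the provisional estimate, record the response, re-estimate, and stop
at the first of (a) standard error below ``se_stop`` after at least
``min_items_per_domain`` items, (b) bank exhausted, (c) item cap.  The
default ``se_stop`` of 0.45 logits corresponds to a marginal reliability
of roughly 0.80 under a unit-variance trait.

The final trait estimate is mapped to a norm-referenced Z score and then
to the 0 (worst) .. 100 (best) reporting scale via ``50 + (100/6)*z``
clipped to the scale, so +/-3 reference SD spans the whole range.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping

from .irt import (
    DEFAULT_THETA_BOUNDS,
    ItemBank,
    PcmItem,
    ThetaEstimate,
    estimate_theta_mle,
    pcm_item_information,
)

__all__ = [
    "StopReason",
    "CatConfig",
    "CatSession",
    "DomainScore",
    "select_next_item",
    "run_cat",
    "theta_to_domain_score",
    "session_to_jsonl",
]


class StopReason(str, enum.Enum):
    SE_REACHED = "se_reached"
    BANK_EXHAUSTED = "bank_exhausted"
    MAX_ITEMS = "max_items"


@dataclass(frozen=True)
class CatConfig:
    """Tunables of the adaptive loop and the score transformation.

    ``norms`` maps a domain id to the reference-population mean and SD of
    theta (logits) used for the Z transform; domains absent from the map
    cannot be scored on 0-100.
    """

    se_stop: float = 0.45
    max_items_per_domain: int | None = None
    min_items_per_domain: int = 2
    theta_init: float = 0.0
    bounds: tuple[float, float] = DEFAULT_THETA_BOUNDS
    norms: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.se_stop > 0:
            raise ValueError("se_stop must be positive")
        if self.min_items_per_domain < 1:
            raise ValueError("min_items_per_domain must be >= 1")
        if (
            self.max_items_per_domain is not None
            and self.max_items_per_domain < self.min_items_per_domain
        ):
            raise ValueError("max_items_per_domain must be >= min_items_per_domain")
        for dom, (_, sd) in dict(self.norms).items():
            if not sd > 0:
                raise ValueError(f"norm SD for domain {dom!r} must be positive")


@dataclass
class CatSession:
    """Record of one adaptive administration for one domain."""

    domain_id: str
    administered: list[tuple[str, int]]
    trajectory: list[ThetaEstimate]
    stopped_reason: StopReason

    @property
    def n_items(self) -> int:
        return len(self.administered)

    @property
    def final(self) -> ThetaEstimate:
        return self.trajectory[-1]


@dataclass(frozen=True)
class DomainScore:
    """Norm-referenced domain score on the 0-100 reporting scale."""

    domain_id: str
    z: float
    score_0_100: float
    source: str  # "cat" | "fixed"

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_0_100 <= 100.0:
            raise ValueError("score_0_100 must lie in [0, 100]")


class BankExhausted(Exception):
    """No unadministered items remain for the session's domain."""


def select_next_item(
    bank: ItemBank,
    administered_ids: set[str] | frozenset[str],
    theta: float,
    domain_id: str,
) -> PcmItem:
    """Unadministered item of the domain with maximum information at theta.

    Ties are broken by lexicographic ``item_id`` so selection is fully
    deterministic.
    """
    candidates = [
        it for it in bank.for_domain(domain_id) if it.item_id not in administered_ids
    ]
    if not candidates:
        raise BankExhausted(domain_id)
    return max(
        candidates, key=lambda it: (pcm_item_information(it, theta), _revlex(it.item_id))
    )


def _revlex(s: str) -> tuple[int, ...]:
    # max() keeps the first of equal keys; encode "smaller id wins" by
    # comparing on negated codepoints.
    return tuple(-ord(c) for c in s)


def run_cat(
    bank: ItemBank,
    responder: Callable[[PcmItem], int],
    config: CatConfig,
    domain_id: str,
) -> CatSession:
    """Run one adaptive session for ``domain_id`` against ``responder``.

    ``responder`` maps an item to the observed category (e.g. a seeded
    PCM sampler at a simulated respondent's true theta, or a replay of
    recorded responses).  Returns the full session with the estimate
    trajectory after every response.
    """
    if not bank.for_domain(domain_id):
        raise ValueError(f"bank has no items for domain {domain_id!r}")

    administered: list[tuple[str, int]] = []
    trajectory: list[ThetaEstimate] = []
    responses: list[tuple[PcmItem, int]] = []
    theta = float(config.theta_init)

    while True:
        try:
            item = select_next_item(bank, {i for i, _ in administered}, theta, domain_id)
        except BankExhausted:
            n = len(administered)
            last = trajectory[-1] if trajectory else None
            if last is not None and n >= config.min_items_per_domain and last.se < config.se_stop:
                reason = StopReason.SE_REACHED
            else:
                reason = StopReason.BANK_EXHAUSTED
            return CatSession(domain_id, administered, trajectory, reason)

        category = int(responder(item))
        if not 0 <= category <= item.max_category:
            raise ValueError(
                f"responder returned category {category} out of range "
                f"0..{item.max_category} for item {item.item_id!r}"
            )
        administered.append((item.item_id, category))
        responses.append((item, category))
        est = estimate_theta_mle(responses, bounds=config.bounds)
        trajectory.append(est)
        theta = est.theta

        n = len(administered)
        if n >= config.min_items_per_domain and est.se < config.se_stop:
            return CatSession(domain_id, administered, trajectory, StopReason.SE_REACHED)
        if config.max_items_per_domain is not None and n >= config.max_items_per_domain:
            return CatSession(domain_id, administered, trajectory, StopReason.MAX_ITEMS)


def theta_to_domain_score(
    theta_est: ThetaEstimate | float,
    config: CatConfig,
    domain_id: str,
    source: str = "cat",
) -> DomainScore:
    """Map a trait estimate to the norm-referenced 0-100 scale.

    ``z = (theta - norm_mean) / norm_sd`` and
    ``score = clip(50 + (100/6) * z, 0, 100)``.
    """
    if domain_id not in config.norms:
        raise KeyError(f"no norm parameters configured for domain {domain_id!r}")
    mean, sd = config.norms[domain_id]
    theta = theta_est.theta if isinstance(theta_est, ThetaEstimate) else float(theta_est)
    z = (theta - mean) / sd
    score = min(100.0, max(0.0, 50.0 + (100.0 / 6.0) * z))
    return DomainScore(domain_id=domain_id, z=z, score_0_100=score, source=source)


def session_to_jsonl(session: CatSession) -> str:
    """Serialize a session as JSON lines, one record per administered item."""
    lines = []
    for (item_id, category), est in zip(session.administered, session.trajectory):
        lines.append(
            json.dumps(
                {
                    "domain_id": session.domain_id,
                    "item_id": item_id,
                    "category": category,
                    "theta": round(est.theta, 6),
                    "se": round(est.se, 6) if est.se != float("inf") else None,
                }
            )
        )
    return "\n".join(lines) + "\n"
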