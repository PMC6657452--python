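"""Ordinal psychometrics for the acceptability analysis.

Implemented from first principles (each routine is cross-checked against
an independent oracle in the test suite):

* Cliff's delta — the dominance effect size
  ``d = (#{x_i > y_j} - #{x_i < y_j}) / (n_x n_y)`` with the consistent
  variance estimator (Cliff 1993) and a normal-quantile 95% CI truncated
  to [-1, 1].
* Wilcoxon rank-sum test — exact two-sided P by full enumeration of the
  pooled multiset's splits for small samples, tie-corrected normal
  approximation with continuity correction otherwise.
* Loevinger's H — polytomous Mokken scalability via weighted Guttman
  errors, ``H = 1 - F/E`` at the item-pair, item and scale level, with a
  greedy automated item selection procedure (AISP) at lower bound .3.
* Cronbach's alpha — classical internal consistency.
* The study's evidence convention — P < .005 significant, .005 <= P < .05
  suggestive, otherwise null.
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "Verdict",
    "EffectSizeResult",
    "MokkenResult",
    "ReliabilityResult",
    "AcceptabilityRecord",
    "CONDITIONS",
    "SURVEY_ITEMS",
    "cliffs_delta",
    "wilcoxon_rank_sum",
    "classify_p",
    "compare_groups",
    "loevinger_h",
    "cronbach_alpha",
]

#: The six experimental arms: assessment form x feedback condition.
CONDITIONS: tuple[str, ...] = (
    "fixed_none",
    "fixed_graphical",
    "fixed_graphical_text",
    "cat_none",
    "cat_graphical",
    "cat_graphical_text",
)

#: The four acceptability/engagement survey items (0-4 Likert each).
SURVEY_ITEMS: tuple[str, ...] = ("interesting", "information", "share", "recommend")


class Verdict(str, enum.Enum):
    SIGNIFICANT = "significant"
    SUGGESTIVE = "suggestive"
    NULL = "null"


def classify_p(p: float) -> Verdict:
    """Apply the P < .005 significant / P < .05 suggestive convention."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.005:
        return Verdict.SIGNIFICANT
    if p < 0.05:
        return Verdict.SUGGESTIVE
    return Verdict.NULL


@dataclass(frozen=True)
class EffectSizeResult:
    """Cliff's delta with CI, rank-test P and the evidence verdict."""

    delta: float
    ci_low: float
    ci_high: float
    se: float
    p_value: float | None = None
    verdict: Verdict | None = None

    def __post_init__(self) -> None:
        if not (-1.0 <= self.ci_low <= self.delta <= self.ci_high <= 1.0):
            raise ValueError("require -1 <= ci_low <= delta <= ci_high <= 1")


@dataclass(frozen=True)
class MokkenResult:
    item_h: dict[str, float]
    scale_h: float
    selected_scales: tuple[tuple[str, ...], ...]
    classification: str  # weak | medium | strong

    @property
    def unidimensional(self) -> bool:
        """All items land in a single selected scale."""
        return len(self.selected_scales) == 1 and len(self.selected_scales[0]) == len(
            self.item_h
        )


@dataclass(frozen=True)
class ReliabilityResult:
    alpha: float
    n_items: int
    n_respondents: int


@dataclass(frozen=True)
class AcceptabilityRecord:
    """One respondent's post-assessment survey row.

    ``items`` are the four 0-4 Likert responses in ``SURVEY_ITEMS`` order;
    ``total`` is their 0-16 sum.  ``feedback_seconds`` is None exactly for
    the no-feedback arms.  ``appraisal`` holds the extra feedback-appraisal
    Likert items asked only in feedback arms.
    """

    respondent_id: str
    condition: str
    items: tuple[int, int, int, int]
    attention_failed: bool = False
    feedback_seconds: float | None = None
    appraisal: dict[str, int] = field(default_factory=dict)
    age: int | None = None
    gender: str | None = None
    working_status: str | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if len(self.items) != 4 or not all(0 <= v <= 4 for v in self.items):
            raise ValueError("items must be four integers in 0..4")
        has_feedback = not self.condition.endswith("_none")
        if (self.feedback_seconds is not None) != has_feedback:
            raise ValueError(
                "feedback_seconds must be present iff the condition shows feedback"
            )
        if self.feedback_seconds is not None and self.feedback_seconds < 0:
            raise ValueError("feedback_seconds must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.items))


# ---------------------------------------------------------------------------
# Cliff's delta
# ---------------------------------------------------------------------------

def cliffs_delta(
    x: Sequence[float], y: Sequence[float], conf_level: float = 0.95
) -> EffectSizeResult:
    """Cliff's dominance delta of ``x`` over ``y`` with a normal CI.

    The dominance matrix ``d_ij = sign(x_i - y_j)`` is evaluated exactly;
    delta is its mean.  The CI uses Cliff's consistent variance estimate
    with the normal quantile, truncated to [-1, 1].  For degenerate
    samples (every pair tied) the variance is 0 and the CI collapses.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size

    dom = np.sign(x[:, None] - y[None, :])
    d = float(dom.mean())
    di = dom.mean(axis=1)  # row means: dominance of each x_i
    dj = dom.mean(axis=0)  # col means
    if n1 > 1 and n2 > 1:
        s2 = (
            n2**2 * np.sum((di - d) ** 2)
            + n1**2 * np.sum((dj - d) ** 2)
            - np.sum((dom - d) ** 2)
        ) / (n1 * n2 * (n1 - 1) * (n2 - 1))
        s2 = max(float(s2), 0.0)
    else:
        s2 = float("nan")
    se = float(np.sqrt(s2))
    z = float(norm.ppf(0.5 + conf_level / 2.0))
    if np.isfinite(se):
        lo = max(-1.0, d - z * se)
        hi = min(1.0, d + z * se)
    else:
        lo, hi = -1.0, 1.0
    return EffectSizeResult(delta=d, ci_low=lo, ci_high=hi, se=se)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

#: Pooled sample size at and below which the exact permutation null is used.
EXACT_CUTOFF = 20


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) P value.

    For pooled ``n <= 20`` the exact null is enumerated: every split of
    the pooled multiset (midranks for ties) is equally likely, and the
    P value is the proportion of splits whose rank sum deviates from its
    mean at least as much as observed.  Above the cutoff a tie-corrected
    normal approximation with continuity correction is used.  If every
    pooled value is identical there is no evidence either way and P = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all pooled values identical; rank test carries no information")
        return 1.0
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = rankdata(pooled)  # midranks
    w_obs = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0

    if n <= EXACT_CUTOFF:
        dev = abs(w_obs - mu) - 1e-9
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), n1):
            w = ranks[list(idx)].sum()
            total += 1
            if abs(w - mu) >= dev:
                count += 1
        return count / total

    # tie-corrected normal approximation
    _, t = np.unique(pooled, return_counts=True)
    tie_term = np.sum(t**3 - t) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0
    dev = abs(w_obs - mu)
    z = max(dev - 0.5, 0.0) / np.sqrt(sigma2)  # continuity correction
    return float(min(1.0, 2.0 * norm.sf(z)))


def compare_groups(x: Sequence[float], y: Sequence[float]) -> EffectSizeResult:
    """Cliff's delta + rank-sum P + evidence verdict for one comparison."""
    base = cliffs_delta(x, y)
    p = wilcoxon_rank_sum(x, y)
    return EffectSizeResult(
        delta=base.delta,
        ci_low=base.ci_low,
        ci_high=base.ci_high,
        se=base.se,
        p_value=p,
        verdict=classify_p(p),
    )


# ---------------------------------------------------------------------------
# Mokken scalability (Loevinger's H)
# ---------------------------------------------------------------------------

def _pair_guttman_fe(xi: np.ndarray, xj: np.ndarray) -> tuple[float, float]:
    """Observed (F) and expected-under-independence (E) weighted Guttman
    errors for one item pair.

    Each item category step ``X >= s`` is a dichotomous "subtask" with
    sample popularity ``P(X >= s)``.  Steps of both items are ordered by
    decreasing popularity; a response cell commits one weighted error per
    pair of steps in which the less popular step is passed while a more
    popular one is failed (Molenaar's polytomous weights).
    """
    n = xi.size
    mi, mj = int(xi.max()), int(xj.max())
    # step popularities: (item, s) -> P(X >= s), s = 1..m
    steps: list[tuple[float, int, int]] = []  # (popularity, item_idx, s)
    for s in range(1, mi + 1):
        steps.append((float(np.mean(xi >= s)), 0, s))
    for s in range(1, mj + 1):
        steps.append((float(np.mean(xj >= s)), 1, s))
    # decreasing popularity; deterministic tie-break by (item, step)
    steps.sort(key=lambda t: (-t[0], t[1], t[2]))

    # cross-tabs
    obs = np.zeros((mi + 1, mj + 1))
    np.add.at(obs, (xi, xj), 1.0)
    pi = obs.sum(axis=1)
    pj = obs.sum(axis=0)
    exp = np.outer(pi, pj) / n

    # weight per cell = number of inverted step pairs (earlier=more popular
    # failed, later passed)
    weights = np.zeros_like(obs)
    for a in range(mi + 1):
        for b in range(mj + 1):
            passed = [(a >= s) if item == 0 else (b >= s) for _, item, s in steps]
            w = 0
            failed_so_far = 0
            for p in passed:
                if p:
                    w += failed_so_far
                else:
                    failed_so_far += 1
            weights[a, b] = w

    return float(np.sum(weights * obs)), float(np.sum(weights * exp))


def loevinger_h(
    data: np.ndarray | Sequence[Sequence[int]],
    item_labels: Sequence[str] | None = None,
    lower_bound: float = 0.3,
) -> MokkenResult:
    """Mokken scale analysis of a respondent x item ordinal matrix.

    Returns per-item and total-scale Loevinger H (``1 - F/E`` over the
    relevant pair sums) plus the greedy AISP partition at ``lower_bound``.
    Pairs with zero expected errors (degenerate marginals) are excluded
    with a warning.  Scale classification follows the conventional
    cutoffs: weak below .3, strong above .5, medium between.
    """
    X = np.asarray(data, dtype=int)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 items")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 respondents")
    if np.any(X < 0):
        raise ValueError("categories must be non-negative integers")
    n, k = X.shape
    labels = list(item_labels) if item_labels is not None else [f"item{i+1}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("item_labels length must match the number of items")

    F = np.full((k, k), np.nan)
    E = np.full((k, k), np.nan)
    for i, j in itertools.combinations(range(k), 2):
        f, e = _pair_guttman_fe(X[:, i], X[:, j])
        if e <= 0:
            warnings.warn(
                f"item pair ({labels[i]}, {labels[j]}) has zero expected Guttman "
                "errors (degenerate marginals); pair excluded"
            )
            continue
        F[i, j] = F[j, i] = f
        E[i, j] = E[j, i] = e

    def h_pair(i: int, j: int) -> float:
        return 1.0 - F[i, j] / E[i, j]

    item_h: dict[str, float] = {}
    for i in range(k):
        mask = ~np.isnan(E[i])
        item_h[labels[i]] = float(1.0 - np.nansum(F[i]) / np.nansum(E[i])) if mask.any() else float("nan")
    tot_mask = ~np.isnan(np.triu(E, 1))
    total_f = np.nansum(np.triu(F, 1))
    total_e = np.nansum(np.triu(E, 1))
    scale_h = float(1.0 - total_f / total_e) if total_e > 0 else float("nan")

    scales = _aisp(F, E, labels, lower_bound)
    if np.isnan(scale_h) or scale_h < 0.3:
        cls = "weak"
    elif scale_h > 0.5:
        cls = "strong"
    else:
        cls = "medium"
    return MokkenResult(item_h=item_h, scale_h=scale_h, selected_scales=scales, classification=cls)


def _aisp(
    F: np.ndarray, E: np.ndarray, labels: list[str], c: float
) -> tuple[tuple[str, ...], ...]:
    """Greedy automated item selection at lower bound ``c``.

    Start each scale from the best remaining pair with H_ij >= c, then
    repeatedly add the item that maximises the scale H while keeping its
    own within-scale item H >= c.  Items never placed remain unscaled.
    """
    k = len(labels)

    def pair_h(i: int, j: int) -> float:
        if np.isnan(E[i, j]) or E[i, j] <= 0:
            return float("-inf")
        return 1.0 - F[i, j] / E[i, j]

    def scale_h_of(idx: list[int]) -> float:
        f = sum(F[i, j] for i, j in itertools.combinations(idx, 2) if not np.isnan(F[i, j]))
        e = sum(E[i, j] for i, j in itertools.combinations(idx, 2) if not np.isnan(E[i, j]))
        return 1.0 - f / e if e > 0 else float("nan")

    def item_h_in(i: int, idx: list[int]) -> float:
        others = [j for j in idx if j != i]
        f = sum(F[i, j] for j in others if not np.isnan(F[i, j]))
        e = sum(E[i, j] for j in others if not np.isnan(E[i, j]))
        return 1.0 - f / e if e > 0 else float("nan")

    remaining = set(range(k))
    scales: list[tuple[str, ...]] = []
    while len(remaining) >= 2:
        pairs = [
            (pair_h(i, j), i, j)
            for i, j in itertools.combinations(sorted(remaining), 2)
        ]
        best = max(pairs, key=lambda t: t[0])
        if best[0] < c:
            break
        current = [best[1], best[2]]
        remaining -= set(current)
        while remaining:
            candidates = []
            for m in sorted(remaining):
                trial = current + [m]
                hm = item_h_in(m, trial)
                if np.isnan(hm) or hm < c:
                    continue
                if any(item_h_in(i, trial) < c for i in current):
                    continue
                candidates.append((scale_h_of(trial), m))
            if not candidates:
                break
            _, pick = max(candidates)
            current.append(pick)
            remaining.discard(pick)
        scales.append(tuple(labels[i] for i in sorted(current)))
    return tuple(scales)


# ---------------------------------------------------------------------------
# Cronbach's alpha
# ---------------------------------------------------------------------------

def cronbach_alpha(data: np.ndarray | Sequence[Sequence[float]]) -> ReliabilityResult:
    """Cronbach's alpha: ``k/(k-1) * (1 - sum(var_i) / var_total)``.

    Sample variances use denominator ``n - 1``.  Raises if the total
    score has zero variance (alpha undefined).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 items")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 respondents")
    n, k = X.shape
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance; alpha is undefined")
    alpha = k / (k - 1) * (1.0 - item_vars.sum() / total_var)
    return ReliabilityResult(alpha=float(alpha), n_items=k, n_respondents=n)
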