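"""Seeded generators for every input the study pipeline consumes.

Three generators:

* ``generate_bank`` — synthetic per-domain PCM item banks standing in
  for the (copyrighted) WHOQOL-100 item pool: item centers span the
  trait range and step thresholds fan out around them.
* ``generate_respondents`` — latent traits ``theta ~ N(0, 1)`` per
  domain and PCM-sampled responses to every bank item, with the truth
  table retained for parameter-recovery checks.
* ``generate_acceptability`` — six-arm post-assessment surveys.  Each
  respondent has a shared normal latent "favourability" (so the four
  Likert items are positively correlated, as a coherent acceptability
  scale requires); item responses discretize the latent plus logistic
  noise at fixed cutpoints whose mass sits toward the agree end,
  mirroring the skew of real acceptability ratings.  Between-condition
  location shifts are calibrated by root finding so the *population*
  Cliff delta of the 0-16 total versus the control arm hits the
  configured target exactly (the population total pmf is computed by
  Gauss-Hermite integration over the shared latent and convolution over
  items).  Attention-check failures are Bernoulli; feedback-viewing
  times are log-normal with per-condition medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .irt import ItemBank, PcmItem, pcm_category_probs
from .psych import CONDITIONS, SURVEY_ITEMS, AcceptabilityRecord

__all__ = [
    "BankSpec",
    "SynthConfig",
    "CalibrationError",
    "generate_bank",
    "generate_respondents",
    "generate_acceptability",
    "population_total_pmf",
    "population_cliffs_delta",
    "calibrate_shift",
    "condition_shifts",
    "records_to_frame",
    "frame_to_records",
    "DOMAINS",
]

DOMAINS: tuple[str, ...] = ("physical", "psychological", "social", "environment")


class CalibrationError(ValueError):
    """The requested population effect size is unattainable."""


# ---------------------------------------------------------------------------
# Item banks and PCM responses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BankSpec:
    """Shape of the synthetic item banks.

    ``dispersion`` scales both the spread of item centers (which span
    ``[-center_span, center_span]`` at dispersion 1) and the jitter, so
    dispersion 0 makes every item identical.  ``step_offsets`` are the
    within-item threshold offsets; the defaults give 6-category items
    informative enough that the SE < 0.45 rule terminates after roughly
    4-5 items per domain (about 18 items total across the 4 domains).
    """

    domains: tuple[str, ...] = DOMAINS
    n_items_per_domain: int = 25
    step_offsets: tuple[float, ...] = (-1.3, -0.65, 0.0, 0.65, 1.3)
    center_span: float = 2.0
    jitter_sd: float = 0.15
    dispersion: float = 1.0

    def __post_init__(self) -> None:
        if self.n_items_per_domain < 1:
            raise ValueError("n_items_per_domain must be >= 1")
        if len(self.step_offsets) < 1:
            raise ValueError("items need at least one step")


def generate_bank(spec: BankSpec, seed: int) -> ItemBank:
    """Deterministic synthetic PCM bank for every domain of ``spec``."""
    rng = np.random.default_rng(seed)
    items = []
    for dom in spec.domains:
        n = spec.n_items_per_domain
        centers = spec.dispersion * (
            np.linspace(-spec.center_span, spec.center_span, n) if n > 1 else np.zeros(1)
        )
        for i, c in enumerate(centers, start=1):
            jitter = spec.dispersion * rng.normal(0.0, spec.jitter_sd, len(spec.step_offsets))
            thr = np.sort(np.asarray(spec.step_offsets) + c + jitter)
            items.append(
                PcmItem(item_id=f"{dom[:4]}_{i:02d}", domain_id=dom, thresholds=tuple(thr))
            )
    return ItemBank(items=tuple(items))


def generate_respondents(
    bank: ItemBank, n: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent traits and full-bank PCM responses for ``n`` respondents.

    Returns ``(responses, thetas)``: ``responses`` is respondent x item
    (integer categories), ``thetas`` respondent x domain, both indexed by
    respondent id ``r0001..``.  Traits are N(0, 1) per domain.
    """
    rng = np.random.default_rng(seed)
    ids = [f"r{i+1:04d}" for i in range(n)]
    domains = bank.domains
    theta = pd.DataFrame(
        rng.standard_normal((n, len(domains))), index=ids, columns=list(domains)
    )
    cols: dict[str, np.ndarray] = {}
    for item in bank:
        t = theta[item.domain_id].to_numpy()
        # vectorized PCM sampling: cumulative logits per respondent
        b = np.asarray(item.thresholds)
        cum = np.concatenate(
            [np.zeros((n, 1)), np.cumsum(t[:, None] - b[None, :], axis=1)], axis=1
        )
        cum -= cum.max(axis=1, keepdims=True)
        w = np.exp(cum)
        p = w / w.sum(axis=1, keepdims=True)
        u = rng.random(n)
        cols[item.item_id] = (u[:, None] > np.cumsum(p, axis=1)[:, :-1]).sum(axis=1)
    responses = pd.DataFrame(cols, index=ids)
    return responses, theta


# ---------------------------------------------------------------------------
# Acceptability surveys
# ---------------------------------------------------------------------------

#: Fixed cutpoints of the item-discretization latent (an item response is
#: the number of cutpoints below latent + logistic noise).  Chosen so the
#: control arm's 0-16 total has mean ~11.5 and SD ~2.9 with mass toward
#: the agree end.
CUTPOINTS: tuple[float, ...] = (-4.1, -2.8, -1.3, 0.95)

#: SD of the shared per-respondent latent; with unit-scale logistic item
#: noise this yields inter-item correlation ~0.45 (alpha ~0.75 for 4 items).
LATENT_SD: float = 1.7

#: Appraisal item response distributions (0-4), mass concentrated on
#: agreement as observed for feedback accuracy/clarity ratings.
_APPRAISAL_PMF: dict[str, tuple[float, ...]] = {
    "graphical_accurate": (0.030, 0.060, 0.086, 0.350, 0.474),
    "graphical_clear": (0.010, 0.019, 0.042, 0.300, 0.629),
    "text_accurate": (0.035, 0.072, 0.075, 0.350, 0.468),
    "text_clear": (0.005, 0.010, 0.034, 0.300, 0.651),
}

_GENDER_PMF = {"female": 0.483, "male": 0.392, "not_reported": 0.125}
_WORK_PMF = {
    "full_time": 0.401,
    "part_time": 0.163,
    "education": 0.046,
    "home": 0.097,
    "retired": 0.056,
    "disabled": 0.042,
    "unemployed": 0.040,
    "other": 0.155,
}


@dataclass(frozen=True)
class SynthConfig:
    """Study-level generator settings.

    ``condition_sizes`` are the target *analyzed* arm sizes (after the
    attention filter); enrollment per arm is inflated by
    ``1 / (1 - attention_fail_rate)`` so the expected enrolled total
    matches ``n_respondents``.  ``target_deltas`` give the population
    Cliff delta of each arm's 0-16 total versus the fixed/no-feedback
    control; ``pooled_graphical_text_delta`` instead calibrates a single
    shift for both graphical+text arms against the pooled no-feedback
    population.  ``time_medians`` are feedback-viewing medians in seconds
    for the four feedback arms.
    """

    n_respondents: int = 1454
    condition_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "fixed_none": 226,
            "fixed_graphical": 247,
            "fixed_graphical_text": 219,
            "cat_none": 223,
            "cat_graphical": 211,
            "cat_graphical_text": 260,
        }
    )
    target_deltas: Mapping[str, float] = field(
        default_factory=lambda: {
            "fixed_graphical": 0.09,
            "cat_none": -0.11,
            "cat_graphical": 0.01,
        }
    )
    pooled_graphical_text_delta: float | None = 0.22
    attention_fail_rate: float = 68 / 1454
    time_medians: Mapping[str, float] = field(
        default_factory=lambda: {
            "fixed_graphical": 115.0,
            "fixed_graphical_text": 132.0,
            "cat_graphical": 124.0,
            "cat_graphical_text": 147.0,
        }
    )
    time_log_sd: float = 0.55
    bank_spec: BankSpec = field(default_factory=BankSpec)

    def __post_init__(self) -> None:
        sizes = dict(self.condition_sizes)
        if set(sizes) - set(CONDITIONS):
            raise ValueError(f"unknown conditions in condition_sizes: {set(sizes) - set(CONDITIONS)}")
        if sum(sizes.values()) > self.n_respondents:
            raise ValueError("condition sizes must sum to at most n_respondents")
        if not 0.0 <= self.attention_fail_rate < 1.0:
            raise ValueError("attention_fail_rate must lie in [0, 1)")
        for cmp, d in dict(self.target_deltas).items():
            if not -1.0 < d < 1.0:
                raise ValueError(f"target delta for {cmp!r} must lie in (-1, 1)")


# --- population machinery ---------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(61)


def _item_pmf_given_latent(a: np.ndarray) -> np.ndarray:
    """P(item response = t | shared latent a); logistic noise, fixed cutpoints."""
    c = np.asarray(CUTPOINTS)
    cdf = expit(c[None, :] - a[:, None])  # P(X <= t-1 boundaries)
    cdf = np.concatenate([cdf, np.ones((a.size, 1))], axis=1)
    pmf = np.diff(np.concatenate([np.zeros((a.size, 1)), cdf], axis=1), axis=1)
    return pmf


def population_total_pmf(mu: float, n_items: int = 4) -> np.ndarray:
    """Exact pmf of the 0-16 survey total for a condition at shift ``mu``.

    Items are conditionally iid given the shared latent
    ``a ~ N(mu, LATENT_SD)``: convolve the conditional item pmf
    ``n_items`` times, then integrate over ``a`` with Gauss-Hermite
    quadrature (61 nodes).
    """
    a = mu + LATENT_SD * _GH_NODES
    w = _GH_WEIGHTS / _GH_WEIGHTS.sum()
    pmf_items = _item_pmf_given_latent(a)  # nodes x 5
    out = np.zeros(4 * len(CUTPOINTS) + 1)
    for wi, p in zip(w, pmf_items):
        conv = p
        for _ in range(n_items - 1):
            conv = np.convolve(conv, p)
        out += wi * conv
    return out


def population_cliffs_delta(p: np.ndarray, q: np.ndarray) -> float:
    """Cliff delta of distribution ``p`` over ``q`` on a common ordinal support."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    s = len(p)
    sgn = np.sign(np.arange(s)[:, None] - np.arange(len(q))[None, :])
    return float(p @ sgn @ q)


def calibrate_shift(
    target_delta: float,
    ref_pmf: np.ndarray,
    bounds: tuple[float, float] = (-5.0, 5.0),
    tol: float = 1e-10,
) -> float:
    """Latent shift whose population total delta vs ``ref_pmf`` hits the target.

    The delta is strictly increasing in the shift, so a bracketing root
    find suffices; raises :class:`CalibrationError` (reporting the
    achievable range) if the target lies outside what the discretization
    can produce within ``bounds``.
    """
    def f(mu: float) -> float:
        return population_cliffs_delta(population_total_pmf(mu), ref_pmf) - target_delta

    lo, hi = bounds
    flo, fhi = f(lo), f(hi)
    if not flo <= 0 <= fhi:
        raise CalibrationError(
            f"target delta {target_delta} unattainable; achievable range is "
            f"[{flo + target_delta:.4f}, {fhi + target_delta:.4f}]"
        )
    return float(brentq(f, lo, hi, xtol=tol))


def condition_shifts(config: SynthConfig) -> dict[str, float]:
    """Calibrated latent shift per condition (control fixed at 0)."""
    shifts = {"fixed_none": 0.0}
    ref = population_total_pmf(0.0)
    for cond, d in config.target_deltas.items():
        shifts[cond] = calibrate_shift(d, ref)
    gt_arms = ("fixed_graphical_text", "cat_graphical_text")
    if config.pooled_graphical_text_delta is not None:
        # pooled no-feedback population: mixture of the two none arms
        sizes = dict(config.condition_sizes)
        w0 = sizes.get("fixed_none", 0)
        w1 = sizes.get("cat_none", 0)
        none_mix = (
            w0 * ref + w1 * population_total_pmf(shifts.get("cat_none", 0.0))
        ) / max(w0 + w1, 1)
        s = calibrate_shift(config.pooled_graphical_text_delta, none_mix)
        for cond in gt_arms:
            shifts[cond] = s
    for cond in CONDITIONS:
        shifts.setdefault(cond, 0.0)
    return shifts


# --- sampling ---------------------------------------------------------------

def _sample_categorical(rng: np.random.Generator, pmf: Sequence[float], n: int) -> np.ndarray:
    p = np.asarray(pmf, dtype=float)
    p = p / p.sum()
    return rng.choice(len(p), size=n, p=p)


def generate_acceptability(config: SynthConfig, seed: int) -> list[AcceptabilityRecord]:
    """Simulate the six-arm acceptability survey, enrollment to flags.

    Deterministic per (config, seed).  Arm enrollment is the analyzed
    target size inflated by the attention-failure rate; every record
    carries the four Likert items, demographics, an attention flag and —
    for feedback arms — appraisal items and a viewing time.
    """
    rng = np.random.default_rng(seed)
    shifts = condition_shifts(config)
    records: list[AcceptabilityRecord] = []
    rid = 0
    for cond in CONDITIONS:
        target_n = dict(config.condition_sizes).get(cond, 0)
        if target_n == 0:
            continue
        n_enrolled = int(round(target_n / (1.0 - config.attention_fail_rate)))
        a = rng.normal(shifts[cond], LATENT_SD, n_enrolled)
        noise = rng.logistic(0.0, 1.0, (n_enrolled, 4))
        latent = a[:, None] + noise
        items = (latent[:, :, None] > np.asarray(CUTPOINTS)[None, None, :]).sum(axis=2)
        flags = rng.random(n_enrolled) < config.attention_fail_rate
        ages = np.clip(np.round(rng.normal(40, 12, n_enrolled)), 18, 75).astype(int)
        genders = _sample_categorical(rng, list(_GENDER_PMF.values()), n_enrolled)
        works = _sample_categorical(rng, list(_WORK_PMF.values()), n_enrolled)
        has_feedback = not cond.endswith("_none")
        has_text = cond.endswith("graphical_text")
        if has_feedback:
            median = dict(config.time_medians)[cond]
            secs = rng.lognormal(np.log(median), config.time_log_sd, n_enrolled)
            appraisal_items = ["graphical_accurate", "graphical_clear"]
            if has_text:
                appraisal_items += ["text_accurate", "text_clear"]
            appraisals = {
                name: _sample_categorical(rng, _APPRAISAL_PMF[name], n_enrolled)
                for name in appraisal_items
            }
        for i in range(n_enrolled):
            rid += 1
            records.append(
                AcceptabilityRecord(
                    respondent_id=f"p{rid:04d}",
                    condition=cond,
                    items=tuple(int(v) for v in items[i]),
                    attention_failed=bool(flags[i]),
                    feedback_seconds=float(secs[i]) if has_feedback else None,
                    appraisal={k: int(v[i]) for k, v in appraisals.items()} if has_feedback else {},
                    age=int(ages[i]),
                    gender=list(_GENDER_PMF)[genders[i]],
                    working_status=list(_WORK_PMF)[works[i]],
                )
            )
    return records


# --- frames and files -------------------------------------------------------

def records_to_frame(records: Sequence[AcceptabilityRecord]) -> pd.DataFrame:
    """Flatten records to the acceptability CSV layout."""
    rows = []
    for r in records:
        row = {
            "respondent_id": r.respondent_id,
            "condition": r.condition,
            **{f"q{i+1}_{name}": r.items[i] for i, name in enumerate(SURVEY_ITEMS)},
            "total": r.total,
            "attention_failed": int(r.attention_failed),
            "feedback_seconds": r.feedback_seconds,
            "age": r.age,
            "gender": r.gender,
            "working_status": r.working_status,
        }
        for k in _APPRAISAL_PMF:
            row[k] = r.appraisal.get(k)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[AcceptabilityRecord]:
    """Inverse of :func:`records_to_frame` (appraisal/demographics optional)."""
    records = []
    item_cols = [f"q{i+1}_{name}" for i, name in enumerate(SURVEY_ITEMS)]
    for _, row in frame.iterrows():
        secs = row.get("feedback_seconds")
        secs = None if secs is None or (isinstance(secs, float) and np.isnan(secs)) else float(secs)
        appraisal = {
            k: int(row[k])
            for k in _APPRAISAL_PMF
            if k in frame.columns and pd.notna(row[k])
        }
        records.append(
            AcceptabilityRecord(
                respondent_id=str(row["respondent_id"]),
                condition=str(row["condition"]),
                items=tuple(int(row[c]) for c in item_cols),
                attention_failed=bool(int(row["attention_failed"])),
                feedback_seconds=secs,
                appraisal=appraisal,
                age=int(row["age"]) if "age" in frame.columns and pd.notna(row.get("age")) else None,
                gender=row.get("gender") if pd.notna(row.get("gender", np.nan)) else None,
                working_status=row.get("working_status")
                if pd.notna(row.get("working_status", np.nan))
                else None,
            )
        )
    return records
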