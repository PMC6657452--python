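"""Deterministic per-respondent feedback in three experimental flavours.

``none`` produces an empty bundle; ``graphical`` produces one 0-100 bar
per domain; ``graphical_text`` additionally renders a tailored message
per domain chosen by comparing the respondent's score with the reference
population mean: scores more than ``band_halfwidth`` points below the
norm fall in the *lower* band, more than ``band_halfwidth`` above in the
*higher* band, and everything else (boundaries included) in *average*.
Templates interpolate ``{score}`` and ``{domain}`` so every message
states the numeric score it describes.  Rendering is a pure function —
identical inputs give byte-identical output.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .cat import DomainScore

__all__ = [
    "Band",
    "FeedbackCondition",
    "FeedbackBundle",
    "assign_band",
    "render_feedback",
    "default_templates",
    "bundle_to_json",
    "save_bar_chart",
]


class Band(str, enum.Enum):
    LOWER = "lower"
    AVERAGE = "average"
    HIGHER = "higher"


class FeedbackCondition(str, enum.Enum):
    NONE = "none"
    GRAPHICAL = "graphical"
    GRAPHICAL_TEXT = "graphical_text"


@dataclass(frozen=True)
class FeedbackBundle:
    condition: FeedbackCondition
    bars: tuple[tuple[str, float], ...]  # (domain_id, score_0_100)
    texts: tuple[tuple[str, Band, str], ...]  # (domain_id, band, message)

    def __post_init__(self) -> None:
        if self.condition is FeedbackCondition.NONE and (self.bars or self.texts):
            raise ValueError("condition 'none' must carry no bars or texts")
        if self.condition is FeedbackCondition.GRAPHICAL and self.texts:
            raise ValueError("condition 'graphical' must carry no texts")
        if self.condition is FeedbackCondition.GRAPHICAL_TEXT:
            if not all(msg for _, _, msg in self.texts):
                raise ValueError("graphical_text messages must be non-empty")


def assign_band(score: float, norm_score: float, band_halfwidth: float = 5.0) -> Band:
    """Band a 0-100 score relative to the population mean on that scale."""
    if not 0.0 <= score <= 100.0:
        raise ValueError("score must lie in [0, 100]")
    if score < norm_score - band_halfwidth:
        return Band.LOWER
    if score > norm_score + band_halfwidth:
        return Band.HIGHER
    return Band.AVERAGE


def render_feedback(
    scores: Sequence[DomainScore],
    condition: FeedbackCondition | str,
    templates: Mapping[tuple[str, Band], str] | None = None,
    norms: Mapping[str, float] | None = None,
    band_halfwidth: float = 5.0,
) -> FeedbackBundle:
    """Build the feedback bundle for one respondent's domain scores.

    ``norms`` maps domain_id to the population mean on the 0-100 scale;
    ``templates`` maps (domain_id, band) to a message template.  Both are
    required only for the ``graphical_text`` condition.
    """
    condition = FeedbackCondition(condition)
    if condition is FeedbackCondition.NONE:
        return FeedbackBundle(condition, (), ())

    bars = tuple((s.domain_id, round(s.score_0_100, 1)) for s in scores)
    if condition is FeedbackCondition.GRAPHICAL:
        return FeedbackBundle(condition, bars, ())

    if norms is None:
        raise ValueError("graphical_text feedback requires domain norms")
    if templates is None:
        templates = default_templates(tuple(s.domain_id for s in scores))
    texts = []
    for s in scores:
        if s.domain_id not in norms:
            raise KeyError(f"no 0-100 norm configured for domain {s.domain_id!r}")
        band = assign_band(s.score_0_100, norms[s.domain_id], band_halfwidth)
        key = (s.domain_id, band)
        if key not in templates:
            raise KeyError(f"missing feedback template for (domain={key[0]!r}, band={key[1].value!r})")
        msg = templates[key].format(score=round(s.score_0_100), domain=s.domain_id)
        texts.append((s.domain_id, band, msg))
    return FeedbackBundle(condition, bars, tuple(texts))


_BAND_WORDING = {
    Band.LOWER: (
        "Your score of {score} on this scale indicates that your {domain} "
        "quality of life is lower than average. This suggests that your "
        "satisfaction with this area of your life is lower than it could be. "
        "You could discuss these things with your doctor."
    ),
    Band.AVERAGE: (
        "Your score of {score} on this scale indicates that your {domain} "
        "quality of life is about average. Most people score in this range."
    ),
    Band.HIGHER: (
        "Your score of {score} on this scale indicates that your {domain} "
        "quality of life is higher than average. You appear satisfied with "
        "this area of your life."
    ),
}


def default_templates(domains: Sequence[str]) -> dict[tuple[str, Band], str]:
    """Representative band-keyed templates covering every given domain."""
    return {(d, band): tpl for d in domains for band, tpl in _BAND_WORDING.items()}


def bundle_to_json(bundle: FeedbackBundle) -> str:
    return json.dumps(
        {
            "condition": bundle.condition.value,
            "bars": [{"domain_id": d, "score_0_100": s} for d, s in bundle.bars],
            "texts": [
                {"domain_id": d, "band": b.value, "message": m}
                for d, b, m in bundle.texts
            ],
        },
        sort_keys=True,
    )


def save_bar_chart(bundle: FeedbackBundle, path: str) -> None:
    """Write a horizontal bar chart (one bar per domain, 0-100 axis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    domains = [d for d, _ in bundle.bars]
    scores = [s for _, s in bundle.bars]
    fig, ax = plt.subplots(figsize=(6, 0.6 * max(len(domains), 1) + 1))
    ax.barh(domains, scores, color="#4c72b0")
    ax.set_xlim(0, 100)
    ax.set_xlabel("score (0 = worst, 100 = best)")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
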