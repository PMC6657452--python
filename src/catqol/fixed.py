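"""Fixed-length questionnaire scoring (WHOQOL-BREF style).

Items are ordinal with categories ``1..n_categories``; negatively worded
items are recoded ``x -> n_categories + 1 - x`` before aggregation.  A
domain score is the mean of its non-missing items, linearly rescaled to
0 (worst) .. 100 (best).  If more than ``missing_tolerance`` of a
domain's items are missing the domain score is missing — never imputed.
The 4-20 intermediate used by the published scoring syntax is exposed as
an extra column; it is the same linear map composed differently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FixedFormItem", "FixedForm", "score_fixed_form"]


@dataclass(frozen=True)
class FixedFormItem:
    item_id: str
    domain_id: str
    n_categories: int = 5
    reversed: bool = False

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError(f"item {self.item_id!r}: n_categories must be >= 2")


@dataclass(frozen=True)
class FixedForm:
    """Definition of a fixed-length multi-domain form."""

    items: tuple[FixedFormItem, ...]
    missing_tolerance: float = 0.2

    def __post_init__(self) -> None:
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        if not 0.0 <= self.missing_tolerance < 1.0:
            raise ValueError("missing_tolerance must lie in [0, 1)")
        for dom in self.domains:
            if len(self.for_domain(dom)) < 3:
                raise ValueError(f"domain {dom!r} must have at least 3 items")

    @property
    def domains(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for it in self.items:
            seen.setdefault(it.domain_id, None)
        return tuple(seen)

    def for_domain(self, domain_id: str) -> tuple[FixedFormItem, ...]:
        return tuple(it for it in self.items if it.domain_id == domain_id)


def score_fixed_form(form: FixedForm, responses: pd.DataFrame) -> pd.DataFrame:
    """Score every respondent of ``responses`` on every domain of ``form``.

    Parameters
    ----------
    form
        The form definition (items, categories, reversed flags).
    responses
        Respondent x item frame; the index identifies respondents, one
        column per ``item_id``, values in ``1..n_categories`` or NaN for
        missing.

    Returns
    -------
    Tidy frame with columns ``respondent_id, domain_id, raw_mean,
    score_4_20, score_0_100``; score columns are NaN when the domain's
    missing fraction exceeds the form's tolerance.
    """
    recoded: dict[str, np.ndarray] = {}
    for it in form.items:
        if it.item_id not in responses.columns:
            raise KeyError(f"responses are missing column for item {it.item_id!r}")
        col = responses[it.item_id].to_numpy(dtype=float)
        bad = ~np.isnan(col) & ((col < 1) | (col > it.n_categories) | (col % 1 != 0))
        if bad.any():
            rid = responses.index[np.argmax(bad)]
            raise ValueError(
                f"out-of-range response for respondent {rid!r}, item {it.item_id!r}: "
                f"{col[np.argmax(bad)]!r}"
            )
        recoded[it.item_id] = (it.n_categories + 1 - col) if it.reversed else col

    rows = []
    for dom in form.domains:
        dom_items = form.for_domain(dom)
        ncat = {it.n_categories for it in dom_items}
        if len(ncat) != 1:
            raise ValueError(f"domain {dom!r} mixes items with different category counts")
        k = ncat.pop()
        mat = np.column_stack([recoded[it.item_id] for it in dom_items])
        n_items = mat.shape[1]
        n_missing = np.isnan(mat).sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(mat, axis=1)
        ok = n_missing / n_items <= form.missing_tolerance
        mean = np.where(ok, mean, np.nan)
        score = (mean - 1.0) / (k - 1.0) * 100.0
        for rid, m, s in zip(responses.index, mean, score):
            rows.append(
                {
                    "respondent_id": rid,
                    "domain_id": dom,
                    "raw_mean": m,
                    "score_4_20": m * 4.0,
                    "score_0_100": s,
                }
            )
    return pd.DataFrame(rows)
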