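"""File formats: item banks (CSV/JSON), response matrices, acceptability CSV.

Bank CSV layout: ``item_id, domain_id, b1..bK`` with empty trailing
cells for items with fewer steps.  The JSON equivalent stores explicit
threshold arrays.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .irt import ItemBank, PcmItem

__all__ = [
    "read_bank_csv",
    "write_bank_csv",
    "read_bank_json",
    "write_bank_json",
    "read_responses_csv",
    "write_responses_csv",
]


def write_bank_csv(bank: ItemBank, path: str | Path) -> None:
    kmax = max(len(it.thresholds) for it in bank)
    rows = []
    for it in bank:
        row = {"item_id": it.item_id, "domain_id": it.domain_id}
        for j in range(kmax):
            row[f"b{j+1}"] = it.thresholds[j] if j < len(it.thresholds) else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_bank_csv(path: str | Path) -> ItemBank:
    df = pd.read_csv(path)
    bcols = sorted(
        (c for c in df.columns if c.startswith("b") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    items = []
    for _, row in df.iterrows():
        thr = [float(row[c]) for c in bcols if pd.notna(row[c])]
        items.append(
            PcmItem(item_id=str(row["item_id"]), domain_id=str(row["domain_id"]), thresholds=tuple(thr))
        )
    return ItemBank(items=tuple(items))


def write_bank_json(bank: ItemBank, path: str | Path) -> None:
    payload = [
        {"item_id": it.item_id, "domain_id": it.domain_id, "thresholds": list(it.thresholds)}
        for it in bank
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_bank_json(path: str | Path) -> ItemBank:
    payload = json.loads(Path(path).read_text())
    return ItemBank(
        items=tuple(
            PcmItem(
                item_id=str(d["item_id"]),
                domain_id=str(d["domain_id"]),
                thresholds=tuple(float(b) for b in d["thresholds"]),
            )
            for d in payload
        )
    )


def write_responses_csv(responses: pd.DataFrame, path: str | Path) -> None:
    responses.to_csv(path, index_label="respondent_id")


def read_responses_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="respondent_id")
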