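"""Readers and writers for item banks (JSON) and response matrices (CSV).

Bank files carry the reporting-metric metadata alongside the item parameters
so that a bank is self-describing; round-trips are lossless to 1e-12.
Response CSVs have the person id in the first column and one column per
item; empty cells or ``NA`` mark missing responses.  Files coded 1..K can be
read with ``one_based=True``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grm import MISSING, ItemBank, ItemParameters, Metric, ResponseMatrix

__all__ = [
    "read_bank_json",
    "write_bank_json",
    "read_responses_csv",
    "write_responses_csv",
]


def write_bank_json(bank: ItemBank, path: str | Path) -> None:
    doc = {
        "label": bank.label,
        "metric": {
            "reference_mean": bank.metric.reference_mean,
            "reference_sd": bank.metric.reference_sd,
        },
        "items": [
            {
                "item_id": it.item_id,
                "slope": it.slope,
                "thresholds": list(it.thresholds),
                "n_categories": it.n_categories,
            }
            for it in bank.items
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_bank_json(path: str | Path) -> ItemBank:
    doc = json.loads(Path(path).read_text())
    metric = Metric(**doc.get("metric", {}))
    items = [
        ItemParameters(
            item_id=d["item_id"],
            slope=d["slope"],
            thresholds=tuple(d["thresholds"]),
            n_categories=d.get("n_categories", 0),
        )
        for d in doc["items"]
    ]
    return ItemBank(items, metric=metric, label=doc.get("label", ""))


def write_responses_csv(matrix: ResponseMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        matrix.codes.astype(float), columns=matrix.item_ids,
    )
    df[df == MISSING] = np.nan
    df = df.astype("Int64")
    df.insert(0, "person_id", matrix.persons)
    df.to_csv(path, index=False)


def read_responses_csv(
    path: str | Path, one_based: bool = False
) -> ResponseMatrix:
    df = pd.read_csv(path, na_values=["NA", ""], dtype={0: str})
    persons = df.iloc[:, 0].astype(str).tolist()
    item_ids = list(df.columns[1:])
    codes = df.iloc[:, 1:].to_numpy(dtype=float)
    if one_based:
        codes = codes - 1
    if np.nanmin(codes, initial=0) < 0:
        raise ValueError("negative response codes (is the file 1-based?)")
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int16)
    return ResponseMatrix(persons, item_ids, codes)
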