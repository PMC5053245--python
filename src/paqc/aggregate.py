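"""Aggregation of patient-level scores to clinician/ward/hospital level.

Patient-level scores only become management information once averaged at
the reporting level of interest; this module produces per-group summary
rows (n, mean, median, IQR, per-item scored-1 proportions) in the
"median (IQR)" style quality reports use.

Quantiles use the inclusive linear-interpolation convention
(``numpy`` ``method="linear"``), fixed so summaries are bit-reproducible
across runs.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import CaseRecord
from .paqc_score import ITEM_NAMES, PAQCScore

GROUP_KEYS = ("hospital_id", "clinician_id", "arm", "survey")


def scores_to_frame(
    scores: Sequence[PAQCScore], records: Optional[Sequence[CaseRecord]] = None
) -> pd.DataFrame:
    """One row per scored record: grouping keys, the six combined items,
    domain scores and Q, plus per-disease item sums in wide form."""
    by_id = {r.record_id: r for r in records} if records else {}
    rows = []
    for s in scores:
        row: dict[str, object] = {"record_id": s.record_id,
                                  "diseases": "+".join(s.diseases)}
        rec = by_id.get(s.record_id)
        if rec is not None:
            row.update(hospital_id=rec.hospital_id, clinician_id=rec.clinician_id,
                       arm=rec.arm.value, survey=rec.survey)
        for item in ITEM_NAMES:
            row[item] = getattr(s.combined, item)
        row.update(D1=s.d1, D2=s.d2, D3=s.d3, Q=s.q)
        for disease, items in s.per_disease.items():
            row[f"S_{disease}"] = items.total
        rows.append(row)
    return pd.DataFrame(rows)


def summarise(
    scores: pd.DataFrame,
    by: Sequence[str] = (),
    not_scoreable: Optional[dict[tuple, int]] = None,
) -> pd.DataFrame:
    """Per-group score summaries.

    ``scores`` is the frame from :func:`scores_to_frame`; ``by`` lists
    grouping keys present in it (empty = one overall row). Groups with
    n = 0 keep their row with missing statistics.
    """
    by = list(by)
    for key in by:
        if key not in scores.columns:
            raise KeyError(f"grouping key {key!r} not in scores")

    def one(group: pd.DataFrame, keys: tuple) -> dict:
        q = group["Q"].to_numpy(dtype=float)
        row: dict[str, object] = dict(zip(by, keys))
        row["n"] = len(q)
        if len(q):
            row["mean"] = float(np.mean(q))
            row["median"] = float(np.quantile(q, 0.5, method="linear"))
            row["q25"] = float(np.quantile(q, 0.25, method="linear"))
            row["q75"] = float(np.quantile(q, 0.75, method="linear"))
            for item in ITEM_NAMES:
                row[f"p_{item}"] = float(group[item].mean())
        else:
            for col in ("mean", "median", "q25", "q75", *(f"p_{i}" for i in ITEM_NAMES)):
                row[col] = np.nan
        if not_scoreable is not None:
            row["not_scoreable"] = not_scoreable.get(keys, 0)
        return row

    if not by:
        return pd.DataFrame([one(scores, ())])
    grouped = scores.groupby(by, dropna=False, sort=True)
    rows = [one(g, k if isinstance(k, tuple) else (k,)) for k, g in grouped]
    return pd.DataFrame(rows)


def item_proportion_table(scores: pd.DataFrame, by: Sequence[str]) -> pd.DataFrame:
    """Items-by-groups table of scored-1 percentages (report layout)."""
    summary = summarise(scores, by)
    cols = [f"p_{i}" for i in ITEM_NAMES]
    labels = summary[list(by)].astype(str).agg("/".join, axis=1)
    out = summary[cols].T * 100.0
    out.columns = list(labels)
    out.index = list(ITEM_NAMES)
    return out
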