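"""Reading and writing case-record abstraction data.

Two plain CSV files describe a cohort:

* a records file — one row per admission episode with identifiers, age,
  weight, one column per canonical sign (``P`` documented present, ``A``
  documented absent, ``V`` or ``V:<number>`` documented with a value,
  ``N``/empty not documented) and the recorded classification wording per
  disease (``dx_malaria``, ``dx_pneumonia``, ``dx_diarrhoea``: an empty
  cell means not diagnosed, the marker ``dx`` means diagnosed with no
  classification wording, anything else is the wording as abstracted);
* a long-format prescriptions file keyed by ``record_id``.

Sign column headers may use documented synonyms (e.g.
``level_of_consciousness``); they are canonicalised at load time, and
unknown columns are rejected with the offending name.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import ValidationError

from .codebook import GuidelineCodebook
from .errors import RecordError
from .model import (
    Arm,
    CaseRecord,
    DocStatus,
    Documentation,
    Prescription,
    Role,
    Route,
)

_META_COLS = ("record_id", "hospital_id", "clinician_id", "arm", "survey",
              "age_months", "weight_kg")
_DX_COLS = {"dx_malaria": "malaria", "dx_pneumonia": "pneumonia",
            "dx_diarrhoea": "diarrhoea_dehydration"}
#: marker for "diagnosed, but no classification recorded"
DX_NO_CLASSIFICATION = "dx"

_RX_COLS = ("record_id", "drug", "role", "dose_amount", "dose_units", "route",
            "frequency_per_day", "duration", "infusion_time_hours")


def _parse_sign_cell(cell: str, row: int, col: str) -> Documentation:
    cell = cell.strip()
    if cell in ("", "N"):
        return Documentation(status=DocStatus.not_documented)
    if cell == "P":
        return Documentation(status=DocStatus.documented_present)
    if cell == "A":
        return Documentation(status=DocStatus.documented_absent)
    if cell == "V" or cell.startswith("V:"):
        qty = None
        if cell.startswith("V:"):
            try:
                qty = float(cell[2:])
            except ValueError:
                raise RecordError(f"row {row}, column {col!r}: bad value cell {cell!r}")
        if qty is None:
            raise RecordError(f"row {row}, column {col!r}: V cells need a quantity (V:<number>)")
        return Documentation(status=DocStatus.documented_value, quantity=qty)
    raise RecordError(f"row {row}, column {col!r}: unknown sign code {cell!r}")


def read_prescriptions(path: str | Path) -> dict[str, list[Prescription]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_RX_COLS) - set(df.columns)
    if missing:
        raise RecordError(f"prescriptions file lacks columns {sorted(missing)}")
    out: dict[str, list[Prescription]] = {}
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based with header
        try:
            rx = Prescription(
                drug=row["drug"].strip(),
                role=Role(row["role"].strip()) if row["role"].strip() else Role.single,
                dose_amount=float(row["dose_amount"]) if row["dose_amount"].strip() else None,
                dose_units=row["dose_units"].strip() or None,
                route=Route(row["route"].strip()) if row["route"].strip() else Route.missing,
                frequency_per_day=(float(row["frequency_per_day"])
                                   if row["frequency_per_day"].strip() else None),
                duration=row["duration"].strip() or None,
                infusion_time_hours=(float(row["infusion_time_hours"])
                                     if row["infusion_time_hours"].strip() else None),
            )
        except (ValueError, ValidationError) as exc:
            raise RecordError(f"prescriptions row {rownum}: {exc}") from exc
        out.setdefault(row["record_id"], []).append(rx)
    return out


def read_records(
    path: str | Path,
    codebook: GuidelineCodebook,
    prescriptions_path: Optional[str | Path] = None,
) -> list[CaseRecord]:
    """Load case records (and optionally their prescriptions) from CSV.

    Raises :class:`RecordError` naming the row and column on any
    malformed cell, unknown sign column or invariant violation.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_META_COLS) - set(df.columns)
    if missing:
        raise RecordError(f"records file lacks columns {sorted(missing)}")
    sign_cols: dict[str, str] = {}
    for col in df.columns:
        if col in _META_COLS or col in _DX_COLS:
            continue
        canonical = codebook.canonical_sign(col)
        if canonical is None:
            raise RecordError(f"unknown sign column {col!r}")
        if canonical in sign_cols.values():
            raise RecordError(f"column {col!r} duplicates sign {canonical!r}")
        sign_cols[col] = canonical

    rx_by_record = read_prescriptions(prescriptions_path) if prescriptions_path else {}

    records: list[CaseRecord] = []
    for i, row in df.iterrows():
        rownum = i + 2
        signs = {}
        for col, canonical in sign_cols.items():
            doc = _parse_sign_cell(row[col], rownum, col)
            if doc.documented:
                signs[canonical] = doc
        diagnoses = {}
        for col, disease in _DX_COLS.items():
            if col not in df.columns:
                continue
            cell = row[col].strip()
            if cell:
                diagnoses[disease] = "" if cell == DX_NO_CLASSIFICATION else cell
        try:
            records.append(CaseRecord(
                record_id=row["record_id"],
                hospital_id=row["hospital_id"],
                clinician_id=row["clinician_id"].strip() or None,
                arm=Arm(row["arm"].strip()) if row["arm"].strip() else Arm.unknown,
                survey=row["survey"].strip() or "baseline",
                age_months=float(row["age_months"]),
                weight_kg=float(row["weight_kg"]) if row["weight_kg"].strip() else None,
                signs=signs,
                diagnoses=diagnoses,
                prescriptions=tuple(rx_by_record.get(row["record_id"], ())),
            ))
        except (ValueError, ValidationError) as exc:
            raise RecordError(f"row {rownum}: {exc}") from exc
    return records


def _sign_cell(doc: Documentation) -> str:
    if doc.status == DocStatus.documented_present:
        return "P"
    if doc.status == DocStatus.documented_absent:
        return "A"
    if doc.status == DocStatus.documented_value:
        return f"V:{doc.quantity:g}"
    return "N"


def write_records(
    records: list[CaseRecord],
    path: str | Path,
    codebook: GuidelineCodebook,
    prescriptions_path: Optional[str | Path] = None,
) -> None:
    """Write records (and optionally prescriptions) in the CSV schema
    accepted by :func:`read_records`."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "record_id": rec.record_id,
            "hospital_id": rec.hospital_id,
            "clinician_id": rec.clinician_id or "",
            "arm": rec.arm.value if rec.arm != Arm.unknown else "",
            "survey": rec.survey,
            "age_months": rec.age_months,
            "weight_kg": "" if rec.weight_kg is None else rec.weight_kg,
        }
        for sign in codebook.signs:
            doc = rec.signs.get(sign)
            row[sign] = _sign_cell(doc) if doc is not None else "N"
        for col, disease in _DX_COLS.items():
            if disease in rec.diagnoses:
                row[col] = rec.diagnoses[disease] or DX_NO_CLASSIFICATION
            else:
                row[col] = ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)

    if prescriptions_path is not None:
        rx_rows = []
        for rec in records:
            for p in rec.prescriptions:
                rx_rows.append({
                    "record_id": rec.record_id,
                    "drug": p.drug,
                    "role": p.role.value,
                    "dose_amount": "" if p.dose_amount is None else p.dose_amount,
                    "dose_units": p.dose_units or "",
                    "route": "" if p.route == Route.missing else p.route.value,
                    "frequency_per_day": "" if p.frequency_per_day is None else p.frequency_per_day,
                    "duration": p.duration or "",
                    "infusion_time_hours": "" if p.infusion_time_hours is None else p.infusion_time_hours,
                })
        pd.DataFrame(rx_rows, columns=list(_RX_COLS)).to_csv(prescriptions_path, index=False)
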