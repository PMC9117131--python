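"""Cohort file I/O: one wide CSV row per participant.

Layout conventions
------------------
* RFC-4180 CSV, UTF-8, mandatory header, fixed column order.
* Missingness is an empty cell, never a sentinel number: the analysis treats
  "missing" as a distinct state (missing outcomes count as non-abstinent),
  so a missing cotinine must never read back as 0.
* Twins are encoded as repeated infant column groups (``infant1_*``,
  ``infant2_*``); the reader re-assembles them into one delivery record.
* ``write_cohort`` followed by ``read_cohort`` is the identity on every field.
"""

from __future__ import annotations

import csv
import io
import os
from typing import Dict, List, Optional, Sequence

from .records import (Arm, AssayPanel, DeliveryRecord, Education, EopReport,
                      InfantOutcome, ParticipantBaseline, ParticipantRecord,
                      ProductUsePattern, WeeklyStatus)

SCHEMA_VERSION = "1"

_INFANT_FIELDS = [
    "birthweight_g", "gestational_age_weeks", "miscarriage", "stillbirth",
    "neonatal_death", "post_neonatal_death", "preterm", "low_birthweight",
    "nicu_admission", "congenital_abnormality", "cesarean",
]

_PRODUCT_FIELDS = [
    "allocated_5plus_days_first4wks", "allocated_current_4wks",
    "allocated_current_eop", "allocated_regular_study",
    "nonallocated_5plus_consecutive_days_first4wks", "nonallocated_current_eop",
    "nonallocated_regular_1wk", "nonallocated_occasional_3wks",
]

COLUMNS: List[str] = (
    ["id", "arm",
     "age_years", "gestation_weeks_at_entry", "cigarettes_per_day",
     "ftcd_score", "baseline_cotinine_ng_ml", "lives_with_smoker",
     "education", "employed",
     "tqd_set", "contacted_ever", "started_allocated_product",
     "week1_status", "week2_status", "week3_status", "week4_status",
     "lapse_count", "eop_self_report", "eop_cigarettes_per_day"]
    + _PRODUCT_FIELDS
    + ["saliva_returned", "cotinine_ng_ml", "anabasine_ng_ml", "co_ppm",
       "nicotine_product_user_at_validation", "withdrew_before_delivery",
       "n_infants"]
    + [f"infant1_{f}" for f in _INFANT_FIELDS]
    + [f"infant2_{f}" for f in _INFANT_FIELDS]
)


def _fmt_bool(v: bool) -> str:
    return "true" if v else "false"


def _fmt_opt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return _fmt_bool(v)
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _parse_bool(s: str, col: str, row: int) -> bool:
    if s == "true":
        return True
    if s == "false":
        return False
    raise ValueError(f"row {row}: invalid boolean {s!r} in column {col!r}")


def _parse_opt_float(s: str) -> Optional[float]:
    return None if s == "" else float(s)


def _parse_opt_int(s: str) -> Optional[int]:
    return None if s == "" else int(s)


def record_to_row(rec: ParticipantRecord) -> Dict[str, str]:
    b, pu, a = rec.baseline, rec.product_use, rec.assays
    row: Dict[str, str] = {
        "id": rec.id,
        "arm": rec.arm.value,
        "age_years": repr(b.age_years),
        "gestation_weeks_at_entry": repr(b.gestation_weeks_at_entry),
        "cigarettes_per_day": str(b.cigarettes_per_day),
        "ftcd_score": str(b.ftcd_score),
        "baseline_cotinine_ng_ml": _fmt_opt(b.cotinine_ng_ml),
        "lives_with_smoker": _fmt_bool(b.lives_with_smoker),
        "education": b.education.value,
        "employed": _fmt_bool(b.employed),
        "tqd_set": _fmt_bool(rec.tqd_set),
        "contacted_ever": _fmt_bool(rec.contacted_ever),
        "started_allocated_product": _fmt_bool(rec.started_allocated_product),
        "lapse_count": str(rec.lapse_count),
        "eop_self_report": ("" if rec.eop_self_report is EopReport.MISSING
                            else rec.eop_self_report.value),
        "eop_cigarettes_per_day": _fmt_opt(rec.eop_cigarettes_per_day),
        "saliva_returned": _fmt_bool(a.saliva_returned),
        "cotinine_ng_ml": _fmt_opt(a.cotinine_ng_ml),
        "anabasine_ng_ml": _fmt_opt(a.anabasine_ng_ml),
        "co_ppm": _fmt_opt(a.co_ppm),
        "nicotine_product_user_at_validation":
            _fmt_bool(a.nicotine_product_user_at_validation),
        "withdrew_before_delivery": _fmt_bool(rec.withdrew_before_delivery),
        "n_infants": "" if rec.delivery is None else str(rec.delivery.n_infants),
    }
    for i, status in enumerate(rec.weekly_self_report, start=1):
        row[f"week{i}_status"] = ("" if status is WeeklyStatus.MISSING
                                  else status.value)
    for f in _PRODUCT_FIELDS:
        row[f] = _fmt_bool(getattr(pu, f))
    for j in (1, 2):
        infant = (rec.delivery.infants[j - 1]
                  if rec.delivery is not None and rec.delivery.n_infants >= j
                  else None)
        for f in _INFANT_FIELDS:
            row[f"infant{j}_{f}"] = "" if infant is None else _fmt_opt(getattr(infant, f))
    return row


def row_to_record(row: Dict[str, str], rownum: int) -> ParticipantRecord:
    try:
        arm = Arm(row["arm"])
    except ValueError:
        raise ValueError(f"row {rownum}: unknown arm label {row['arm']!r}") from None
    try:
        education = Education(row["education"])
    except ValueError:
        raise ValueError(
            f"row {rownum}: unknown education level {row['education']!r}") from None

    baseline = ParticipantBaseline(
        age_years=float(row["age_years"]),
        gestation_weeks_at_entry=float(row["gestation_weeks_at_entry"]),
        cigarettes_per_day=int(row["cigarettes_per_day"]),
        ftcd_score=int(row["ftcd_score"]),
        cotinine_ng_ml=_parse_opt_float(row["baseline_cotinine_ng_ml"]),
        lives_with_smoker=_parse_bool(row["lives_with_smoker"],
                                      "lives_with_smoker", rownum),
        education=education,
        employed=_parse_bool(row["employed"], "employed", rownum),
    )
    weekly = tuple(
        WeeklyStatus(row[f"week{i}_status"]) if row[f"week{i}_status"] != ""
        else WeeklyStatus.MISSING
        for i in (1, 2, 3, 4)
    )
    product_use = ProductUsePattern(
        **{f: _parse_bool(row[f], f, rownum) for f in _PRODUCT_FIELDS})
    assays = AssayPanel(
        saliva_returned=_parse_bool(row["saliva_returned"], "saliva_returned", rownum),
        cotinine_ng_ml=_parse_opt_float(row["cotinine_ng_ml"]),
        anabasine_ng_ml=_parse_opt_float(row["anabasine_ng_ml"]),
        co_ppm=_parse_opt_float(row["co_ppm"]),
        nicotine_product_user_at_validation=_parse_bool(
            row["nicotine_product_user_at_validation"],
            "nicotine_product_user_at_validation", rownum),
    )
    delivery = None
    if row["n_infants"] != "":
        infants = []
        for j in range(1, int(row["n_infants"]) + 1):
            infants.append(InfantOutcome(
                birthweight_g=_parse_opt_float(row[f"infant{j}_birthweight_g"]),
                gestational_age_weeks=_parse_opt_float(
                    row[f"infant{j}_gestational_age_weeks"]),
                **{f: _parse_bool(row[f"infant{j}_{f}"], f"infant{j}_{f}", rownum)
                   for f in _INFANT_FIELDS[2:]},
            ))
        delivery = DeliveryRecord(infants=tuple(infants))

    rec = ParticipantRecord(
        id=row["id"],
        arm=arm,
        baseline=baseline,
        tqd_set=_parse_bool(row["tqd_set"], "tqd_set", rownum),
        contacted_ever=_parse_bool(row["contacted_ever"], "contacted_ever", rownum),
        started_allocated_product=_parse_bool(
            row["started_allocated_product"], "started_allocated_product", rownum),
        weekly_self_report=weekly,  # type: ignore[arg-type]
        lapse_count=int(row["lapse_count"]),
        eop_self_report=(EopReport(row["eop_self_report"])
                         if row["eop_self_report"] != "" else EopReport.MISSING),
        eop_cigarettes_per_day=_parse_opt_int(row["eop_cigarettes_per_day"]),
        product_use=product_use,
        assays=assays,
        withdrew_before_delivery=_parse_bool(
            row["withdrew_before_delivery"], "withdrew_before_delivery", rownum),
        delivery=delivery,
    )
    try:
        rec.validate()
    except ValueError as e:
        raise ValueError(f"row {rownum}: {e}") from None
    return rec


def write_cohort(records: Sequence[ParticipantRecord], path) -> None:
    """Write records as a wide CSV; an empty collection yields a header-only file."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        _write(records, fh)


def write_cohort_string(records: Sequence[ParticipantRecord]) -> str:
    buf = io.StringIO()
    _write(records, buf)
    return buf.getvalue()


def _write(records: Sequence[ParticipantRecord], fh) -> None:
    writer = csv.DictWriter(fh, fieldnames=COLUMNS)
    writer.writeheader()
    for rec in records:
        writer.writerow(record_to_row(rec))


def read_cohort(path, schema_version: str = SCHEMA_VERSION) -> List[ParticipantRecord]:
    """Read a cohort CSV, validating the header and every row.

    Raises ``ValueError`` naming the offending row for unknown arm labels,
    duplicated ids, or out-of-range fields.
    """
    if schema_version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {schema_version!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != COLUMNS:
            raise ValueError("cohort file header does not match the published schema")
        records: List[ParticipantRecord] = []
        seen = set()
        for rownum, row in enumerate(reader, start=2):  # header is line 1
            rec = row_to_record(row, rownum)
            if rec.id in seen:
                raise ValueError(f"row {rownum}: duplicated id {rec.id!r}")
            seen.add(rec.id)
            records.append(rec)
    return records
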