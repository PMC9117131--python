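"""Trial outcome definitions.

Implements Russell-Standard prolonged abstinence, point-prevalence abstinence,
the biochemical validation hierarchy (salivary cotinine for nicotine-product
non-users; salivary anabasine or expired carbon monoxide — CO prevailing on
discrepancy — for product users), the >=50% smoking-reduction endpoint, and
the analysis-set eligibility flags used by the estimand builders.

Classification is a pure function of a single participant record: missing
data is a classification outcome (non-abstinent), never an error, and a
validated call can only confirm, never create, a self-reported one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import pandas as pd

from . import constants as C
from .records import EopReport, ParticipantRecord, ProductUsePattern, WeeklyStatus


@dataclass
class OutcomeCalls:
    """All outcome calls and analysis-set flags for one participant."""

    id: str
    arm: str
    self_prolonged_eop: bool
    self_pp_4wk: bool
    self_pp_eop: bool
    validated_prolonged_eop: bool
    validated_pp_eop: bool
    reduction50_self: Optional[bool]       # None: abstinent, not in denominator
    reduction50_validated: Optional[bool]
    in_per_protocol: bool
    nonallocated_use: bool
    abstinent_switcher: bool


def nonallocated_use_flag(pattern: ProductUsePattern) -> bool:
    """Regular non-allocated product use: any of the four adherence disjuncts."""
    return (pattern.nonallocated_5plus_consecutive_days_first4wks
            or pattern.nonallocated_current_eop
            or pattern.nonallocated_regular_1wk
            or pattern.nonallocated_occasional_3wks)


def _self_reported_abstinent_eop(record: ParticipantRecord) -> bool:
    # Participants reached only after delivery who were abstinent at delivery
    # count as self-reported abstinent; missing follow-up counts as smoking.
    return record.eop_self_report in (
        EopReport.ABSTINENT_7DAY,
        EopReport.ABSTINENT_AT_DELIVERY_RELAPSED_SINCE)


def classify_prolonged(record: ParticipantRecord) -> bool:
    """Russell-Standard prolonged abstinence from 2 weeks post-TQD to EOP.

    True iff the end-of-pregnancy self-report indicates abstinence, at most
    five lapses occurred over the window, and no week after the two-week
    grace period (weeks 3-4 of the weekly timeline) was reported as smoking.
    A missing end-of-pregnancy report classifies as non-abstinent.
    """
    if not _self_reported_abstinent_eop(record):
        return False
    if record.lapse_count > C.MAX_LAPSES_PROLONGED:
        return False
    for status in record.weekly_self_report[2:]:
        if status is WeeklyStatus.SMOKING:
            return False
    return True


def _assay_pass(record: ParticipantRecord) -> bool:
    """Biochemical hierarchy shared by abstinence and reduction validation.

    Nicotine-product non-users are judged on salivary cotinine alone; current
    users of e-cigarettes or patches on anabasine or CO, with the CO verdict
    prevailing whenever a CO reading exists.  No usable measurement means no
    validation.  Thresholds are strict, exactly as defined.
    """
    a = record.assays
    a.validate()
    if a.nicotine_product_user_at_validation:
        if a.co_ppm is not None:
            return a.co_ppm < C.CO_THRESHOLD_PPM
        if a.anabasine_ng_ml is not None:
            return a.anabasine_ng_ml < C.ANABASINE_THRESHOLD_NG_ML
        return False
    if a.cotinine_ng_ml is not None:
        return a.cotinine_ng_ml < C.COTININE_THRESHOLD_NG_ML
    return False


def validate_abstinence(record: ParticipantRecord) -> bool:
    """Biochemical validation of a self-reported abstinence claim.

    Returns False unless some self-reported abstinence call holds; a
    participant abstinent at delivery but relapsed by the time of contact is
    non-abstinent in every validated outcome.
    """
    if not _self_reported_abstinent_eop(record):
        return False
    if record.eop_self_report is EopReport.ABSTINENT_AT_DELIVERY_RELAPSED_SINCE:
        return False
    return _assay_pass(record)


def classify_reduction(record: ParticipantRecord
                       ) -> Tuple[Optional[bool], Optional[bool]]:
    """>=50% cigarette reduction among non-abstinent participants.

    Returns ``(None, None)`` for participants outside the denominator
    (self-reported point-prevalence abstinent at end of pregnancy).  The self
    call requires a reported consumption at most half of baseline; the
    validated call additionally requires an assay pass under the same
    hierarchy (dual users judged on anabasine / CO).
    """
    if _self_reported_abstinent_eop(record):
        return (None, None)
    if record.baseline.cigarettes_per_day < 1:
        return (False, False)
    if record.eop_cigarettes_per_day is None:
        return (False, False)
    reduced = (record.eop_cigarettes_per_day
               <= C.REDUCTION_FRACTION * record.baseline.cigarettes_per_day)
    return (reduced, reduced and _assay_pass(record))


def classify_record(record: ParticipantRecord) -> OutcomeCalls:
    self_prolonged = classify_prolonged(record)
    self_pp_eop = _self_reported_abstinent_eop(record)
    self_pp_4wk = record.weekly_self_report[3] is WeeklyStatus.ABSTINENT
    validated = validate_abstinence(record)
    red_self, red_val = classify_reduction(record)
    nonalloc = nonallocated_use_flag(record.product_use)
    any_self_abstinent = self_prolonged or self_pp_eop or self_pp_4wk
    return OutcomeCalls(
        id=record.id,
        arm=record.arm.value,
        self_prolonged_eop=self_prolonged,
        self_pp_4wk=self_pp_4wk,
        self_pp_eop=self_pp_eop,
        validated_prolonged_eop=self_prolonged and validated,
        validated_pp_eop=self_pp_eop and validated,
        reduction50_self=red_self,
        reduction50_validated=red_val,
        in_per_protocol=(record.started_allocated_product
                         and record.contacted_ever),
        nonallocated_use=nonalloc,
        abstinent_switcher=any_self_abstinent and nonalloc,
    )


OUTCOME_COLUMNS = ["validated_prolonged_eop", "self_prolonged_eop",
                   "self_pp_4wk", "self_pp_eop", "validated_pp_eop",
                   "reduction50_self", "reduction50_validated"]


def classify_cohort(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """One row of outcome calls per participant, in cohort order."""
    calls: List[OutcomeCalls] = [classify_record(r) for r in records]
    return pd.DataFrame([vars(c) for c in calls])
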