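"""Participant-level domain types for a two-arm cessation trial in pregnancy.

One :class:`ParticipantRecord` per randomized participant, carrying the
baseline covariates, the weekly self-report timeline, the product-use pattern,
the end-of-pregnancy assay panel and the delivery outcomes that the outcome
classifier and the estimand builders consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Tuple

from . import constants as C


class Arm(str, Enum):
    ECIG = "ECIG"   # refillable e-cigarette arm
    NRT = "NRT"     # nicotine-patch arm


class Education(str, Enum):
    PRIMARY_SECONDARY = "primary_secondary"
    FURTHER = "further"
    HIGHER = "higher"


class WeeklyStatus(str, Enum):
    SMOKING = "smoking"
    ABSTINENT = "abstinent"
    MISSING = "missing"


class EopReport(str, Enum):
    """Self-reported smoking status at the end-of-pregnancy follow-up."""

    ABSTINENT_7DAY = "abstinent_7day"
    SMOKING = "smoking"
    # Reached only after delivery, abstinent at delivery but smoking again:
    # counts as self-reported abstinent, never as validated abstinent.
    ABSTINENT_AT_DELIVERY_RELAPSED_SINCE = "abstinent_at_delivery_relapsed_since"
    MISSING = "missing"


@dataclass
class ParticipantBaseline:
    age_years: float
    gestation_weeks_at_entry: float
    cigarettes_per_day: int
    ftcd_score: int
    cotinine_ng_ml: Optional[float]   # baseline salivary cotinine; None = missing
    lives_with_smoker: bool
    education: Education
    employed: bool

    def validate(self) -> None:
        if self.age_years <= 0:
            raise ValueError("age_years must be positive")
        if not (C.GESTATION_WEEKS_MIN <= self.gestation_weeks_at_entry
                <= C.GESTATION_WEEKS_MAX):
            raise ValueError(
                f"gestation_weeks_at_entry {self.gestation_weeks_at_entry} outside "
                f"eligibility window [{C.GESTATION_WEEKS_MIN}, {C.GESTATION_WEEKS_MAX}]")
        if self.cigarettes_per_day < 1:
            raise ValueError("cigarettes_per_day must be >= 1 (daily smokers only)")
        if not (C.FTCD_MIN <= self.ftcd_score <= C.FTCD_MAX):
            raise ValueError(f"ftcd_score {self.ftcd_score} outside [0, 10]")
        if self.cotinine_ng_ml is not None and self.cotinine_ng_ml < 0:
            raise ValueError("baseline cotinine must be nonnegative")


@dataclass
class ProductUsePattern:
    """Allocated and non-allocated product use over the study.

    ``*_regular_study`` follows the adherence-table definition: used for 5+
    days during the first 4 weeks, or currently at end of pregnancy, or
    regularly for >= 1 week, or occasionally for >= 3 weeks.  Current use at
    end of pregnancy therefore implies regular use during the study.
    """

    allocated_5plus_days_first4wks: bool = False
    allocated_current_4wks: bool = False
    allocated_current_eop: bool = False
    allocated_regular_study: bool = False
    nonallocated_5plus_consecutive_days_first4wks: bool = False
    nonallocated_current_eop: bool = False
    nonallocated_regular_1wk: bool = False
    nonallocated_occasional_3wks: bool = False

    def __post_init__(self) -> None:
        # current use at EOP implies "regular use during study"
        if self.allocated_current_eop:
            self.allocated_regular_study = True


@dataclass
class AssayPanel:
    """End-of-pregnancy biochemical measurements.

    Saliva assays (cotinine, anabasine) exist only if a usable saliva sample
    was returned; the carbon monoxide reading is collected independently.
    """

    saliva_returned: bool = False
    cotinine_ng_ml: Optional[float] = None
    anabasine_ng_ml: Optional[float] = None
    co_ppm: Optional[float] = None
    nicotine_product_user_at_validation: bool = False

    def validate(self) -> None:
        if not self.saliva_returned and (
                self.cotinine_ng_ml is not None or self.anabasine_ng_ml is not None):
            raise ValueError("saliva assay values present without a returned sample")
        for name in ("cotinine_ng_ml", "anabasine_ng_ml", "co_ppm"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"negative assay value for {name}: {v}")


@dataclass
class InfantOutcome:
    birthweight_g: Optional[float] = None
    gestational_age_weeks: Optional[float] = None
    miscarriage: bool = False
    stillbirth: bool = False
    neonatal_death: bool = False
    post_neonatal_death: bool = False
    preterm: bool = False
    low_birthweight: bool = False
    nicu_admission: bool = False
    congenital_abnormality: bool = False
    cesarean: bool = False

    def validate(self) -> None:
        if self.birthweight_g is not None:
            if self.birthweight_g <= 0:
                raise ValueError("birthweight_g must be positive")
            if self.low_birthweight != (self.birthweight_g < C.LOW_BIRTHWEIGHT_THRESHOLD_G):
                raise ValueError("low_birthweight flag inconsistent with birthweight_g")
        if self.gestational_age_weeks is not None:
            if self.gestational_age_weeks <= 0:
                raise ValueError("gestational_age_weeks must be positive")
            if self.preterm != (self.gestational_age_weeks < C.PRETERM_THRESHOLD_WEEKS):
                raise ValueError("preterm flag inconsistent with gestational_age_weeks")

    @classmethod
    def from_measurements(cls, birthweight_g: Optional[float],
                          gestational_age_weeks: Optional[float],
                          **flags: bool) -> "InfantOutcome":
        """Build with derived preterm / low-birthweight flags where measured."""
        out = cls(birthweight_g=birthweight_g,
                  gestational_age_weeks=gestational_age_weeks, **flags)
        if birthweight_g is not None:
            out.low_birthweight = birthweight_g < C.LOW_BIRTHWEIGHT_THRESHOLD_G
        if gestational_age_weeks is not None:
            out.preterm = gestational_age_weeks < C.PRETERM_THRESHOLD_WEEKS
        return out


@dataclass
class DeliveryRecord:
    infants: Tuple[InfantOutcome, ...]

    @property
    def n_infants(self) -> int:
        return len(self.infants)

    def validate(self) -> None:
        if self.n_infants not in (1, 2):
            raise ValueError("n_infants must be 1 or 2")
        for infant in self.infants:
            infant.validate()


@dataclass
class ParticipantRecord:
    id: str
    arm: Arm
    baseline: ParticipantBaseline
    tqd_set: bool
    contacted_ever: bool
    started_allocated_product: bool
    weekly_self_report: Tuple[WeeklyStatus, WeeklyStatus, WeeklyStatus, WeeklyStatus]
    lapse_count: int
    eop_self_report: EopReport
    eop_cigarettes_per_day: Optional[int]
    product_use: ProductUsePattern = field(default_factory=ProductUsePattern)
    assays: AssayPanel = field(default_factory=AssayPanel)
    withdrew_before_delivery: bool = False
    delivery: Optional[DeliveryRecord] = None

    def validate(self) -> None:
        self.baseline.validate()
        self.assays.validate()
        if len(self.weekly_self_report) != 4:
            raise ValueError("weekly_self_report must have exactly 4 slots")
        if self.lapse_count < 0:
            raise ValueError("lapse_count must be >= 0")
        if (self.eop_cigarettes_per_day is not None
                and self.eop_self_report is not EopReport.SMOKING):
            raise ValueError(
                "eop_cigarettes_per_day present requires eop_self_report == smoking")
        if self.delivery is not None:
            self.delivery.validate()
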