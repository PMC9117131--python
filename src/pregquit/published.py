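"""Published summary counts from the motivating trial.

These are the reported arm-level counts of the randomized trial of refillable
e-cigarettes versus nicotine patches for smoking cessation in pregnancy that
this package re-analyzes.  They are inputs: summary tables printed in the
trial report, usable to rebuild every calculable relative risk and test
statistic without participant-level data.

Each entry is ``(events_ecig, total_ecig, events_nrt, total_nrt)`` with the
patch (NRT) arm as reference, alongside the relative risk and 95% interval
the report prints for that row.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

Counts = Tuple[int, int, int, int]
Printed = Optional[Tuple[float, float, float]]   # (RR, lo, hi); None = NC

# Smoking-cessation outcomes (intention-to-treat unless noted; sensitivity
# rows exclude abstinent non-allocated-product users, hence the smaller
# outcome-specific denominators).
CESSATION: Dict[str, Tuple[Counts, Printed]] = {
    "validated_prolonged_eop": ((39, 571, 25, 569), (1.55, 0.95, 2.53)),
    "per_protocol_validated_prolonged": ((39, 483, 23, 382), (1.34, 0.82, 2.21)),
    "excl_switchers_validated_prolonged": ((39, 571, 20, 564), (1.93, 1.14, 3.26)),
    "self_pp_4wk": ((89, 571, 61, 569), (1.45, 1.07, 1.97)),
    "self_prolonged_eop": ((63, 571, 44, 569), (1.43, 0.99, 2.06)),
    "validated_pp_eop": ((58, 571, 40, 569), (1.44, 0.98, 2.13)),
    "self_pp_eop": ((118, 571, 78, 569), (1.51, 1.16, 1.96)),
    "excl_switchers_self_pp_4wk": ((88, 570, 48, 556), (1.79, 1.28, 2.49)),
    "excl_switchers_self_prolonged": ((61, 569, 31, 556), (1.92, 1.27, 2.92)),
    "excl_switchers_validated_pp_eop": ((56, 569, 29, 558), (1.89, 1.23, 2.92)),
    "excl_switchers_self_pp_eop": ((112, 565, 53, 544), (2.03, 1.50, 2.76)),
}

# Treatment-adherence rows.
ADHERENCE: Dict[str, Tuple[Counts, Printed]] = {
    "tqd_set": ((418, 571, 394, 569), (1.06, 0.98, 1.14)),
    "did_not_use_allocated": ((88, 571, 184, 569), (0.48, 0.38, 0.60)),
    "resupply_requested": ((315, 571, 207, 569), (1.52, 1.33, 1.73)),
    "allocated_current_4wk": ((228, 571, 128, 569), (1.78, 1.48, 2.13)),
    "allocated_regular_study": ((438, 571, 292, 569), (1.49, 1.36, 1.64)),
    "allocated_current_eop": ((193, 571, 32, 569), (6.01, 4.21, 8.58)),
    "nonallocated_current_4wk": ((11, 571, 56, 569), (0.20, 0.10, 0.37)),
    "nonallocated_regular_study": ((16, 571, 101, 569), (0.16, 0.09, 0.26)),
    "nonallocated_current_eop": ((4, 571, 49, 569), (0.08, 0.03, 0.22)),
}

# Birth outcomes, singleton births.
BIRTH: Dict[str, Tuple[Counts, Printed]] = {
    "miscarriage": ((2, 546, 3, 549), (0.67, 0.11, 4.00)),
    "stillbirth": ((2, 546, 0, 549), None),
    "neonatal_death": ((2, 546, 3, 549), (0.67, 0.11, 4.00)),
    "post_neonatal_death": ((0, 546, 3, 549), None),
    "preterm": ((46, 546, 63, 549), (0.73, 0.51, 1.05)),
    "low_birthweight": ((52, 541, 80, 541), (0.65, 0.47, 0.90)),
    "nicu_admission": ((51, 546, 46, 549), (1.11, 0.76, 1.63)),
    "congenital_abnormality": ((25, 546, 15, 549), (1.68, 0.89, 3.14)),
    "any_adverse_birth_outcome": ((112, 546, 119, 549), (0.95, 0.75, 1.19)),
    "cesarean": ((131, 546, 148, 549), (0.89, 0.73, 1.09)),
}

# Nicotine-product use among point-prevalence abstinent participants at end
# of pregnancy: 58 of 118 (e-cigarette arm) vs 15 of 78 (patch arm).
NICOTINE_USE_AMONG_ABSTAINERS: Counts = (58, 118, 15, 78)

# Design assumptions: patch-arm quit rate 8%, e-cigarette-arm 14%,
# two-tailed alpha 0.05, power 90%.
DESIGN = {"p_nrt": 0.08, "p_ecig": 0.14, "alpha": 0.05, "power": 0.90}

PRIMARY_COUNTS: Counts = CESSATION["validated_prolonged_eop"][0]
EXCL_SWITCHERS_COUNTS: Counts = CESSATION["excl_switchers_validated_prolonged"][0]
LOW_BIRTHWEIGHT_COUNTS: Counts = BIRTH["low_birthweight"][0]

ALL_RR_ROWS: Dict[str, Tuple[Counts, Printed]] = {
    **{f"cessation:{k}": v for k, v in CESSATION.items()},
    **{f"adherence:{k}": v for k, v in ADHERENCE.items()},
    **{f"birth:{k}": v for k, v in BIRTH.items()},
}
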