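"""Generate the trial-like synthetic cohort and summarize its margins.

Writes results/cohort.csv (one wide row per randomized participant) and
prints the marginal rates the generator is calibrated to: arm sizes, baseline
cotinine, self-reported and saliva-return rates, product use by arm, and the
birth-outcome margins.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from pregquit.cohort_io import write_cohort
from pregquit.records import EopReport
from pregquit.simulate import trial_like_config, generate_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=2018)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    config = trial_like_config(seed=args.seed)
    cohort = generate_cohort(config)
    write_cohort(cohort, args.out / "cohort.csv")

    by_arm = {arm: [r for r in cohort if r.arm.value == arm]
              for arm in ("ECIG", "NRT")}
    summary = {"seed": args.seed, "n_per_arm": {a: len(v) for a, v in by_arm.items()}}

    cotinine = np.array([r.baseline.cotinine_ng_ml for r in cohort
                         if r.baseline.cotinine_ng_ml is not None])
    summary["baseline_cotinine_median_iqr"] = [
        round(float(np.percentile(cotinine, q)), 1) for q in (50, 25, 75)]

    for arm, recs in by_arm.items():
        self_abst = [r for r in recs if r.eop_self_report in
                     (EopReport.ABSTINENT_7DAY,
                      EopReport.ABSTINENT_AT_DELIVERY_RELAPSED_SINCE)]
        summary[f"{arm}_self_reported_eop_abstinent"] = len(self_abst)
        summary[f"{arm}_ascertained"] = sum(
            r.eop_self_report is not EopReport.MISSING for r in recs)
        summary[f"{arm}_nonallocated_regular_use"] = round(
            float(np.mean([r.product_use.nonallocated_regular_1wk
                           or r.product_use.nonallocated_current_eop
                           or r.product_use.nonallocated_5plus_consecutive_days_first4wks
                           or r.product_use.nonallocated_occasional_3wks
                           for r in recs])), 3)
    quitters = [r for r in cohort if r.eop_self_report in
                (EopReport.ABSTINENT_7DAY,
                 EopReport.ABSTINENT_AT_DELIVERY_RELAPSED_SINCE)]
    summary["saliva_return_among_self_reported_quitters"] = round(
        float(np.mean([r.assays.saliva_returned for r in quitters])), 3)

    bw = np.array([i.birthweight_g for r in cohort if r.delivery
                   for i in r.delivery.infants if i.birthweight_g is not None])
    summary["birthweight_kg_mean_sd"] = [round(float(bw.mean()) / 1000, 2),
                                         round(float(bw.std()) / 1000, 2)]
    summary["low_birthweight_frac"] = round(float(np.mean(bw < 2500)), 3)
    summary["twin_pregnancies"] = sum(
        1 for r in cohort if r.delivery and r.delivery.n_infants == 2)

    (args.out / "cohort_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote {args.out/'cohort.csv'} with {len(cohort)} participants")
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
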