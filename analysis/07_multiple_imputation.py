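"""Multiple-imputation sensitivity analysis on the synthetic cohort.

Imputes missing self-reported sustained status, biochemical validation and
current nicotine use by chained equations (separately by arm), derives the
validated sustained-abstinence outcome passively in each completed dataset,
and pools the log relative risk with Rubin's rules.

This is a sensitivity analysis: missingness in cessation trials is typically
not random (missing-as-failure is the primary convention), so the multiply
imputed quit rates are indicative, not primary.
"""

import argparse
import json
from pathlib import Path

from pregquit.cohort_io import read_cohort
from pregquit.mice import ImputationSpec, mi_primary_rr


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="inp", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--m", type=int, default=50)
    ap.add_argument("--cycles", type=int, default=10)
    ap.add_argument("--seed", type=int, default=2018)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort(args.inp)
    spec = ImputationSpec(m=args.m, cycles=args.cycles, seed=args.seed)
    est = mi_primary_rr(cohort, spec)
    out = {"analysis": "sensitivity: multiple imputation by chained equations "
                       "(missingness in cessation trials is not random; "
                       "missing-as-failure remains the primary convention)",
           "m": est.m, "pooled_rr": round(est.rr, 3),
           "ci": [round(est.ci_low, 3), round(est.ci_high, 3)],
           "p": round(est.p, 4),
           "within_var": est.within_var, "between_var": est.between_var,
           "total_var": est.total_var, "df": est.df}
    print(json.dumps(out, indent=2))
    (args.out / "mi_sensitivity.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
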