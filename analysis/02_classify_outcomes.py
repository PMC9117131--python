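"""Classify every participant's outcomes under the trial's definitions.

Reads results/cohort.csv (from 01_simulate_cohort.py), applies the
Russell-Standard prolonged-abstinence rule, the biochemical validation
hierarchy and the reduction endpoint, and writes one row of outcome calls per
participant to results/outcome_calls.csv.
"""

import argparse
from pathlib import Path

from pregquit.cohort_io import read_cohort
from pregquit.outcomes import OUTCOME_COLUMNS, classify_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="inp", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort(args.inp)
    calls = classify_cohort(cohort)
    calls.to_csv(args.out / "outcome_calls.csv", index=False)
    print(f"classified {len(calls)} participants -> {args.out/'outcome_calls.csv'}")
    print("\nITT event counts by arm:")
    print(calls.groupby("arm")[OUTCOME_COLUMNS].apply(
        lambda g: g.fillna(False).astype(bool).sum()).T)


if __name__ == "__main__":
    main()
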