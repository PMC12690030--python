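#!/usr/bin/env python
"""Fit the outcome-association models with HC3-robust errors.

Runs the full pipeline (indices → classification → summaries →
univariate, subgroup and incremental-R² models) on the cohort and
outcomes files and writes the report tables under results/report/.
Prints the association table: slope, robust 95% CI, R² (%), p, n.
"""

import argparse
import pathlib

from co2gap import read_cohort, read_outcomes, run_pipeline, write_report


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=pathlib.Path,
                    default=pathlib.Path("results/synthetic/cohort.csv"))
    ap.add_argument("--outcomes", type=pathlib.Path,
                    default=pathlib.Path("results/synthetic/outcomes.csv"))
    ap.add_argument("--out", type=pathlib.Path,
                    default=pathlib.Path("results/report"))
    args = ap.parse_args()

    report = run_pipeline(read_cohort(args.cohort), read_outcomes(args.outcomes))
    write_report(report, args.out)
    print(f"report written to {args.out}")

    assoc = report.associations
    for _, row in assoc.iterrows():
        if row.isna()["coefficient"]:
            print(f"  {row['variable']} / {row['outcome']}: {row['note']}")
            continue
        print(
            f"  {row['variable']:<38} {row['outcome']:<26} "
            f"{row['coefficient']:7.2f} ({row['ci95_low']:.2f}–{row['ci95_high']:.2f}) "
            f"R² {row['r2_pct']:5.1f}%  p {row['p_value']:.3f}  n {int(row['n'])}"
        )
    if not report.incremental.empty:
        print("\n  incremental R² over lactate + O2 extraction:")
        for _, row in report.incremental.iterrows():
            print(
                f"  {row['predictor']:<24} {row['outcome']:<26} "
                f"ΔR² {row['delta_r2_pct']:5.2f}%  (base {row['r2_base_pct']:.1f}%"
                f" → full {row['r2_full_pct']:.1f}%)  n {int(row['n'])}"
            )


if __name__ == "__main__":
    main()
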