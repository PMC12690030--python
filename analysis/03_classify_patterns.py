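#!/usr/bin/env python
"""Assign anaerobic-metabolism and hypoperfusion pattern groups.

Reads results/indices.csv, writes per-sample group labels to
results/classification.csv, and prints the admission group distributions
for both four-quadrant schemes.
"""

import argparse
import pathlib

import pandas as pd

from co2gap import classify_table, group_distribution


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indices", type=pathlib.Path,
                    default=pathlib.Path("results/indices.csv"))
    ap.add_argument("--out", type=pathlib.Path,
                    default=pathlib.Path("results/classification.csv"))
    args = ap.parse_args()

    idx = pd.read_csv(args.indices, float_precision="round_trip")
    classed = classify_table(idx)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    classed.to_csv(args.out, index=False)
    print(f"wrote {len(classed)} classified samples to {args.out}")

    h0 = classed[classed["timepoint"] == "H0"]
    for scheme in ("anaerobic_group", "hypoperfusion_group"):
        dist = group_distribution(h0[scheme])
        parts = ", ".join(f"{g}: {p:.1f}%" for g, p in dist.items())
        n_missing = h0[scheme].isna().sum()
        print(f"  admission {scheme}: {parts} (unclassifiable: {n_missing})")


if __name__ == "__main__":
    main()
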