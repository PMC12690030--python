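#!/usr/bin/env python
"""Plot the 24-hour evolution of the O2- and CO2-derived indices.

Median with IQR band per time point for ΔCCO2, ΔCCO2/AV-DO2, O2 extraction
and lactate, written to results/figures/trends.png.
"""

import argparse
import pathlib

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from co2gap.indices import TIMEPOINTS

PANELS = [
    ("dcco2", "ΔCCO2 (mL/dL)"),
    ("ratio", "ΔCCO2/AV-DO2"),
    ("o2_extraction", "O2 extraction (%)"),
    ("lactate", "Lactate (mmol/L)"),
]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indices", type=pathlib.Path,
                    default=pathlib.Path("results/indices.csv"))
    ap.add_argument("--out", type=pathlib.Path,
                    default=pathlib.Path("results/figures/trends.png"))
    args = ap.parse_args()

    idx = pd.read_csv(args.indices)
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
    x = np.arange(len(TIMEPOINTS))
    for ax, (col, label) in zip(axes.ravel(), PANELS):
        med, lo, hi = [], [], []
        for tp in TIMEPOINTS:
            v = idx.loc[idx["timepoint"] == tp, col].dropna()
            q25, q50, q75 = np.percentile(v, [25, 50, 75])
            med.append(q50), lo.append(q25), hi.append(q75)
        ax.plot(x, med, "o-", color="tab:blue")
        ax.fill_between(x, lo, hi, alpha=0.2, color="tab:blue")
        ax.set_ylabel(label)
        ax.set_xticks(x, TIMEPOINTS)
    fig.suptitle("Evolution of O2- and CO2-derived indices after bypass")
    fig.tight_layout()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(args.out, dpi=150)
    print(f"figure written to {args.out}")


if __name__ == "__main__":
    main()
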