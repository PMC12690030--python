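"""Four-quadrant hemodynamic pattern assignment.

Two schemes, each crossing one O2-derived and one CO2-derived marker at
fixed published cutoffs, with the boundary always falling in the lower
group (the cutoffs are "greater than" rules):

* anaerobic metabolism — lactate (> 2 mmol/L) × ΔCCO2/AV-DO2 (> 1.8):
  I neither high, II lactate only, III ratio only, IV both.
* hypoperfusion — O2 extraction (> 30 percentage points) × ΔCCO2
  (> 6 mL/dL): same quadrant layout.

Missing or undefined inputs make a sample unclassifiable (explicit None,
never a silent default group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

GROUPS = ("I", "II", "III", "IV")

LACTATE_CUTOFF_MMOL_L = 2.0
RATIO_CUTOFF = 1.8
EXTRACTION_CUTOFF_PCT = 30.0
DCCO2_CUTOFF_ML_DL = 6.0


def _quadrant(first_high: bool, second_high: bool) -> str:
    if first_high:
        return "IV" if second_high else "II"
    return "III" if second_high else "I"


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def anaerobic_group(lactate: float, ratio: float) -> str | None:
    """Anaerobic-metabolism group from lactate (mmol/L) and ΔCCO2/AV-DO2."""
    if _missing(lactate) or _missing(ratio):
        return None
    return _quadrant(lactate > LACTATE_CUTOFF_MMOL_L, ratio > RATIO_CUTOFF)


def hypoperfusion_group(o2_extraction: float, dcco2: float) -> str | None:
    """Hypoperfusion group from O2 extraction (%) and ΔCCO2 (mL/dL)."""
    if _missing(o2_extraction) or _missing(dcco2):
        return None
    return _quadrant(
        o2_extraction > EXTRACTION_CUTOFF_PCT, dcco2 > DCCO2_CUTOFF_ML_DL
    )


@dataclass(frozen=True)
class PatternAssignment:
    """Group labels plus the defining values they were computed from."""

    anaerobic: str | None
    hypoperfusion: str | None
    lactate: float
    ratio: float
    o2_extraction: float
    dcco2: float


def classify(lactate, ratio, o2_extraction, dcco2) -> PatternAssignment:
    return PatternAssignment(
        anaerobic=anaerobic_group(lactate, ratio),
        hypoperfusion=hypoperfusion_group(o2_extraction, dcco2),
        lactate=lactate,
        ratio=ratio,
        o2_extraction=o2_extraction,
        dcco2=dcco2,
    )


def classify_table(indices: pd.DataFrame) -> pd.DataFrame:
    """Per-row pattern assignment for an indices table.

    Expects columns patient_id, timepoint, lactate, ratio, o2_extraction,
    dcco2; returns those plus anaerobic_group and hypoperfusion_group
    (pandas NA where unclassifiable).
    """
    out = indices[
        ["patient_id", "timepoint", "lactate", "ratio", "o2_extraction", "dcco2"]
    ].copy()
    out["anaerobic_group"] = [
        anaerobic_group(l, r) for l, r in zip(out["lactate"], out["ratio"])
    ]
    out["hypoperfusion_group"] = [
        hypoperfusion_group(e, d)
        for e, d in zip(out["o2_extraction"], out["dcco2"])
    ]
    return out


def group_distribution(labels) -> pd.Series:
    """Percentage of classifiable samples in each group I–IV."""
    s = pd.Series(list(labels)).dropna()
    if len(s) == 0:
        return pd.Series({g: math.nan for g in GROUPS})
    counts = s.value_counts()
    return pd.Series({g: 100.0 * counts.get(g, 0) / len(s) for g in GROUPS})
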