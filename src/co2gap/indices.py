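"""Paired arterial/venous panels → CO2/O2-derived hemodynamic indices.

ΔCCO2 (venous minus arterial whole-blood CO2 content, mL/dL) is a Fick
surrogate for VCO2/cardiac output; AV-DO2 (arterial minus venous O2 content)
plays the same role for VO2; their ratio is a content-based respiratory
quotient surrogate. O2 extraction here is the saturation *difference* in
percentage points (SaO2 − SvO2), not the conventional extraction ratio —
the ratio form is exposed separately as ``o2_extraction_ratio``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import PlausibilityWarning
from .gas_content import GasPanel, blood_co2_content, o2_content

TIMEPOINTS = ("H0", "H6", "H12", "H24")

DCCO2_CUTOFF_ML_DL = 6.0  # content-gap exceedance threshold, mL/dL
RATIO_CUTOFF = 1.8        # RQ-surrogate exceedance threshold, dimensionless


@dataclass(frozen=True)
class PairedSample:
    """Arterial + central-venous panels for one patient at one time point."""

    patient_id: str
    timepoint: str
    arterial: GasPanel
    venous: GasPanel

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"timepoint {self.timepoint!r} not one of {TIMEPOINTS}"
            )
        if self.venous.pco2 < self.arterial.pco2:
            warnings.warn(
                f"{self.patient_id}/{self.timepoint}: venous pCO2 below arterial "
                "(inverted gradient)",
                PlausibilityWarning,
                stacklevel=2,
            )
        if abs(self.venous.hb - self.arterial.hb) > 2.0:
            warnings.warn(
                f"{self.patient_id}/{self.timepoint}: arterial/venous hemoglobin "
                f"differ by more than 2 g/dL",
                PlausibilityWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class DerivedIndices:
    """All O2/CO2-derived quantities for one paired sample.

    Contents in mL/dL; ratio dimensionless (NaN when AV-DO2 ≤ 0);
    o2_extraction in percentage points; flags per the >6 mL/dL and >1.8
    cutoffs (ratio flag is None when the ratio is undefined).
    """

    cao2: float
    cvo2: float
    avdo2: float
    caco2: float
    cvco2: float
    dcco2: float
    ratio: float
    o2_extraction: float
    sao2: float
    svo2: float
    lactate: float
    dcco2_high: bool
    ratio_high: bool | None

    @property
    def o2_extraction_ratio(self) -> float:
        """Conventional extraction ratio (SaO2 − SvO2)/SaO2, dimensionless."""
        return (self.sao2 - self.svo2) / self.sao2


def exceedance_flags(dcco2: float, ratio: float) -> tuple[bool, bool | None]:
    """Strict-inequality exceedance flags; boundary values fall low."""
    dcco2_high = dcco2 > DCCO2_CUTOFF_ML_DL
    ratio_high = None if math.isnan(ratio) else ratio > RATIO_CUTOFF
    return dcco2_high, ratio_high


def derive_indices(
    sample: PairedSample, *, paper_literal_cvo2: bool = False
) -> DerivedIndices:
    """Compute all derived indices for one paired sample.

    ``paper_literal_cvo2=True`` computes the venous O2 dissolved term with
    the *arterial* pO2 (reproducing a published rendering of the formula);
    the default uses the venous panel's own pO2.
    """
    art, ven = sample.arterial, sample.venous
    cao2 = float(o2_content(art.hb, art.so2, art.po2, validate=False))
    ven_po2 = art.po2 if paper_literal_cvo2 else ven.po2
    cvo2 = float(o2_content(ven.hb, ven.so2, ven_po2, validate=False))
    avdo2 = cao2 - cvo2

    caco2 = blood_co2_content(art)
    cvco2 = blood_co2_content(ven)
    dcco2 = cvco2 - caco2

    if avdo2 > 0:
        ratio = dcco2 / avdo2
    else:
        warnings.warn(
            f"{sample.patient_id}/{sample.timepoint}: AV-DO2 = {avdo2:.3g} ≤ 0; "
            "ratio undefined",
            PlausibilityWarning,
            stacklevel=2,
        )
        ratio = math.nan

    dcco2_high, ratio_high = exceedance_flags(dcco2, ratio)
    return DerivedIndices(
        cao2=cao2,
        cvo2=cvo2,
        avdo2=avdo2,
        caco2=caco2,
        cvco2=cvco2,
        dcco2=dcco2,
        ratio=ratio,
        o2_extraction=100.0 * (art.so2 - ven.so2),
        sao2=art.so2,
        svo2=ven.so2,
        lactate=art.lactate,
        dcco2_high=dcco2_high,
        ratio_high=ratio_high,
    )
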