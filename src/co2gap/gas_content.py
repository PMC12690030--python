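"""Whole-blood CO2 content and O2 content from a single blood-gas panel.

The CO2 content chain is the classical empirical Douglas model: an apparent
carbonic-acid dissociation constant pK' (pH- and temperature-dependent), a
plasma CO2 solubility coefficient, a Henderson–Hasselbalch plasma content
term, and a Haldane-effect correction converting plasma content into
whole-blood content (oxygenated hemoglobin binds less CO2).  O2 content is
the standard hemoglobin-bound-plus-dissolved formula.

All formula functions accept floats or numpy arrays and broadcast
elementwise.  The internal canonical CO2 content unit is mmol/L; reported
values are STPD mL per dL of blood (factor 2.226 mL·dL⁻¹ per mmol·L⁻¹).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, MissingDataError

# Empirical coefficient table for the CO2/O2 content chain.  Kept in one
# place so a lab with a different rendering of the model can swap values.
CONSTANTS = {
    # pK' = pk_a + pk_b·(7.4 − pH) + (38 − T)·[pk_c + pk_d·(7.4 − pH)]
    "pk_a": 6.086,
    "pk_b": 0.042,
    "pk_c": 0.00472,
    "pk_d": 0.00139,
    # plasma CO2 solubility S = sol_a + sol_b·(37 − T) + sol_c·(37 − T)²
    "sol_a": 0.0307,
    "sol_b": 0.00057,
    "sol_c": 0.00002,
    # Haldane blood/plasma ratio F = 1 − hald_a·Hb / ((hald_b − hald_c·SO2)·(hald_d − pH))
    "hald_a": 0.0289,
    "hald_b": 3.352,
    "hald_c": 0.456,
    "hald_d": 8.142,
    # unit conversion, mmol/L → mL(STPD)/dL
    "ml_dl_per_mmol_l": 2.226,
    # O2 content: Hb-bound capacity (mL O2 per g Hb) and dissolved O2 (mL/dL/mmHg)
    "o2_hb_capacity": 1.34,
    "o2_solubility": 0.003,
}

ML_DL_PER_MMOL_L = CONSTANTS["ml_dl_per_mmol_l"]

# Plausibility bounds shared by panel validation and the formula guards.
_BOUNDS = {
    "ph": (6.5, 8.0),
    "pco2": (0.0, 150.0),
    "po2": (0.0, 800.0),
    "so2": (0.0, 1.0),
    "hb": (0.0, 25.0),
    "temp": (30.0, 42.0),
}
# bounds open/closed per field: (low_inclusive, high_inclusive)
_INCLUSIVE = {
    "ph": (False, False),
    "pco2": (False, False),
    "po2": (True, True),
    "so2": (True, True),
    "hb": (True, False),
    "temp": (False, False),
}


def _check(name: str, value) -> None:
    lo, hi = _BOUNDS[name]
    lo_inc, hi_inc = _INCLUSIVE[name]
    v = np.asarray(value, dtype=float)
    if np.any(np.isnan(v)):
        raise MissingDataError(f"missing value for field '{name}'")
    bad_lo = v < lo if lo_inc else v <= lo
    bad_hi = v > hi if hi_inc else v >= hi
    if np.any(bad_lo | bad_hi):
        raise DomainError(
            f"{name}={value!r} outside plausible range "
            f"{'[' if lo_inc else '('}{lo}, {hi}{']' if hi_inc else ')'}"
        )


@dataclass(frozen=True)
class GasPanel:
    """One site's blood-gas measurement (arterial or central venous).

    Units: pH unitless, pco2/po2 mmHg, so2 as a fraction in [0, 1],
    hb g/dL, temp °C, lactate mmol/L (optional, usually arterial only),
    fio2 fraction in [0.21, 1] (metadata only, not used in any formula).
    """

    ph: float
    pco2: float
    po2: float
    so2: float
    hb: float
    temp: float
    lactate: float = field(default=math.nan)
    fio2: float = field(default=math.nan)

    def __post_init__(self) -> None:
        for name in ("ph", "pco2", "po2", "so2", "hb", "temp"):
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise MissingDataError(f"missing value for field '{name}'")
            _check(name, value)
        if self.so2 > 1.0:
            raise DomainError("so2 must be a fraction in [0, 1]; convert percent first")


def pk_prime(ph, temp, *, validate: bool = True):
    """Apparent dissociation constant pK' of carbonic acid in plasma."""
    if validate:
        _check("ph", ph)
        _check("temp", temp)
    c = CONSTANTS
    dph = 7.4 - ph
    return c["pk_a"] + c["pk_b"] * dph + (38.0 - temp) * (c["pk_c"] + c["pk_d"] * dph)


def co2_solubility(temp, *, validate: bool = True):
    """Plasma CO2 solubility, mmol·L⁻¹·mmHg⁻¹."""
    if validate:
        _check("temp", temp)
    c = CONSTANTS
    dt = 37.0 - temp
    return c["sol_a"] + c["sol_b"] * dt + c["sol_c"] * dt * dt


def plasma_co2_content(ph, pco2, temp, *, validate: bool = True):
    """Plasma CO2 content (dissolved + bicarbonate), mmol/L."""
    if validate:
        _check("ph", ph)
        _check("pco2", pco2)
        _check("temp", temp)
    s = co2_solubility(temp, validate=False)
    pk = pk_prime(ph, temp, validate=False)
    return s * pco2 * (1.0 + 10.0 ** (ph - pk))


def haldane_factor(hb, so2, ph, *, validate: bool = True):
    """Whole-blood/plasma CO2 content ratio; 1 at hb=0, falls as SO2 rises."""
    if validate:
        _check("hb", hb)
        _check("so2", so2)
        _check("ph", ph)
    c = CONSTANTS
    denom = (c["hald_b"] - c["hald_c"] * so2) * (c["hald_d"] - ph)
    if np.any(np.asarray(denom) <= 0):
        raise DomainError("Haldane denominator non-positive")
    return 1.0 - (c["hald_a"] * hb) / denom


def blood_co2_content_mmol(ph, pco2, hb, so2, temp, *, validate: bool = True):
    """Whole-blood CO2 content, mmol/L (plasma content × Haldane factor)."""
    return plasma_co2_content(ph, pco2, temp, validate=validate) * haldane_factor(
        hb, so2, ph, validate=validate
    )


def blood_co2_content_ml_dl(ph, pco2, hb, so2, temp, *, validate: bool = True):
    """Whole-blood CO2 content, mL(STPD) per dL of blood."""
    return ML_DL_PER_MMOL_L * blood_co2_content_mmol(
        ph, pco2, hb, so2, temp, validate=validate
    )


def blood_co2_content(panel: GasPanel) -> float:
    """Whole-blood CO2 content of a panel, mL/dL."""
    return float(
        blood_co2_content_ml_dl(
            panel.ph, panel.pco2, panel.hb, panel.so2, panel.temp, validate=False
        )
    )


def o2_content(hb, so2, po2, *, validate: bool = True):
    """Blood O2 content, mL/dL: Hb-bound (1.34 mL/g) plus dissolved (0.003/mmHg)."""
    if validate:
        _check("hb", hb)
        _check("so2", so2)
        _check("po2", po2)
    c = CONSTANTS
    return c["o2_hb_capacity"] * hb * so2 + c["o2_solubility"] * po2


def panel_o2_content(panel: GasPanel) -> float:
    return float(o2_content(panel.hb, panel.so2, panel.po2, validate=False))
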