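"""Fick-consistent synthetic post-bypass cohort generator.

Each patient carries a latent hemodynamic state — severity, cardiac index,
O2 consumption index (VO2), CO2 production index (VCO2 = aerobic RQ·VO2
plus an anaerobic excess), and a venous CO2 stagnation multiplier standing
for microcirculatory CO2 accumulation in the post-bypass period.  The Fick
relations are then *inverted*: the latent state fixes target content gaps

    ΔCCO2 = stagnation · VCO2 / (10·CI) · trend(t),   AV-DO2 = VO2 / (10·CI),

and paired blood-gas panels are constructed to reproduce them exactly —
venous O2 saturation in closed form, venous pCO2 by root-finding on the
whole-blood CO2 content chain.  Latent truth is therefore exact by
construction, which is what makes downstream parameter-recovery tests
meaningful.  Outcomes (ventilation days, vasoactive hours) are generated
with configurable linear effects of the H0 indices and pattern group.

Randomness is split per patient via ``numpy.random.SeedSequence.spawn`` so
earlier patients' draws are unchanged when the cohort is enlarged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .classification import anaerobic_group
from .gas_content import CONSTANTS, GasPanel, blood_co2_content_ml_dl
from .indices import DerivedIndices, PairedSample, derive_indices

log = logging.getLogger(__name__)

TREND_MULTIPLIERS = {"H0": 1.0, "H6": 1.05, "H12": 1.10, "H24": 1.15}
LACTATE_MULTIPLIERS = {"H0": 1.0, "H6": 1.0, "H12": 1.0, "H24": 0.85}


@dataclass(frozen=True)
class CohortConfig:
    """All marginal and effect parameters of the generator.

    Marginal defaults are calibrated so the simulated admission indices land
    on the observed post-bypass medians (lactate ≈ 1.6 mmol/L, O2 extraction
    ≈ 29 %, ΔCCO2 ≈ 9.3 mL/dL, ratio ≈ 2.1); effect defaults are the
    association sizes the analysis stage should recover (ventilation slope
    0.14 days per mL/dL of ΔCCO2; group-IV vasoactive excess 28.4 h).
    """

    n: int = 51
    seed: int = 0
    timepoints: tuple[str, ...] = ("H0", "H6", "H12", "H24")

    # latent hemodynamic state
    ci_log_median: float = math.log(2.55)   # cardiac index L/min/m², lognormal
    ci_log_sd: float = 0.25
    ci_severity_coef: float = 0.3           # sicker → lower cardiac index
    ci_bounds: tuple[float, float] = (1.0, 6.0)
    vo2_mean: float = 120.0                 # mL/min/m²
    vo2_sd: float = 20.0
    aerobic_rq: float = 0.8
    anaerobic_excess_mean: float = 15.0     # mL/min/m², exponential
    anaerobic_logit_intercept: float = -0.5
    anaerobic_logit_slope: float = 0.8
    stagnation_median: float = 2.45         # venous CO2 stagnation multiplier
    stagnation_log_sd: float = 0.25
    dcco2_cap_ml_dl: float = 20.0           # physiologic ceiling on the latent gap
    hb_mean: float = 12.0                   # g/dL
    hb_sd: float = 1.5
    cyanotic_prob: float = 0.15

    # arterial panel marginals
    ph_mean: float = 7.38
    ph_sd: float = 0.04
    pco2_mean: float = 39.0                 # mmHg
    pco2_sd: float = 4.0
    temp_mean: float = 36.5                 # °C
    temp_sd: float = 0.4
    sao2_acyanotic: float = 0.98
    sao2_cyanotic: float = 0.85
    pao2_acyanotic_mean: float = 120.0
    pao2_acyanotic_sd: float = 20.0
    pao2_cyanotic_mean: float = 50.0
    pao2_cyanotic_sd: float = 5.0
    venous_ph_offset: float = -0.03
    trend_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(TREND_MULTIPLIERS)
    )

    # lactate
    lactate_log_median: float = math.log(1.4)
    lactate_log_sd: float = 0.35
    lactate_excess_coef: float = 0.05       # mmol/L per mL/min/m² of excess
    lactate_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(LACTATE_MULTIPLIERS)
    )

    # outcome effects
    vent_intercept: float = 2.5             # days
    vent_slope_per_ml: float = 0.14         # days per mL/dL of H0 ΔCCO2
    vent_noise_sd: float = 1.28             # days
    vaso_intercept: float = 17.0            # hours
    vaso_group4_excess: float = 28.4        # hours
    vaso_severity_coef: float = 0.0         # hours per severity SD
    vaso_noise_sd: float = 10.0             # hours
    picu_log_median: float = math.log(2.0)  # days
    picu_log_sd: float = 0.3
    picu_vaso_coef: float = 0.02            # days per vasoactive hour
    vis_log_median: float = math.log(11.0)
    vis_log_sd: float = 0.55
    vis_severity_coef: float = 0.25         # on the log scale
    vis_decay: float = 0.9                  # per time point after H0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be ≥ 1")
        for name in ("ci_log_sd", "vo2_sd", "hb_sd", "ph_sd", "pco2_sd",
                     "temp_sd", "vent_noise_sd", "vaso_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class SyntheticPatientState:
    """Latent hemodynamic truth for one simulated patient."""

    patient_id: str
    severity: float            # standard-normal latent
    cardiac_index: float       # L/min/m²
    vo2_index: float           # mL/min/m²
    vco2_index: float          # mL/min/m² (aerobic + anaerobic excess)
    anaerobic_excess: float    # mL/min/m², ≥ 0
    stagnation: float          # venous CO2 stagnation multiplier
    hb: float                  # g/dL
    cyanotic: bool
    lactate_h0: float          # mmol/L
    fio2: float


@dataclass(frozen=True)
class OutcomeRecord:
    patient_id: str
    vasoactive_hours: float
    vent_days: float
    picu_days: float
    vis_by_timepoint: dict[str, float]


def sample_patient_state(
    config: CohortConfig, rng: np.random.Generator, patient_id: str = "P0"
) -> SyntheticPatientState:
    """Draw one patient's latent state from the configured marginals."""
    sev = rng.normal()
    ci = math.exp(
        rng.normal(config.ci_log_median, config.ci_log_sd)
        - config.ci_severity_coef * sev
    )
    vo2 = max(rng.normal(config.vo2_mean, config.vo2_sd), 40.0)
    hb = min(max(rng.normal(config.hb_mean, config.hb_sd), 6.0), 20.0)
    cyanotic = rng.random() < config.cyanotic_prob
    # flow floor: VO2 cannot exceed deliverable O2 (keeps SvO2 ≥ ~0.10)
    sao2 = config.sao2_cyanotic if cyanotic else config.sao2_acyanotic
    o2cap = CONSTANTS["o2_hb_capacity"] * hb
    ci_floor = vo2 / (10.0 * o2cap * (sao2 - 0.10))
    ci = min(max(ci, config.ci_bounds[0], ci_floor), config.ci_bounds[1])
    p_anaerobic = 1.0 / (
        1.0
        + math.exp(
            -(config.anaerobic_logit_intercept + config.anaerobic_logit_slope * sev)
        )
    )
    excess = (
        rng.exponential(config.anaerobic_excess_mean)
        if rng.random() < p_anaerobic
        else 0.0
    )
    stagnation = config.stagnation_median * math.exp(
        rng.normal(0.0, config.stagnation_log_sd)
    )
    lact = (
        math.exp(rng.normal(config.lactate_log_median, config.lactate_log_sd))
        + config.lactate_excess_coef * excess
    )
    fio2 = rng.uniform(0.25, 0.6)
    return SyntheticPatientState(
        patient_id=patient_id,
        severity=sev,
        cardiac_index=ci,
        vo2_index=vo2,
        vco2_index=config.aerobic_rq * vo2 + excess,
        anaerobic_excess=excess,
        stagnation=stagnation,
        hb=hb,
        cyanotic=cyanotic,
        lactate_h0=lact,
        fio2=fio2,
    )


def latent_targets(
    state: SyntheticPatientState, timepoint: str, config: CohortConfig
) -> tuple[float, float]:
    """Fick-implied (ΔCCO2, AV-DO2) content-gap targets in mL/dL."""
    dcco2 = min(
        state.stagnation
        * state.vco2_index
        / (10.0 * state.cardiac_index)
        * config.trend_multipliers[timepoint],
        config.dcco2_cap_ml_dl,
    )
    avdo2 = state.vo2_index / (10.0 * state.cardiac_index)
    return dcco2, avdo2


def state_to_gases(
    state: SyntheticPatientState,
    timepoint: str,
    rng: np.random.Generator,
    config: CohortConfig,
    *,
    max_attempts: int = 10,
) -> tuple[PairedSample, float, float]:
    """Construct a paired sample whose recomputed indices hit the latent
    targets; returns (sample, target_dcco2, target_avdo2).

    Venous SO2 is solved in closed form so the O2 content difference equals
    the AV-DO2 target; venous pCO2 is solved by root-finding on the
    whole-blood CO2 content chain so the content gap equals the ΔCCO2
    target.  An unreachable target (bracket or saturation infeasibility)
    triggers a logged redraw of the panel noise, with a hard error after
    ``max_attempts``.
    """
    target_dcco2, target_avdo2 = latent_targets(state, timepoint, config)
    hb = state.hb
    o2cap = CONSTANTS["o2_hb_capacity"] * hb
    o2sol = CONSTANTS["o2_solubility"]
    for attempt in range(max_attempts):
        ph_a = float(np.clip(rng.normal(config.ph_mean, config.ph_sd), 6.9, 7.75))
        pco2_a = float(np.clip(rng.normal(config.pco2_mean, config.pco2_sd), 18.0, 90.0))
        temp = float(np.clip(rng.normal(config.temp_mean, config.temp_sd), 33.0, 40.0))
        if state.cyanotic:
            sao2 = config.sao2_cyanotic
            pao2 = float(np.clip(
                rng.normal(config.pao2_cyanotic_mean, config.pao2_cyanotic_sd), 35.0, 70.0
            ))
        else:
            sao2 = config.sao2_acyanotic
            pao2 = float(np.clip(
                rng.normal(config.pao2_acyanotic_mean, config.pao2_acyanotic_sd), 70.0, 400.0
            ))
        # provisional venous pO2 from an approximate SvO2, then exact SvO2
        svo2_approx = sao2 - target_avdo2 / o2cap
        pvo2 = float(np.clip(40.0 + 30.0 * (svo2_approx - 0.70), 25.0, 60.0))
        svo2 = sao2 - (target_avdo2 - o2sol * (pao2 - pvo2)) / o2cap
        if not (0.02 < svo2 < sao2):
            log.warning(
                "%s/%s attempt %d: infeasible venous saturation %.3f; redrawing",
                state.patient_id, timepoint, attempt + 1, svo2,
            )
            continue
        ph_v = ph_a + config.venous_ph_offset
        caco2 = float(
            blood_co2_content_ml_dl(ph_a, pco2_a, hb, sao2, temp, validate=False)
        )

        def gap_error(pv: float) -> float:
            return (
                float(blood_co2_content_ml_dl(ph_v, pv, hb, svo2, temp, validate=False))
                - caco2
                - target_dcco2
            )

        lo, hi = pco2_a, pco2_a + 40.0
        if gap_error(lo) > 0.0 or gap_error(hi) < 0.0:
            log.warning(
                "%s/%s attempt %d: ΔCCO2 target %.2f mL/dL outside venous pCO2 "
                "bracket; redrawing", state.patient_id, timepoint, attempt + 1,
                target_dcco2,
            )
            continue
        pco2_v = brentq(gap_error, lo, hi, xtol=1e-12, rtol=8.9e-16)
        if abs(gap_error(pco2_v)) > 1e-8:
            continue
        lact = state.lactate_h0 * config.lactate_multipliers.get(timepoint, 1.0)
        arterial = GasPanel(
            ph=ph_a, pco2=pco2_a, po2=pao2, so2=sao2, hb=hb, temp=temp,
            lactate=lact, fio2=state.fio2,
        )
        venous = GasPanel(
            ph=ph_v, pco2=float(pco2_v), po2=pvo2, so2=svo2, hb=hb, temp=temp,
            fio2=state.fio2,
        )
        sample = PairedSample(
            patient_id=state.patient_id, timepoint=timepoint,
            arterial=arterial, venous=venous,
        )
        return sample, target_dcco2, target_avdo2
    raise RuntimeError(
        f"{state.patient_id}/{timepoint}: could not realize latent gap targets "
        f"after {max_attempts} attempts"
    )


def generate_outcomes(
    state: SyntheticPatientState,
    h0_indices: DerivedIndices,
    config: CohortConfig,
    rng: np.random.Generator,
) -> OutcomeRecord:
    """Outcome durations with configurable linear effects of the H0 indices."""
    vent = max(
        0.0,
        config.vent_intercept
        + config.vent_slope_per_ml * h0_indices.dcco2
        + rng.normal(0.0, config.vent_noise_sd),
    )
    group = anaerobic_group(h0_indices.lactate, h0_indices.ratio)
    vaso = max(
        0.0,
        config.vaso_intercept
        + config.vaso_group4_excess * (group == "IV")
        + config.vaso_severity_coef * state.severity
        + rng.normal(0.0, config.vaso_noise_sd),
    )
    picu = max(
        1.0,
        round(
            math.exp(rng.normal(config.picu_log_median, config.picu_log_sd))
            + config.picu_vaso_coef * vaso
        ),
    )
    vis0 = math.exp(
        rng.normal(config.vis_log_median, config.vis_log_sd)
        + config.vis_severity_coef * state.severity
    )
    vis = {
        tp: vis0 * config.vis_decay**k * math.exp(rng.normal(0.0, 0.1))
        for k, tp in enumerate(config.timepoints)
    }
    return OutcomeRecord(
        patient_id=state.patient_id,
        vasoactive_hours=vaso,
        vent_days=vent,
        picu_days=picu,
        vis_by_timepoint=vis,
    )


@dataclass
class SyntheticCohort:
    """Generated cohort: long gas table, outcomes table, latent truth table."""

    cohort: pd.DataFrame     # interface CSV schema (one row per panel)
    outcomes: pd.DataFrame
    latents: pd.DataFrame    # per patient-timepoint latent targets
    samples: list[PairedSample]
    states: list[SyntheticPatientState]
    config: CohortConfig


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full longitudinal cohort deterministically from the seed."""
    children = np.random.SeedSequence(config.seed).spawn(config.n)
    rows: list[dict] = []
    latent_rows: list[dict] = []
    outcome_rows: list[dict] = []
    samples: list[PairedSample] = []
    states: list[SyntheticPatientState] = []
    for i, child in enumerate(children):
        pid = f"P{i + 1:04d}"
        gas_ss, outcome_ss = child.spawn(2)
        gas_rng = np.random.default_rng(gas_ss)
        state = sample_patient_state(config, gas_rng, patient_id=pid)
        states.append(state)
        h0_indices: DerivedIndices | None = None
        vis_placeholder: dict[str, float] = {}
        patient_samples = []
        for tp in config.timepoints:
            sample, t_dcco2, t_avdo2 = state_to_gases(state, tp, gas_rng, config)
            patient_samples.append(sample)
            if tp == "H0":
                h0_indices = derive_indices(sample)
            latent_rows.append(
                dict(
                    patient_id=pid, timepoint=tp,
                    target_dcco2=t_dcco2, target_avdo2=t_avdo2,
                    severity=state.severity, cardiac_index=state.cardiac_index,
                    vo2_index=state.vo2_index, vco2_index=state.vco2_index,
                    anaerobic_excess=state.anaerobic_excess,
                    stagnation=state.stagnation,
                )
            )
        if h0_indices is None:
            h0_indices = derive_indices(patient_samples[0])
        outcome = generate_outcomes(
            state, h0_indices, config, np.random.default_rng(outcome_ss)
        )
        samples.extend(patient_samples)
        for sample in patient_samples:
            vis = outcome.vis_by_timepoint.get(sample.timepoint, math.nan)
            for site, panel in (
                ("arterial", sample.arterial), ("venous", sample.venous)
            ):
                rows.append(
                    dict(
                        patient_id=pid, timepoint=sample.timepoint, site=site,
                        ph=panel.ph, pco2_mmhg=panel.pco2, po2_mmhg=panel.po2,
                        so2=panel.so2, hb_g_dl=panel.hb, temp_c=panel.temp,
                        lactate_mmol_l=panel.lactate, fio2=panel.fio2, vis=vis,
                    )
                )
        orow = dict(
            patient_id=pid,
            vasoactive_hours=outcome.vasoactive_hours,
            vent_days=outcome.vent_days,
            picu_days=outcome.picu_days,
        )
        for tp in ("H0", "H6", "H12", "H24"):
            orow[f"vis_{tp.lower()}"] = outcome.vis_by_timepoint.get(tp, math.nan)
        outcome_rows.append(orow)
    return SyntheticCohort(
        cohort=pd.DataFrame(rows),
        outcomes=pd.DataFrame(outcome_rows),
        latents=pd.DataFrame(latent_rows),
        samples=samples,
        states=states,
        config=config,
    )


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    """Copy of a config with a different seed (for replicate cohorts)."""
    return replace(config, seed=seed)
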