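"""CSV I/O, validation/quarantine, and the end-to-end pipeline.

The cohort file is long format, one row per blood-gas panel:
``patient_id, timepoint (H0/H6/H12/H24), site (arterial/venous), ph,
pco2_mmhg, po2_mmhg, so2, hb_g_dl, temp_c, lactate_mmol_l, fio2, vis``.
O2 saturations may be given as fractions or percent; a column whose values
exceed 1.5 is interpreted as percent and converted (logged).  Implausible
rows are quarantined with a reason, never silently dropped, and the run log
accounts for every input row.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classification as cls
from . import cohort_analysis as ca
from .errors import SampleSizeError
from .gas_content import GasPanel
from .indices import (
    DCCO2_CUTOFF_ML_DL,
    RATIO_CUTOFF,
    TIMEPOINTS,
    PairedSample,
    derive_indices,
)

log = logging.getLogger(__name__)

MANDATORY_COLUMNS = (
    "patient_id", "timepoint", "site", "ph", "pco2_mmhg", "po2_mmhg",
    "so2", "hb_g_dl", "temp_c",
)
OPTIONAL_COLUMNS = ("lactate_mmol_l", "fio2", "vis")


class SchemaError(ValueError):
    """The cohort file lacks a mandatory column."""


@dataclass
class CohortTable:
    """Validated paired samples plus the quarantine ledger."""

    samples: list[PairedSample]
    quarantined: pd.DataFrame   # original rows + 'reason'
    log_lines: list[str] = field(default_factory=list)

    @property
    def n_patients(self) -> int:
        return len({s.patient_id for s in self.samples})


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the analysis pipeline (not of the generator)."""

    paper_literal_cvo2: bool = False
    ci_dist: str = "t"          # "t" (df = n−p) or "normal"
    n_floor: int = 10
    float_digits: int | None = 6  # None = full precision on output


def _detect_percent(series: pd.Series, name: str, log_lines: list[str]) -> pd.Series:
    values = pd.to_numeric(series, errors="coerce")
    if values.dropna().gt(1.5).any():
        log_lines.append(f"column {name}: values > 1.5 → interpreted as percent")
        log.info("column %s interpreted as percent; converting to fraction", name)
        return values / 100.0
    return values


def read_cohort(path) -> CohortTable:
    """Read, validate, and pair a long-format cohort CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    for c in OPTIONAL_COLUMNS:
        if c not in df.columns:
            df[c] = math.nan
    log_lines: list[str] = [f"read {len(df)} rows from {path}"]
    df = df.copy()
    df["so2"] = _detect_percent(df["so2"], "so2", log_lines)

    dup = df.duplicated(subset=["patient_id", "timepoint", "site"], keep=False)
    quarantine_frames = []
    if dup.any():
        qd = df[dup].copy()
        qd["reason"] = "duplicate (patient_id, timepoint, site)"
        quarantine_frames.append(qd)
        df = df[~dup]

    panels: dict[tuple[str, str], dict[str, GasPanel]] = {}
    bad_rows = []
    for idx, row in df.iterrows():
        site = str(row["site"]).strip().lower()
        tp = str(row["timepoint"]).strip()
        if site not in ("arterial", "venous"):
            bad_rows.append((idx, f"unknown site {row['site']!r}"))
            continue
        if tp not in TIMEPOINTS:
            bad_rows.append((idx, f"invalid timepoint {row['timepoint']!r}"))
            continue
        try:
            panel = GasPanel(
                ph=float(row["ph"]), pco2=float(row["pco2_mmhg"]),
                po2=float(row["po2_mmhg"]), so2=float(row["so2"]),
                hb=float(row["hb_g_dl"]), temp=float(row["temp_c"]),
                lactate=float(row["lactate_mmol_l"])
                if pd.notna(row["lactate_mmol_l"]) else math.nan,
                fio2=float(row["fio2"]) if pd.notna(row["fio2"]) else math.nan,
            )
        except (ValueError, TypeError) as exc:
            bad_rows.append((idx, f"implausible panel: {exc}"))
            continue
        panels.setdefault((str(row["patient_id"]), tp), {})[site] = panel

    samples: list[PairedSample] = []
    for (pid, tp), sites in sorted(panels.items()):
        if "arterial" in sites and "venous" in sites:
            samples.append(
                PairedSample(
                    patient_id=pid, timepoint=tp,
                    arterial=sites["arterial"], venous=sites["venous"],
                )
            )
        else:
            present = next(iter(sites))
            mask = (
                (df["patient_id"].astype(str) == pid)
                & (df["timepoint"].astype(str) == tp)
                & (df["site"].astype(str).str.lower() == present)
            )
            qd = df[mask].copy()
            qd["reason"] = "unpaired"
            quarantine_frames.append(qd)

    if bad_rows:
        idxs = [i for i, _ in bad_rows]
        qd = df.loc[idxs].copy()
        qd["reason"] = [r for _, r in bad_rows]
        quarantine_frames.append(qd)

    quarantined = (
        pd.concat(quarantine_frames, ignore_index=True)
        if quarantine_frames
        else pd.DataFrame(columns=list(df.columns) + ["reason"])
    )
    log_lines.append(
        f"paired samples: {len(samples)}; quarantined rows: {len(quarantined)}"
    )
    for _, row in quarantined.iterrows():
        log_lines.append(
            f"quarantined {row['patient_id']}/{row['timepoint']}/{row['site']}: "
            f"{row['reason']}"
        )
    return CohortTable(samples=samples, quarantined=quarantined, log_lines=log_lines)


def read_outcomes(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if "patient_id" not in df.columns:
        raise SchemaError("outcomes table must have a patient_id column")
    for col in ("vasoactive_hours", "vent_days", "picu_days"):
        if col in df.columns and (pd.to_numeric(df[col], errors="coerce") < 0).any():
            raise ValueError(f"negative values in outcome column {col}")
    return df


def indices_table(
    samples: list[PairedSample], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Derived-indices table, one row per paired sample."""
    config = config or PipelineConfig()
    rows = []
    for s in samples:
        d = derive_indices(s, paper_literal_cvo2=config.paper_literal_cvo2)
        rows.append(
            dict(
                patient_id=s.patient_id, timepoint=s.timepoint,
                cao2=d.cao2, cvo2=d.cvo2, avdo2=d.avdo2,
                caco2=d.caco2, cvco2=d.cvco2, dcco2=d.dcco2,
                ratio=d.ratio, o2_extraction=d.o2_extraction,
                lactate=d.lactate, dcco2_high=d.dcco2_high,
                ratio_high=d.ratio_high,
            )
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineReport:
    indices: pd.DataFrame
    classification: pd.DataFrame
    summaries: pd.DataFrame
    associations: pd.DataFrame
    incremental: pd.DataFrame
    log_lines: list[str]


def _summary_rows(idx: pd.DataFrame) -> pd.DataFrame:
    specs = [
        ("dcco2", "mL/dL", DCCO2_CUTOFF_ML_DL),
        ("ratio", "", RATIO_CUTOFF),
        ("o2_extraction", "%", None),
        ("lactate", "mmol/L", None),
    ]
    rows = []
    for tp in TIMEPOINTS:
        sub = idx[idx["timepoint"] == tp]
        if sub.empty:
            continue
        for var, unit, thr in specs:
            s = ca.summarize(sub[var], threshold=thr)
            rows.append(
                dict(
                    timepoint=tp, variable=var, unit=unit, n=s.n,
                    median=s.median, q25=s.q25, q75=s.q75,
                    threshold=thr, n_above=s.n_above, pct_above=s.pct_above,
                )
            )
    return pd.DataFrame(rows)


def _assoc_row(variable, outcome_name, result, n_note="") -> dict:
    if isinstance(result, str):
        return dict(
            variable=variable, outcome=outcome_name, coefficient=math.nan,
            ci95_low=math.nan, ci95_high=math.nan, r2_pct=math.nan,
            p_value=math.nan, n=math.nan, note=result,
        )
    return dict(
        variable=variable, outcome=outcome_name, coefficient=result.coefficient,
        ci95_low=result.ci95_low, ci95_high=result.ci95_high,
        r2_pct=result.r2_pct, p_value=result.p_value, n=result.n, note=n_note,
    )


OUTCOME_COLUMNS = {
    "vasoactive_hours": "Vasoactive support (h)",
    "vent_days": "Mechanical ventilation (d)",
}


def run_pipeline(
    cohort: CohortTable,
    outcomes: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> PipelineReport:
    """Indices → classification → summaries → association report.

    Associations mirror the study design: H0 ΔCCO2 and H0 ratio univariate
    against both outcomes, the two four-group schemes (reference group I
    with unadjusted post-hoc I-vs-group contrasts), and the incremental-R²
    models adding each CO2-derived predictor (level at H0 and H6/H0, H24/H0
    dynamic ratios) to a lactate + O2-extraction base model.
    """
    config = config or PipelineConfig()
    log_lines = list(cohort.log_lines)
    idx = indices_table(cohort.samples, config)
    classed = cls.classify_table(idx) if not idx.empty else pd.DataFrame()
    summaries = _summary_rows(idx)

    h0 = idx[idx["timepoint"] == "H0"].set_index("patient_id")
    merged = outcomes.set_index("patient_id").join(h0, how="inner")
    assoc_rows = []
    for pred, label in (("dcco2", "ΔCCO2 H0"), ("ratio", "ΔCCO2/AV-DO2 H0")):
        for ocol, oname in OUTCOME_COLUMNS.items():
            if ocol not in merged.columns:
                continue
            try:
                res = ca.univariate_association(
                    merged[ocol], merged[pred],
                    n_floor=config.n_floor, ci_dist=config.ci_dist,
                )
                note = ""
            except SampleSizeError as exc:
                res, note = str(exc), ""
                log_lines.append(f"{label} vs {oname}: refused ({exc})")
            assoc_rows.append(_assoc_row(label, oname, res, note))

    classed_h0 = (
        classed[classed["timepoint"] == "H0"].set_index("patient_id")
        if not classed.empty else pd.DataFrame()
    )
    for scheme, col in (
        ("Anaerobic subgroup", "anaerobic_group"),
        ("Hypoperfusion subgroup", "hypoperfusion_group"),
    ):
        if classed_h0.empty:
            continue
        joined = outcomes.set_index("patient_id").join(
            classed_h0[[col]], how="inner"
        )
        for ocol, oname in OUTCOME_COLUMNS.items():
            if ocol not in joined.columns:
                continue
            sub = joined[[ocol, col]].dropna()
            if len(sub) < config.n_floor or sub[col].nunique() < 2:
                log_lines.append(f"{scheme} vs {oname}: refused (insufficient data)")
                assoc_rows.append(
                    _assoc_row(scheme, oname, "insufficient data for subgroup model")
                )
                continue
            try:
                result = ca.subgroup_association(
                    sub[ocol], sub[col], ci_dist=config.ci_dist
                )
            except (SampleSizeError, ValueError) as exc:
                log_lines.append(f"{scheme} vs {oname}: refused ({exc})")
                assoc_rows.append(_assoc_row(scheme, oname, str(exc)))
                continue
            if result.overall is not None:
                assoc_rows.append(
                    _assoc_row(f"{scheme} (ordinal)", oname, result.overall)
                )
            for g, contrast in result.contrasts.items():
                assoc_rows.append(
                    _assoc_row(
                        f"{scheme} post hoc I vs {g}", oname, contrast,
                        "unadjusted post-hoc contrast",
                    )
                )
            log_lines.append(f"{scheme} vs {oname}: n={result.n}")
    associations = pd.DataFrame(assoc_rows)

    # incremental R² over lactate + O2 extraction
    inc_rows = []
    if not h0.empty:
        wide = {
            var: idx.pivot_table(
                index="patient_id", columns="timepoint", values=var
            )
            for var in ("dcco2", "ratio")
        }
        base = outcomes.set_index("patient_id").join(
            h0[["lactate", "o2_extraction"]], how="inner"
        )
        for var, label in (("dcco2", "ΔCCO2"), ("ratio", "ΔCCO2/AV-DO2")):
            transforms = {
                pid: ca.predictor_transforms(
                    wide[var].loc[pid] if pid in wide[var].index else {},
                    threshold=ca.DEFAULT_THRESHOLDS[var],
                )
                for pid in base.index
            }
            tdf = pd.DataFrame(transforms).T
            for key, tag in (
                ("h0", "H0 level"), ("ratio_h6_h0", "H6/H0"),
                ("ratio_h24_h0", "H24/H0"),
            ):
                for ocol, oname in OUTCOME_COLUMNS.items():
                    if ocol not in base.columns:
                        continue
                    try:
                        inc = ca.incremental_r2(
                            base[ocol], base[["lactate", "o2_extraction"]],
                            tdf[key],
                        )
                    except (SampleSizeError, ValueError) as exc:
                        log_lines.append(
                            f"incremental {label} {tag} vs {oname}: refused ({exc})"
                        )
                        continue
                    inc_rows.append(
                        dict(
                            predictor=f"{label} {tag}", outcome=oname,
                            r2_base_pct=100 * inc.r2_base,
                            r2_full_pct=100 * inc.r2_full,
                            delta_r2_pct=100 * inc.delta_r2, n=inc.n,
                        )
                    )
    incremental = pd.DataFrame(inc_rows)
    for _, row in associations.iterrows():
        if isinstance(row.get("note"), str) and row["note"]:
            continue
    log_lines.append(
        f"models fitted: {len(associations)} association rows, "
        f"{len(incremental)} incremental-R² rows"
    )
    return PipelineReport(
        indices=idx, classification=classed, summaries=summaries,
        associations=associations, incremental=incremental, log_lines=log_lines,
    )


def write_report(report: PipelineReport, outdir, config: PipelineConfig | None = None):
    """Write the report tables and run log under a directory."""
    import pathlib

    config = config or PipelineConfig()
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = None
    if config.float_digits is not None:
        fmt = f"%.{config.float_digits}g"
    for name in ("indices", "classification", "summaries", "associations",
                 "incremental"):
        df = getattr(report, name)
        df.to_csv(out / f"{name}.csv", index=False, float_format=fmt)
    (out / "run.log").write_text("\n".join(report.log_lines) + "\n")
    return out
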