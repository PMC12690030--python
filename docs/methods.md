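# Methods

Derivations, conventions and parameter rationale for the `co2gap`
pipeline. Field names in code are given in backticks.

## 1. Whole-blood CO2 content (`gas_content`)

CO2 content is computed per gas panel from pH, pCO2 (mmHg), hemoglobin
(g/dL), O2 saturation (fraction) and temperature (°C) with the Douglas
relations:

```
pK' = 6.086 + 0.042·(7.4 − pH) + (38 − T)·(0.00472 + 0.00139·(7.4 − pH))
S   = 0.0307 + 0.00057·(37 − T) + 0.00002·(37 − T)²           mmol/L/mmHg
plasma CO2 = S · pCO2 · (1 + 10^(pH − pK'))                    mmol/L
F = 1 − 0.0289·Hb / ((3.352 − 0.456·SO2)·(8.142 − pH))         (Haldane)
CCO2 [mL/dL] = 2.226 · plasma CO2 · F
```

`F < 1` corrects plasma content down to whole-blood content; deoxygenated
blood (lower SO2) carries more CO2 at the same pCO2, which is why a
content-based gradient behaves differently from the raw pCO2 gap when
saturations diverge. The factor 2.226 converts mmol/L to mL/dL at STPD.
All constants are centralized in `gas_content.CONSTANTS`.

O2 content: `CO2ct = 1.34·Hb·SO2 + 0.003·PO2` mL/dL (bound + dissolved).

Inputs are validated against physiologic plausibility windows (e.g. pH
6.8–7.8, pCO2 10–150 mmHg, Hb 3–25 g/dL); violations raise `DomainError`
at the library surface and quarantine rows at the CSV surface.

## 2. Derived indices (`indices`)

For an arterial/venous panel pair:

- `dcco2 = CvCO2 − CaCO2` (mL/dL)
- `avdo2 = CaO2 − CvO2` (mL/dL)
- `ratio = dcco2 / avdo2` (≈ respiratory quotient by Fick; NaN when
  `avdo2 ≤ 0`)
- `o2_extraction = 100·(SaO2 − SvO2)` — a *saturation difference in
  percentage points*, not the extraction ratio `(SaO2−SvO2)/SaO2`. The
  ratio form is available as `DerivedIndices.o2_extraction_ratio`.

A `PlausibilityWarning` (never a silent fix) is emitted for inverted
gradients (venous CO2 content below arterial) and arterio-venous Hb
mismatch > 2 g/dL.

`paper_literal_cvo2` option: some published formulations reuse the
*arterial* pO2 in the venous O2-content dissolved term (most plausibly a
transcription slip). Default is the physiologically correct venous pO2;
setting `paper_literal_cvo2=True` reproduces the literal published
arithmetic. The difference is `0.003·(PaO2 − PvO2)` mL/dL on `avdo2`,
usually < 0.25 mL/dL.

## 3. Classification (`classification`)

Fixed cutoffs, all strict (a value exactly at the cutoff falls in the
*lower* stratum):

| quantity | cutoff |
|---|---|
| ΔCCO2 | > 6 mL/dL |
| ΔCCO2/AV-DO2 | > 1.8 |
| lactate | > 2 mmol/L |
| O2 extraction | > 30 % |

Two 2×2 schemes: *anaerobic* crosses lactate × ratio, *hypoperfusion*
crosses O2 extraction × ΔCCO2. Groups: I = both low, II = first high
only, III = second high only, IV = both high (so in the anaerobic scheme
III means "ratio high, lactate still normal" — the early-warning
quadrant). Missing inputs yield a missing group label, never a default
group.

## 4. Cohort analysis (`cohort_analysis`)

- **Summaries**: median and IQR via `numpy.percentile` with linear
  interpolation (the default); exceedance counts use the strict cutoffs.
- **Associations**: OLS via statsmodels with HC3 covariance
  `(XᵀX)⁻¹ Xᵀ diag(e²/(1−h)²) X (XᵀX)⁻¹`. HC3 is the leverage-adjusted
  sandwich recommended for small samples (n ≈ 50) under
  heteroskedasticity. Tests verify it against a brute-force loop
  implementation to 1e-10.
- **CIs**: t-distribution with df = n − p by default (`ci_dist="t"`),
  switchable to `"normal"`. At n = 51 the t/normal difference is visible
  in the second decimal of the CI half-width; t is the conservative
  choice.
- **R²** is reported ×100 (percent).
- **Subgroup models**: indicator coding against reference group I with
  unadjusted post-hoc I-vs-group contrasts, plus an ordinal (1–4 coded)
  single-slope variant. A singleton group has leverage 1, making the HC3
  weight undefined: singleton non-reference groups are flagged in
  `small_groups` and excluded from the indicator model; a singleton
  *reference* group makes all contrasts undefined and the model is
  refused with `SampleSizeError` (the pipeline logs the refusal and
  continues).
- **Incremental R²**: both nested models are fit on the same complete
  cases (listwise deletion on the union of variables); a zero-variance
  added predictor yields ΔR² = 0 by definition.
- `n_floor = 10`: models with fewer complete cases are refused rather
  than fit.

## 5. Synthetic cohort generator (`synthetic_cohort`)

### Latent state per patient

| parameter | default | units | rationale |
|---|---|---|---|
| severity | N(0, 1) | SD | shared illness axis |
| `ci_log_median` / `ci_log_sd` | log 2.55 / 0.25 | L/min/m² | lognormal cardiac index; severity lowers it by `ci_severity_coef`=0.3 per SD; clamped to `ci_bounds` (1, 6) |
| `vo2_mean` / `vo2_sd` | 120 / 20 | mL/min/m² | pediatric post-operative O2 consumption index |
| `aerobic_rq` | 0.8 | — | VCO2 = 0.8·VO2 aerobically |
| anaerobic excess | Exp(15)·Bernoulli(logistic(−0.5 + 0.8·severity)) | mL/min/m² | extra CO2 production in sicker patients |
| `stagnation_median` / `stagnation_log_sd` | 2.45 / 0.25 | — | venous CO2 stagnation multiplier, see below |
| `hb_mean` / `hb_sd` | 12 / 1.5 | g/dL | post-bypass hemoglobin |
| `cyanotic_prob` | 0.15 | — | cyanotic lesions: SaO2 0.85, PaO2 ≈ 50 mmHg |

### Fick inversion

The latent state fixes target gaps per time point `t`:

```
ΔCCO2(t)  = min(cap, stagnation · VCO2 / (10·CI)) · trend(t)
AV-DO2(t) = VO2 / (10·CI)
```

with deterministic `trend` multipliers {H0: 1.00, H6: 1.05, H12: 1.10,
H24: 1.15}. Venous SO2 comes in closed form from the AV-DO2 target;
venous pCO2 is found by `scipy.optimize.brentq` on the CO2 content chain
over `[pCO2_a, pCO2_a + 40]` to |error| < 1e-8, with venous pH = arterial
− 0.03. Infeasible draws are re-sampled (up to 10 attempts, logged).
Because the panels reproduce the latent targets exactly, the generator is
an end-to-end oracle for the analysis stage.

**Stagnation multiplier.** A plain Fick quotient VCO2/VO2 ≈ 0.8–1.0
cannot simultaneously produce the observed post-bypass admission medians
(ΔCCO2 ≈ 9.3 mL/dL *and* ratio ≈ 2.1, i.e. an effective quotient ≈ 2)
with plausible cardiac indices. The generator therefore includes an
explicit venous-side multiplier representing microcirculatory CO2
stagnation — regional low-flow beds accumulating CO2 beyond what global
production implies — applied to the CO2 gap only. Its median (2.45) is a
calibration constant, not a measured physiologic quantity.

**Feasibility guards.** (a) Cardiac-index floor
`CI ≥ VO2 / (10·1.34·Hb·(SaO2 − 0.10))` so the AV-DO2 target never
demands SvO2 < 0.10; (b) `dcco2_cap_ml_dl` = 20 mL/dL ceiling on the
latent gap so the venous pCO2 root stays inside the bracket. Both guards
are state-level (applied before panel construction), so latent truth
remains exact.

### Outcomes

```
vent_days        = max(0, 2.5 + 0.14·ΔCCO2(H0) + N(0, 1.28))
vasoactive_hours = max(0, 17 + 28.4·1{anaerobic group IV} + N(0, 10))
```

`vent_intercept` = 2.5 and `vent_noise_sd` = 1.28 were chosen so that
(i) zero-floor truncation affects < 1 % of patients, keeping the
configured slope identifiable, and (ii) the univariate R² lands in the
low-20 % range typical of single-predictor clinical models. The trade-off
of (i) is a ventilation-days median (~3.7 d) somewhat above a typical
observed median (~2 d); identifiability of the configured slope was
prioritized over matching that one marginal. `vaso_severity_coef`
defaults to 0 because a severity effect would confound the group-IV
contrast and make the configured 28.4 h excess non-recoverable by the
(severity-blind) analysis model. Lactate is lognormal(log 1.4, 0.35) plus
0.05 per unit anaerobic excess, ×0.85 at H24 (clearance).

### Determinism

Each patient gets an independent child stream via
`SeedSequence(seed).spawn(n)`, so patient `k`'s data are byte-identical
for any cohort size ≥ k+1. Generation, the CSV round trip (with pandas
`float_precision="round_trip"`) and the full pipeline report are
byte-for-byte reproducible for a fixed seed.

## 6. Calibration and verification

Design-time calibration targets (admission, H0): ΔCCO2 median ≈ 9.3
mL/dL, ratio ≈ 2.1, O2 extraction ≈ 29 %, lactate ≈ 1.6 mmol/L. The test
suite checks, among others:

- content chain vs hand-computed values and a 1000-panel independent
  straight-line re-derivation (rel. tol. 1e-12), plus monotonicity
  properties (hypothesis, seeded/derandomized);
- HC3 vs a brute-force loop implementation (1e-10);
- classification truth tables at and around every cutoff;
- cohort round trip: simulate n = 500 → write → read → re-derive indices,
  max deviation from latent targets < 1e-6;
- parameter recovery at n = 2000: ventilation slope and group-IV contrast
  within their robust 95 % CIs, bias ≤ 1 % over 200 replicates;
- CI calibration: 93.5 % empirical coverage over 200 replicates of
  n = 500 (accepted band 92–98 %).

## 7. Known limitations

- The trend multipliers are deterministic and applied to ΔCCO2 only,
  while the AV-DO2 target is time-invariant. Consequently the H6/H0 and
  H24/H0 *dynamic ratios* of ΔCCO2 and of the ΔCCO2/AV-DO2 ratio coincide
  and are near-constant across simulated patients (1.05/1.15 exactly,
  except where the 20 mL/dL cap binds). The dynamic-ratio predictors in
  the incremental-R² models are therefore nearly degenerate on synthetic
  data; they are meaningful only on real cohorts with patient-specific
  trajectories.
- The stagnation multiplier is a lumped calibration device; it does not
  model regional flow explicitly.
- Venous pH is a fixed −0.03 offset from arterial rather than being
  solved self-consistently with the CO2 load.
- Outcome models are linear with additive Gaussian noise and a hard zero
  floor; no censoring or competing risks.
- Plausibility windows are tuned for pediatric post-bypass ranges;
  adult or neonatal data may need wider bounds.

## 8. Problem sizes

The default analysis cohort is 51 patients × 4 time points × 2 panels
(408 rows). Acceptance recomputation uses a fresh n = 2000 admission-only
cohort (~3 s). The full test suite, including the 200-replicate recovery
and coverage studies, runs in ~3 minutes single-core.
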