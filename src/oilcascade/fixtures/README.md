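# Packaged study fixtures

These CSVs transcribe the published measurement tables of the rapeseed-oil
thermal-degradation study that this package models: five treatments
(C = no additive; CA-2/CA-4/CA-7 = carnosic acid at 200/400/700 mg/kg;
TB-2 = TBHQ at 200 mg/kg) heated at 180 °C and sampled at 0, 8, 16, 24
and 32 h.

| file | contents |
| --- | --- |
| `study_fatty_acids.csv` | FA compositions (mass %) at 0/16/32 h, long format |
| `study_fa_class_totals.csv` | the UFA/MUFA/PUFA class sums as printed |
| `study_ecn.csv` | effective carbon numbers as printed, all 25 conditions |
| `study_tpc.csv` | total polar compounds (%) as printed, all 25 conditions |
| `study_viscosity_params.csv` | fitted viscosity-model parameters (a, b, R² / μ0, Ea, R²) per condition |

Raw viscosity sweeps were not published; only the fitted parameters per
condition are available, rounded to 2 decimals (a, b) / 2 decimals (μ0).

## Known internal inconsistencies of the source tables

Fixtures transcribe the tables **as printed**; the inconsistencies below are
in the source itself and are asserted as documented deviations by the test
suite rather than patched here.

1. **Control ECN at 32 h.** Recomputing ECN = Σ (Pᵢ/100)(Cᵢ − dbᵢ) from the
   printed C-32 FA row gives 16.19; the ECN table prints 16.23. Every other
   (treatment, time) cell with a printed FA row agrees to ±0.01.
2. **CA-2 TPC at 32 h.** The TPC table prints 32.5 %, and the accompanying
   text gives 32.0 ± 0.5 % (and 32.5 % for TB-2). The published CA-2 trend
   line (slope 0.8438, intercept 4.9) is reproducible only if the 32-h value
   was 35.5 — i.e. the control column's value. The fixture keeps 32.5 as
   printed; refitting it yields slope 0.7688, intercept 5.5.
3. The five 0-h FA rows are identical by design (all treatments start from
   the same fresh oil), so the small spread in printed 0-h ECN values
   (16.13 vs 16.14) is rounding scatter, not signal.
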