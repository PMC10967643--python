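# Methods

## Scope and data model

The package models one study design: a vegetable oil (rapeseed in the
reference study) held at frying temperature (180 °C), optionally dosed with
an antioxidant, and sampled at fixed processing times t_P (default 0, 8,
16, 24, 32 h). Three measurements per condition drive everything:
viscosity sweeps μ(T) at a fixed shear rate (the oil is treated as
Newtonian, so shear rate is metadata only), fatty-acid compositions in mass
percent, and total polar compounds (TPC, %).

## Viscosity–temperature models

Both laws are fit by ordinary least squares after a log transform:

* Lioumbas: ln μ = a + b (ln T)², regressing ln μ on (ln T)²;
* Arrhenius: ln μ = ln μ₀ + Eₐ/(R·T_K), regressing ln μ on 1/(R·T_K),
  R = 8.314 J/(mol·K).

Conventions that matter:

* **Temperature in the Lioumbas law is °C, not Kelvin.** With typical
  fitted parameters (a ≈ 6.3, b ≈ −0.19) the °C convention predicts
  ≈ 23 mPa·s at 60 °C, the right magnitude for rapeseed oil; Kelvin would
  predict ≈ 0.9 mPa·s, absurd for any oil. The Arrhenius law uses Kelvin
  as always.
* **r² is reported on the ln μ scale**, the scale the regression is solved
  on. When the response is perfectly constant both the total and residual
  sums of squares vanish and r² is defined as 1 (the fit is exact); the
  degenerate-case detection uses a relative threshold (10⁻²⁰ of ‖y‖²) so
  float noise in a constant response does not flip the definition.
* Natural logarithms throughout.
* Model comparison ties break toward Lioumbas, the study's working model.

## The degradation cascade

Per-timepoint Lioumbas fits give (a, b) pairs. Two chained OLS lines —
b on t_P, then a on b — composed with the Lioumbas law give the forecast
μ(t_P, T). Design choices:

* **Full-precision propagation.** Trend coefficients are never rounded
  before being chained: refitting the time trend from 2-decimal-rounded b
  values changes its slope by ~50 % (−0.0009 vs −0.0006 for the untreated
  control), so published rounded coefficients serve only as generator
  truth and spot-check inputs, never as intermediate values.
* Predictions outside the fitted t_P range are returned but flagged as
  extrapolation and logged; the trends are empirical, not kinetic laws.
* Trend r² is computed on the original scale; the zero-residual degenerate
  case is again defined as 1.
* The composition-coupled alternative regresses b on (ECN, TPC) as a
  single pooled plane over all (treatment × time) conditions via
  statsmodels OLS, matching the study's single global fit.

### Parity analysis

deviation% = (observed − calculated)/observed × 100 — the residual
normalised by the *experimental* value, the usual convention for parity
plots (the source never defines its denominator). A zero observed value is
rejected rather than producing an undefined deviation. For TPC parity the
0-h baseline is the one place this convention is uninformative: the
denominator is the small fresh-oil TPC (~7 %), so even a sub-2-point
residual can exceed ±20 % there; accuracy statements about TPC deviation%
therefore apply to the heated (t_P > 0) conditions.

## Composition metrics

ECN = Σ (Pᵢ/100)(Cᵢ − dbᵢ) over the *reported* species, with **no
renormalisation** of the (typically ~97 %) percent total. This convention
reproduces the published ECN table to the printed 2 decimals (±0.01 on the
rounded value) for 14 of the 15 conditions with a published FA row;
renormalising to 100 % reproduces none of them. The single exception — the
32-h untreated control, computed 16.19 vs printed 16.23 — is not derivable
from the printed FA row under any convention and is asserted as a
documented deviation. Presentation rounding is half-away-from-zero at 2
decimals, matching the published table precision.

FA codes follow lipid shorthand `C<carbons>:<double_bonds>` with an
optional positional suffix (`C18:3n3`); counts come from the stem only, so
no lookup table is needed. Classes: SFA db = 0, MUFA db = 1, PUFA db ≥ 2,
UFA = MUFA + PUFA. Degradation rate is (initial − final)/initial × 100 and
may be negative (growth).

TPC trends are plain OLS lines per treatment; the waste point solves the
line for a threshold (default 27 %, the Chinese regulatory ceiling). A
non-rising trend has no crossing and raises; an intercept already at or
above the threshold yields a non-positive time flagged `already_exceeded`.

## Correlations

One observation = one (treatment × time) condition, all treatments pooled
(25 conditions in the default design; the observation unit is recorded in
the result's `n`). Pearson r with two-sided t-distribution p-values
(n − 2 df), flagged at 0.05/0.01, no multiple-testing correction. A
zero-variance variable raises a named `ConstantVariableWarning` and its
row/column becomes NaN; other entries are unaffected.

## Synthetic-data generator

Defaults are the published study conditions, chosen once:

| parameter | default | rationale |
| --- | --- | --- |
| treatments | 5, with the published b(t_P), a(b) and TPC(t_P) lines as truth | the study's own regression equations |
| time points | 0, 8, 16, 24, 32 h | the sampling schedule |
| temperature grid | 60–110 °C, step 5 (11 points) | the sweep range; the source never states its point count, 5 °C spacing is a realistic ramp-log density |
| log_noise_sd | 0.01 | ±0.01 dispersion of the published fitted parameters and fitted R² ≥ 0.998 imply ~1 % multiplicative viscosity error |
| tpc_noise_sd | 1.0 % | published TPC parity residuals ≲ 2 % and instrument deviation ±0.5 % |
| pufa_decay_rate | 0.005 /h | gives ≈18 % PUFA loss over 32 h, the untreated-control value (treatment range 13.8–18.9 %) |
| FA baseline | the fresh-oil composition | shared 0-h row of all treatments |

Noise on viscosity is Gaussian on ln μ — multiplicative on μ, positive by
construction, and on the scale the models are fit on. PUFA decay is a
first-order surrogate, faster with more double bonds (factor
exp(−k·t_P·(db−1))), with lost mass redistributed over saturates and
monounsaturates proportionally to their shares; this conserves total mass
to 10⁻⁹ and makes PUFA strictly decreasing and ECN strictly increasing, as
observed. Each (treatment, time point) draws from its own substream of one
explicit seed (`numpy` `SeedSequence` spawn keys), so regeneration is
bit-identical and independent of iteration order.

What the generator does **not** emulate: replicate triplicates and
instrument-specific error models, chemical kinetics beyond the first-order
surrogate, non-Newtonian behaviour, and any treatment effect on the FA
trajectory (all treatments share one decay rate by default). Passing tests
on synthetic data therefore demonstrate the pipeline's correctness and
statistical behaviour under the stated noise model, not the chemistry of a
particular oil.

### A limitation of the published coefficients

The published a(b) line for the 400 mg/kg treatment (slope −42.02,
intercept −1.55) is internally inconsistent with that treatment's published
per-timepoint parameters: it implies a(0 h) ≈ 6.69 where 6.32 was printed.
Synthetic data generated from the published lines therefore gives that
treatment a systematically offset viscosity level, which dilutes the
*pooled* TPC–viscosity correlation (to ~0.7) even though the link is
near-perfect (> 0.98) within every treatment. The correlation checks
assert pooled sign and significance plus per-treatment strength.

## Test and fixture conventions

Packaged fixtures transcribe the published tables as printed; their known
internal inconsistencies (the 32-h control ECN cell; the 32-h CA-2 TPC
value required to reproduce that treatment's published trend line) are
listed in `src/oilcascade/fixtures/README.md` and asserted as documented
deviations. Problem sizes in the test suite — 11-point sweeps, 25-condition
studies, 200–500 Monte-Carlo replicates — match the study design while
keeping the whole suite in a few seconds. Fit oracles in the tests are
hand-assembled normal equations and the covariance formula, independent of
the scipy/statsmodels paths the implementation uses.

CSV I/O writes floats via `repr` and reads with round-trip float parsing,
so a write/read cycle is bit-identical; readers canonicalise row order by
grouping and sorting, so reader output is independent of input row order.
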