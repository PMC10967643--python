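# oilcascade

Stability modelling for thermally degraded frying oils. The package targets
food-lipid researchers and quality-control engineers who track how a
vegetable oil — here rapeseed oil, with or without antioxidant dosing
(carnosic acid, TBHQ) — deteriorates during prolonged heating at frying
temperature, and who want to forecast that deterioration from a handful of
early measurements.

## The model

During heating at 180 °C, three degradation markers are measured every 8 h:
viscosity sweeps μ(T) over 60–110 °C, fatty-acid (FA) compositions, and
total polar compounds (TPC, %). The package chains these into a predictive
cascade:

1. **Viscosity–temperature law.** Each sweep is fit with the Lioumbas form

   ln μ = a + b (ln T)²,  T in °C,

   against the classical Arrhenius form ln μ = ln μ₀ + Eₐ/(R·T_K) as the
   comparison model. On frying-oil sweeps the Lioumbas fit is near-exact
   (R² ≥ 0.998) and is carried forward.

2. **The degradation cascade.** The fitted b falls linearly with processing
   time t_P, and a falls linearly with b. Composing the two trends with the
   Lioumbas law yields a forecast μ(t_P, T) from processing time and
   temperature alone; parity analysis (residual and deviation% against
   observations) quantifies its accuracy. Alternatively b can be regressed
   on the oil's chemistry as a plane b = β₀ + β₁·ECN + β₂·TPC.

3. **Chemistry.** FA profiles are aggregated into SFA/MUFA/PUFA classes,
   and summarised by the effective carbon number

   ECN = Σᵢ (Pᵢ/100)(Cᵢ − dbᵢ),

   which rises as oxidation consumes double bonds. Degradation rates
   (percent loss of PUFA, of linolenic acid, …) compare any two time
   points.

4. **TPC trends and waste point.** TPC grows linearly in t_P; solving the
   fitted line for the regulatory 27 % ceiling gives the predicted waste
   point — the time at which the oil must be discarded.

5. **Correlations.** A Pearson matrix with t-test significance flags links
   all markers (a, b, μ₀, Eₐ, ECN, TPC, t_P, viscosity at 60/100 °C) across
   the pooled (treatment × time) conditions.

A synthetic-data generator (`oilcascade.synthetic_data`) emulates complete
studies with the published design as its default truth, so every stage is
testable end to end.

## Worked example

```python
import oilcascade as oc

profiles = {p.sample_id: p for p in oc.load_fixture_fatty_acids()}
print("ECN(CA-7, 16 h) =", f"{oc.compute_ecn(profiles['CA-7-16']).rounded:.2f}")

c0 = oc.aggregate_fa_classes(profiles["CA-7-0"])
c32 = oc.aggregate_fa_classes(profiles["CA-7-32"])
print(f"PUFA loss over 32 h: {oc.degradation_rate(c0.pufa, c32.pufa):.2f} %")

tpc = {s.treatment: s for s in oc.load_fixture_tpc()}
for name in ("C", "CA-7"):
    trend = oc.fit_tpc_trend(tpc[name])
    wp = oc.waste_point(trend)
    print(f"{name}: TPC = {trend.slope:.4f} t_P + {trend.intercept:.1f} "
          f"(r2 = {trend.r2:.3f}); waste point {wp.hours:.1f} h")
```

prints

```
ECN(CA-7, 16 h) = 16.20
PUFA loss over 32 h: 13.84 %
C: TPC = 0.8625 t_P + 5.2 (r2 = 0.959); waste point 25.3 h
CA-7: TPC = 0.5875 t_P + 6.7 (r2 = 0.992); waste point 34.6 h
```

Read: at 700 mg/kg carnosic acid (CA-7) the oil keeps more of its
polyunsaturates (13.8 % lost versus 18.1 % untreated), its polar compounds
accumulate at 0.59 %/h instead of 0.86 %/h, and its usable life before the
27 % regulatory ceiling stretches from ~25 h to ~35 h.

The same pipeline runs from the shell on any dataset directory:

```sh
oilcascade simulate --seed 1 -o study/     # or your own three CSVs
oilcascade report study/ -o report/
```

which writes the fitted viscosity parameters, composition table, TPC
trends with waste points, cascade parity records and correlation matrices
as CSVs.

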