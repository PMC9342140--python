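# cvrmodel

A cardiovascular response model for computational physiology: given an
individual's age, mass, height, sex and maximal oxygen uptake (V̇o2max), it
predicts heart rate (HR), stroke volume (SV), cardiac output (CO),
arteriovenous oxygen difference (AVO2diff) and the core/skin/muscle
blood-flow split, at rest and across exercise intensities, under heat strain,
dehydration and altitude — and adjudicates whether a workload is aerobically
sustainable. It is aimed at exercise physiologists, thermal-ergonomics and
occupational-safety modellers, and as a cardiac submodel for multisegmental
thermoregulation simulators.

## The model

Everything rests on two identities: the Fick principle
`V̇o2 = CO · AVO2diff` and the cardiac-output principle `CO = SV · HR`.

**Basic layer** (cool, hydrated, sea level). Regression constants from
aggregated population data anchor the endpoints —
`SVmax = 40.59 + 24.81·V̇o2max` (mL·beat⁻¹), `SVrest = 85.1`,
`HRmax = 208 − 0.7·age`, `HRrest = 90.93 − 0.64·V̇o2max/mass·1000` — with
resting V̇o2 from Mifflin–St Jeor energy expenditure converted through the
Weir oxygen energy equivalent. HR and CO interpolate linearly over the V̇o2
reserve fraction `F = (V̇o2 − V̇o2rest)/(V̇o2max − V̇o2rest)`; SV = CO/HR·1000
follows.

**Altitude.** Oxygen extraction at rest and maximum is attenuated by the
curvilinear decline `0.007·km² + 0.03·km` (Fulco-style fit, 0–8 km);
maintaining a given V̇o2 then requires `CO = V̇o2/AVO2diff(altitude)`, and
the attainable V̇o2max falls proportionally.

**Heat and dehydration.** Body-temperature elevation
`ΔT_body = 0.2·T_skin + 0.8·T_core − 36.54` (°C, floored at 0) and
dehydration `D` (% body mass) combine into a cardiac heat strain index,
either additive `0.5·D + 0.5·ΔT` (default) or synergistic
`0.433·D + 0.091·ΔT + 0.125·D·ΔT`. Per index unit: resting SV +2.5 %,
resting CO +31.3 %, maximal SV and CO −8.3 %, maximal HR unchanged. The
strained response re-interpolates between the modulated endpoints, and
`V̇o2max(env) = AVO2diffmax(altitude) · COmax(heat)`.

**Blood-flow partition.** Core flow is CO times
`0.86·FCO² − 1.79·FCO + 1.06` where FCO is CO over the strained maximal CO;
skin flow is 5 % of basic resting CO plus the heat-excess CO; muscle flow is
the remainder, giving a workload-dependent active-muscle extraction
`(V̇o2 − V̇o2rest)/MusBF`.

**Task failure.** A timestep is infeasible when required V̇o2 exceeds the
environment-limited V̇o2max, predicted HR exceeds HRmax (or a user ceiling),
or the flow partition leaves the model's domain.

## Worked example

```python
from cvrmodel import (ThermalState, cardiac_output_at_altitude, chsi,
                      derive_basic_cardio, exercise_response_env,
                      modulate_cardio, reference_profile, reserve_fraction_env)

b = derive_basic_cardio(reference_profile("fit"))  # 25 yr, 75 kg, 175 cm, 4.0 L/min
index = chsi(ThermalState(t_body=39.0, dehydration_pct=2.0), "additive")
env = modulate_cardio(b, index)
co_demand = cardiac_output_at_altitude(b, 2.0, 0.0)
f = reserve_fraction_env(b, env, co_demand)
hr, co, sv = exercise_response_env(b, env, f)
print(round(index.value, 2), round(hr, 1), round(co, 2), round(sv, 1))
```

prints `2.23 151.1 16.34 108.2`: at a fixed 2 L·min⁻¹ workload, a 39 °C mean
body temperature with 2 % dehydration gives a heat strain index of 2.23 and
drives HR from a thermoneutral ~119 up to ~151 beats·min⁻¹ while SV falls
from ~126 to ~108 mL — cardiovascular drift at constant oxygen demand.

The `examples/` scripts walk through each capability (basic profile,
altitude, heat strain, graded-test simulation with blood flows and task
failure, validation harness); each prints its numbers with a one-line
interpretation. A thin CLI mirrors the library:

```sh
cvr fixture --name graded-fit-heated --out scenario.csv
cvr simulate --profile profile.yaml --scenario scenario.csv --out results.csv
cvr validate --pairs pairs.csv
```

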