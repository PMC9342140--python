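# Methods

## Model structure and assumptions

The model is purely algebraic: every output at a timestep is a closed-form
function of the individual's constants and that timestep's environment
(altitude, mean body temperature, dehydration) plus one carried quantity,
progressive dehydration. There is no differential state, no acclimation, no
fatigue and no pacing; a scenario is a sequence of independent evaluations.

The basic layer assumes HR and CO are linear in the V̇o2 reserve fraction
between regression-anchored rest and max endpoints, which forces SV =
CO/HR·1000 into a mildly nonlinear rise that meets the measured resting
(85.1 mL·beat⁻¹) and maximal (40.59 + 24.81·V̇o2max) values exactly at the
endpoints. Arranging the linearity on HR and CO (rather than SV) keeps the
Fick and cardiac-output identities exactly consistent at every intensity.

Altitude acts only on oxygen extraction. Both the resting and maximal
AVO2diff are scaled by (1 − 0.007·km² − 0.03·km); because the two endpoints
share one attenuation factor, the endpoint interpolation collapses
algebraically to `AVO2diff(alt) = (1 − att)·AVO2diff(sea)`, and the
compensatory cardiac output is `CO_sea(V̇o2)/(1 − att)`. Maximal CO is taken
as altitude-invariant. The supported range is 0–8 km, the domain of the
underlying meta-analytic fit; beyond it the quadratic heads toward full
attenuation and inputs are rejected rather than extrapolated.

Heat and dehydration act through a single dimensionless index on a
°C-equivalent scale (CHSI). Two variants are provided; the additive form is
the default because it generalises better to heterogeneous (not
endurance-trained) populations. The index multiplies fixed sensitivities:
+2.5 %/unit on resting SV, +31.3 %/unit on resting CO, −8.3 %/unit on both
maximal SV and CO. Maximal HR is deliberately left unmodulated: equal
maximal SV and CO sensitivities mean the maximal decline is wholly
inotropic, while the diverging resting sensitivities force the compensatory
resting tachycardia (cardiovascular drift) that the strained resting HR
`CO_rest(env)/SV_rest(env)·1000` expresses.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| `rer` | 0.7 | – | resting respiratory exchange ratio for the Weir conversion |
| `vo2rest_divisor` | `weir` | – | `weir` = 3.941 + 1.106·RER kcal·L⁻¹ (≈0.25 L·min⁻¹ resting V̇o2 for 75 kg); `literal` = 5.05·RER (≈0.34 L·min⁻¹) |
| `chsi_variant` | `additive` | – | `synergistic` fits endurance-trained responses |
| `calibration` | `published` | – | `adjusted` scales heat sensitivities ×1.5 and raises the resting-HR intercept to 100.93 — an exploratory recalibration that removes a systematic HR underestimate |
| `mass_loss_mode` | `total` | – | mass-loss column = final loss, interpolated linearly over exercise time; `cumulative` = per-row trajectory |
| `hr_ceiling` | none | beats·min⁻¹ | occupational/work-tolerability HR limit |
| T_body reference | 36.54 | °C | thermoneutral mean body temperature; ΔT_body floored at 0 |

The CHSI is not capped: the 3.9 anchor of its scaling is documented but no
saturation is applied, so very severe combined strain extrapolates beyond the
fitted range (and eventually trips the domain flags).

## What the fixture scenarios emulate — and what they do not

`fixture_graded_test` reproduces an incremental test to exhaustion: rest,
then nine 2-min steps at 20–100 % of basic V̇o2max, with the environment
(mean body temperature, final sweat loss, altitude) held constant per
preset (thermoneutral 36.6 °C/0.25 kg; heated 39 °C/1.5 kg; 5 km altitude).
`fixture_rest_exercise` emits 30-min rest + 60-min exercise protocols at
5-min resolution with linear body-temperature ramps, including 4-km
protocols at absolute vs. altitude-relative workloads (the 4-km level is the
equivalent of breathing 12.7 % O2). These are idealised inputs: real tests
have nonlinear temperature kinetics, inter-individual sweat-rate variation
and measurement noise, none of which the fixtures carry. Passing tests on
them therefore demonstrates internal correctness and the documented
qualitative behaviours, not field accuracy; quantitative validation against
measured heart rate requires user-supplied data through
`regress_predicted_vs_measured`. The published validation statistics were
obtained on datasets that are not redistributable, so the harness is
exercised in-tree only on synthetic pairs with known slope/intercept.

## Numerical choices

- Units are fixed (SV mL·beat⁻¹, CO L·min⁻¹, extraction L·L⁻¹); every
  conversion is an explicit ×1000 or ÷1000, including the one the resting-HR
  quotient `CO_rest(env)/SV_rest(env)` requires.
- Feasibility comparisons use a 1e−9 relative tolerance and run in fixed
  order: oxygen demand, HR against HRmax, user HR ceiling, then domain
  flags; the first violation names the limiting factor.
- Reserve fractions above 1 are never clamped anywhere in the chain; rows
  are computed unclamped and flagged, and the summary reports the first
  failure time, preserving full diagnostic traces.
- Negative compartment flows (possible under extreme heat strain, when the
  strained CO drops below the altitude-demanded CO or the core quadratic
  claims more than is available) are reported as-is with `domain_ok=False`;
  clamping would silently break flow conservation, which is asserted to
  1e−12 at every row.
- The core-flow quadratic is left unclamped at low relative demand (its
  FCO → 0 extrapolation exceeds 1), since resting demand in practice sits
  near FCO ≈ 0.2.
- Active-muscle extraction at exactly resting V̇o2 is defined as 0; if
  muscle flow is simultaneously non-positive the row is flagged instead.
- Dehydration accrues only over exercise intervals, is held (never reset)
  through rest phases, and saturates at the stated total loss.

## Design choices that were genuinely open

- The printed resting-V̇o2 conversion is ambiguous; both readings are
  implemented behind `vo2rest_divisor`, defaulting to the Weir form because
  it yields a physiologically plausible resting V̇o2 (≈3.4 mL·kg⁻¹·min⁻¹).
- The combined-strain reserve fraction references the *basic* resting CO,
  not the heat-elevated one, in both numerator and denominator — kept as
  the model defines it despite the naming asymmetry.
- Fractional workloads are interpreted against basic V̇o2max by default
  (the graded-test convention); `workload_relative_to_env=True` switches to
  the attenuated maximum for relative-workload protocols.
- Heat-modulated quantities carry no altitude term; altitude enters the
  combined response only via the compensatory CO in the reserve fraction
  and the attenuated extraction in the V̇o2max product. This is a property
  of the model, preserved as such.

## Known limitations

- The reserve fraction does not reach exactly 1 at the environment-limited
  V̇o2max: because the fraction is built from the altitude-only CO against
  the heat-only maximal CO with a basic resting origin, at the nominal cap
  it evaluates slightly above 1 (e.g. 1.04 at heat-strain index 2.23, 1.07
  at 5 km). Predicted HR then crosses HRmax marginally before oxygen demand
  crosses the cap, so task failure can be declared at ~97 % of the nominal
  environment-limited maximum. This is an internal property of the published
  equation set, reproduced deliberately rather than patched.
- Coefficients are taken as printed; the meta-analytic refits that produced
  them are out of scope, as are acclimation status, lactate threshold,
  critical power, V̇o2 slow-component and pacing/time-to-exhaustion
  modelling.
- Skin blood flow is a direct value substitution here; when coupling to a
  thermoregulation model it is better treated as a constraint, which is why
  the per-row output table exposes it.
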