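# Methods

## Model structure

The model tracks 25 concentrations: 11 hepatocyte metabolites, and 5
metabolites plus insulin and glucagon in each of two blood compartments
(hepatic and systemic).  All concentrations are μM (μmol/L) except the
hormones, which are dimensionless multiples of their basal fasted level;
rates are μM/s; time is integrated in seconds and reported in hours, with
t = 0 ≡ 08:00.

Hepatocyte reactions use modified Michaelis–Menten/Hill kinetics: each
rate is `V · Π saturation(S_i) · Π (1 − β·X_j/(Ki_j + X_j))`, where the
saturation factors cover substrates and clamped cofactor pools (ATP, ADP,
ATP-Mg²⁻, GTP, NAD⁺/NADH, Pi are held constant — the model provides no
energy-balance ODEs, and treating them as regulatory context rather than
state keeps the 25-variable accounting to metabolites and hormones).
Because every β lies in [0, 1], all rates are non-negative for any
non-negative state, which is the basis of the trajectory non-negativity
property.

Membrane transport between hepatic blood and hepatocytes uses the altered
Michaelis–Menten exchange form `V·(S_out − S_in)/(Km + S_out + S_in)`
(antisymmetric, zero at equal concentrations) plus unidirectional carrier
pumps for the hexoses; fructose rides GLUT2 and GLUT5, with GLUT2 given
the lower pump Km (higher affinity).  Fatty-acid uptake adds an active
term damped by hepatic-blood insulin; triglyceride exchange scales the
hepatocyte pool by `TG_ref` (liver TG is stored at roughly an order of
magnitude above blood TG) and subtracts a saturable hepatic export flux
(the VLDL route).  The hepatic-blood equations lose `T · R_HE` (R_HE = 4,
the hepatocyte-to-hepatic-blood volume ratio) for every unit the
hepatocytes gain.

Circulation transfers each blood species at `R_BS·(C_SBC − C_SHB)/R_RL`
on the hepatic side.  The systemic-side term is the same expression
divided by a further R_RL, which is the unique choice that conserves
volume-weighted moles given V_liver = 0.8 L and V_body = 5 L
(R_RL = (5 − 0.8)/0.8 = 5.25; the registry validates this identity at
load time).  R_BS defaults to 1/60 s⁻¹ — one full circulation per
minute — and is an ordinary overridable parameter.

## Hormone and periphery closures

The insulin/glucagon and rest-of-body ("periphery") sub-models are this
package's own reconstruction, with all constants tagged
`provenance: reconstructed`:

* Systemic insulin is secreted along a rising Hill function of systemic
  glucose (exponent 4) around a glucose setpoint (default 1,200 μM) and
  cleared first-order; glucagon mirrors it with the falling Hill
  function.  Secretion is normalised so that glucose at the setpoint with
  both hormones at 1.0 is an exact fixed point.  Hepatic-blood hormones
  simply ride the circulation.  In a fasted state glucose falls to zero,
  insulin decays to 0 and glucagon settles at twice basal — the model's
  fasted equilibrium.
* Periphery USE terms are Michaelis–Menten drains on systemic glucose
  (insulin-stimulated — this produces the blunting of glucose peaks above
  the setpoint), fatty acids and TG.  The adipose release terms UP_FA and
  UP_TG are suppressed by insulin and, in this implementation, gated by
  systemic glucose availability.  The gate is required for consistency:
  the systemic glucose balance subtracts UP_FA and UP_TG (adipose builds
  its exported lipid from circulating glucose), so without the gate the
  fasted state would drive glucose negative.  With it, all closure fluxes
  vanish at zero substrate and the fasted equilibrium is well defined.

## Dietary forcing

A meal of G grams carbohydrate (fructose fraction f) is absorbed into the
systemic blood as `v_input·sin⁶(π/4·h)` over a 4-h window.  The raw sin⁶
function is periodic, so it is windowed to the three declared meals
(08:00, 12:00, 16:00) — a 24-h day contains exactly three pulses and no
input overnight.  The amplitude uses the mean of sin⁶ over its period,
5/16: `v_input = dose_μM/(5/16 · 14,400 s)`, where
`dose_μM = f·G/180.156 g mol⁻¹ · 10⁶ / 4.2 L`.  The distribution volume
defaults to the systemic blood volume (V_body − V_liver = 4.2 L),
matching the circulation volume convention, and meals enter the systemic
(not portal) blood as the compartment equations prescribe.  A 100-g
pure-fructose meal therefore peaks at ≈ 29.4 μM/s.

## Parameters

The registry holds ~128 named constants in
`src/fructolyse/data/default_parameters.yaml`, each with value, units and
a provenance tag.  The circulation constants (R_HE, R_BS, R_RL, V_body,
V_liver) and the hormone setpoint carry `provenance: SM1` (published
values); everything else is `reconstructed`.  Loading is closed-world —
a file missing any identifier used by a rate law fails with the name —
and validation enforces positivity of V/Km classes, β ∈ [0, 1] and Hill
exponents ≥ 1.

The reconstructed kinetic defaults were chosen to place the model in a
regime where its qualitative behaviour is structurally robust rather than
knife-edge:

* **Effective Km values of the chain enzymes are mM-scale** (e.g.
  Km_F1P = 8 mM, Km_GA3P = 15 mM, Km_Pyr = 15 mM).  These are lumped,
  effective constants for multi-step segments, not single-enzyme
  microscopic Kms.  They make the intermediate pools large and slow
  (minutes-to-hours transit per stage), so concentrations vary smoothly
  across the meal cycle instead of collapsing between meals.  With small
  (μM-scale) Kms the pools empty within minutes of each absorption
  window, and 12-h endpoint comparisons become dominated by phase shifts
  of near-discontinuous trajectories — small parameter changes then move
  endpoints in physically uninformative directions.
* **Every chain stage is partially saturated** at the study workloads
  (operating at roughly 40–80 % of capacity), so each rate constant holds
  genuine flux control: speeding any forward step moves more of the day's
  carbon into triglyceride by the 12-h endpoint, while the gluconeogenic
  recycler (PEPCK), β-oxidation and lipolysis act in the TG-lowering
  direction.  Capacities exceed the pure-fructose peak loads, so a larger
  dose yields proportionally more lipid within the day (the 150 g vs
  100 g steatosis setup).
* **Near-saturated small-Km factors** are used where a regulatory factor
  should act as an on/off context rather than a marginal control channel:
  the TG-synthesis glycerol-backbone factor (Km = 2 μM — the backbone is
  never limiting when any triose is present), the β-oxidation fatty-acid
  saturation (Km = 5 μM — a fixed background drain), and the
  F1P/PPARα suppression of β-oxidation (ki = 30 μM — fully engaged on any
  fructose-containing diet, released on pure glucose).

## Stoichiometry modes and the carbon audit

The published hepatocyte ODE table omits three terms that the reaction
stoichiometries imply: the TG-synthesis, PFK and FBPase contributions to
dGA3P/dt, and the lipolysis glyceraldehyde return to dGA/dt.  The
simulator ships both readings: `stoichiometry_mode="paper-faithful"`
(default) reproduces the table as printed; `"carbon-consistent"` restores
the implied terms.

`carbon_audit` checks each reaction's carbon balance (weights: hexoses
and hexose phosphates 6, trioses 3, pyruvate 3, acetyl-CoA 2, palmitate
16, TG 51) at the reaction level: FAS consumes 8 acetyl-CoA per
palmitate, TGS condenses 3 palmitate + 1 triose backbone, FBP/PFK
interconvert one hexose phosphate with two trioses.  Expected non-zero
residuals are pyruvate oxidation (−1 carbon per event, the CO₂ boundary)
and, in paper-faithful mode only, lipolysis (−3, the unreturned glycerol
backbone).

## Numerical choices

* Integration: `scipy.integrate.solve_ivp` with LSODA (stiff-capable),
  rtol 1e-8 / atol 1e-10, sampled on a fixed 1-min reporting grid.
  Halving both tolerances moves 12-h endpoints by < 0.5 % (checked in the
  suite; measured ≈ 2e-9 relative).
* Negative concentrations are never clipped; rate-law *arguments* are
  floored at zero inside the RHS so the solver may take transiently
  signed steps, but a genuine stoichiometry error would surface as a
  negative trajectory and fail the non-negativity test (tolerance −1e-6
  relative to each species' maximum).
* Baseline: scenarios start from the 08:00 state of the daily periodic
  orbit, found by integrating repeated identical mixed-diet days from a
  built-in cold start until the day-over-day maximum relative change is
  < 0.1 % (converges in ≈ 4 days; cap 30).  The fasted equilibrium is
  cross-checked by Newton root-finding against long integration.
* Endpoints: "12-h endpoint" means the state at t = 12 h (20:00) exactly;
  sensitivity deltas are differences of two full simulations sharing the
  initial state and solver settings.  Everything is deterministic — no
  randomness anywhere in the model.
* Scenario problem sizes: one 12-h simulation takes well under a second;
  the full 23-simulation OAT sweep with run-in completes in ≈ 15 s.

## What the model does and does not represent

The simulator reproduces the fed-day dynamics of a healthy adult liver on
carbohydrate-only diets: the ordering of lipid outcomes across
fructose/mixed/glucose meals, the direction and ranking of rate-constant
sensitivities, and the graded response to fructokinase suppression.  It
is not a fitted patient model.  Known limitations:

* No glycogen storage: overnight, blood glucose and the hepatic G6P pool
  drain to zero rather than being buffered by glycogenolysis, so the
  fasted baseline is emptier than physiology.
* Plasma fructose reaches mM levels after large pure-fructose meals
  because meals enter the systemic blood directly (first-pass portal
  extraction is not modelled, by design of the compartment equations).
* Acute only: a 12-h horizon with identical repeated days; no chronic
  adaptation, no protein/fat intake, no liver zonation, no explicit
  malonyl-CoA/citrate/CO₂ species, pyruvate and lactate pooled.
* Hormone levels are normalised to basal and the glucose setpoint
  (1.2 mM as published) is below the physiological ~5 mM; hormone
  predictions are shapes, not absolute concentrations.
* Cofactor pools are clamped, so energy-state feedback (ATP depletion by
  fructose loading) is represented only through fixed inhibition factors.

Passing the test suite therefore demonstrates internal consistency and
the qualitative structure above under the reconstructed parameter set; it
does not certify quantitative agreement with clinical lipid levels.
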