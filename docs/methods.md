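# Methods

`anmbrsim` is a desk-scale simulation environment for an anaerobic membrane
bioreactor (AnMBR) dosed with a cationic flux enhancer (FE). It couples
three submodels — biochemistry/flocculation, membrane cake filtration, and
standardized sludge-filterability prediction — and uses the coupled model to
compare feedback and feedforward FE-dosing control tools under disturbances.
This note records the model equations in prose, the default parameters and
why they were chosen, what the synthetic influent does and does not emulate,
and the numerical choices.

## Biochemical–flocculation model

The biochemical core is a modified ADM1 in the common mesophilic benchmark
parameterisation (35 °C), carried in kgCOD m⁻³ (organics), kmolC m⁻³
(inorganic carbon) and kmolN m⁻³ (inorganic nitrogen). Modifications for
the FE-dosed membrane reactor:

* **Decoupled disintegration/hydrolysis.** Influent carbohydrates, proteins
  and lipids hydrolyse directly (first order, 10 d⁻¹). Decayed biomass
  enters a composite pool whose disintegration is the rate-limiting step of
  biomass turnover; its constant defaults to 0.2 d⁻¹ (the slow end of
  literature values for anaerobic disintegration) and is configurable.
* **No ammonia inhibition of acetoclastic methanogenesis** (negligible at
  the pH and nitrogen levels of blackwater AnMBRs).
* **Non-competitive FE inhibition** of acetoclastic uptake,
  `I_fe = 1/(1 + cfe/K_I_fe)` with `K_I_fe = 0.55 kgCOD m⁻³`, set so the
  inhibition stays below 5 % at the upper end of the optimal dosing window
  (27 mgCOD L⁻¹). Whether the argument is total or only dissolved FE is a
  config switch (total by default, the conservative choice).
* **pH as an input** — no ion/charge balance is solved; the empirical
  lower-side pH inhibition terms read the supplied pH directly.
* **Three extra components**: colloidal inerts `C_I`, bulk FE `S_fe`,
  adsorbed FE `X_fe`. A small share (5 %) of disintegrating decayed biomass
  reports to `C_I`, giving the reactor a continuous internal colloid source
  on top of the influent one.

Inorganic carbon and nitrogen stoichiometry is closed per process from the
elemental contents of the organic components, so every Petersen column
conserves COD, C and N exactly (asserted numerically in the tests).

**FE adsorption.** The cationic polymer adsorbs onto particulate material
following a pseudo-first-order approach (`k_ads = 20 d⁻¹`, i.e. ~1 h time
scale, typical of polymer adsorption in batch flocculation tests) toward a
Langmuir equilibrium with capacity `q_m_ads = 5·10⁻³ kgCOD kg⁻¹` and
affinity `K_L_ads = 300 m³ kgCOD⁻¹` (strong binding: at reactor conditions
>90 % of the FE inventory is adsorbed). The equilibrium adsorbed
concentration solves the isotherm combined with the FE mass balance — a
quadratic whose physical root is taken in closed form.

**Flocculation.** Colloid removal is slaved to net adsorption:
`ρ_floc = Y_fe_C · ρ_ads · w`, with `Y_fe_C = 40 kgCOD kgCOD⁻¹` and an
availability factor `w` that saturates on the colloid pool during
flocculation and on the particulate-inert pool during deflocculation
(regulariser 10⁻⁶ kgCOD m⁻³), so neither pool can be driven negative. When
bulk FE is lost with the permeate the equilibrium shifts back, FE desorbs
(`ρ_ads < 0`) and material deflocculates — the mechanism behind the slow
post-dosing colloid creep the integrated model reproduces.

**Floc size.** The mean particle diameter follows
`d(dp)/dt = k_floc_fe · dX_fe/dt + (target − dp) · k_floc`, with an
immediate size gain on adsorption (`k_floc_fe = 2.3·10⁻³ m per kgCOD m⁻³`,
i.e. the setpoint dose of ~9 mgCOD L⁻¹ lifts dp by ~20 µm) and relaxation
at `k_floc = 0.34 d⁻¹`. Two relaxation targets are available: a fixed
stable diameter `dp_st = 45 µm`, or (default, used in the control studies)
a target proportional to the FE inventory per unit suspended material,
`Y_floc_fe · cfe/(cX+cC) · dp_st`. The proportionality is anchored by
self-consistency: at the setpoint FE inventory (8.7·10⁻³ kgCOD m⁻³ in
~10 kg m⁻³ of suspended material) the target equals `dp_st`, giving
`Y_floc_fe = 1155 kg kgCOD⁻¹`; richer dosing grows the flocs further,
an FE-free reactor relaxes toward the unflocculated primary-particle
scale. A 10 µm floor (primary particles) and a 0.5 mm cap (overdosed
macro-flocs) bound the state.

**Transport.** All soluble components (including bulk FE) pass the
membrane; colloids and particulates are fully retained and leave only with
waste sludge, enriched by factors `f_X_ws = 2.0` (particulates) and
`f_C_ws = 0.22` (colloids) relative to bulk — the enrichment implied by a
recorded withdrawal event in which removing 31 % of the volume dropped TSS
by 62 % and submicron COD by 7 %. Gas transfer (H₂, CH₄, CO₂) uses standard
two-film kinetics with an overpressure-driven gas outflow; without an ion
balance, dissolved CO₂ is approximated as a fixed fraction (0.4) of total
inorganic carbon at the operating pH.

## Membrane filtration (reactor side)

TMP follows Darcy's law with resistance in series, `TMP = J·μ·(Rm + ωX·αc)`;
irreversible fouling is neglected (none was observed over two years in the
system the model describes). Permeate viscosity equals pure-water viscosity
(cubic-in-θ correlation, K input); mixed-liquor viscosity is
`a·μw·exp(b·TSS)` with `a = 1.05`, `b = 0.08 m³ kg⁻¹`; the apparent shear
rate defaults to the Camp form `G = √(ρ g u/μL)` (the plain ratio is
selectable — the velocity-gradient form is standard in MBR fouling models
and gives physically typical magnitudes).

**Deposition submodels.** Drag-only attachment `J20·c` with gas-sparging
scouring detachment saturating in cake mass (variants differing in a
sigmoid scouring-inhibition factor: full, colloid-extended, or unity), and
a drag-vs-lift force balance with shear erosion. Attachment acts only while
filtering; detachment always. Filtration/relaxation cycling (default
300 s / 60 s — not stated for the original system, configurable) is
integrated with an explicit midpoint scheme at ≤10 s steps, which resolves
the operational stages.

**Specific cake resistance (SCR).** Seven variants: Carman–Kozeny
(`∝ (1−ε)/(ρ dp² ε³)`), a colloid-porosity form without dp dependence, and
empirical exponential-ratio (Cho-type) forms; compressible versions apply
`α/(1 − J μ ωX α/Pa)` with `Pa = 500 kPa` the pressure doubling the
resistance — a deliberately high default, since anaerobic sludge cakes are
mostly non-compressible. Cake porosity decreases linearly in the colloid-to-particulate
deposit ratio and is floored at 0.01 to prevent the ε⁻³ blow-up; the
compression transform raises a dedicated error when its denominator falls
below 0.05 (the pole is physically meaningless). The Carman–Kozeny
coefficient is a lumped value (4.4·10⁶) absorbing floc shape and internal
structure so that the nominal reactor cake (~0.5 kg m⁻²) produces an SCR of
order 10¹³ m kg⁻¹, typical of anaerobic sludge; the classical 180 of a bed
of uniform spheres underestimates sludge-cake SCR by orders of magnitude.

**Fouling rate** is the OLS slope of TMP over one filtration cycle
(Pa s⁻¹; 1 Pa s⁻¹ = 0.6 mbar min⁻¹). Empirical alternatives compute the
fouling rate algebraically from the operating point: exponential
regressions in flux, sparging intensity, particulate/colloidal
concentrations and (optionally) floc size, plus power-law-in-gas-velocity
variants rescaled to match at the mean sparging velocity (0.003 m s⁻¹).
Their coefficients are representative placeholders that the calibration
module refits against data.

## Sludge filterability (ΔR20)

Filterability is expressed as the extra cake resistance after producing
20 L m⁻² of permeate at 60 L m⁻² h⁻¹ (1.67·10⁻⁵ m³ m⁻² s⁻¹) and 1.5 m s⁻¹
crossflow in a standardized side-stream test — 1200 s of continuous
filtration from a clean membrane. The crossflow velocity replaces the
sparging velocity in the deposition kinetics; being three orders of
magnitude larger, it collapses the scouring-inhibition variants to their
simplified form. In addition to the ODE submodels, a dead-end-like
algebraic submodel deposits fixed fractions of the filtered load
(`ωX = f_X_c·VF·cX`, `ωC = f_C_c·VF·cC`). The default filterability model
is this dead-end deposition paired with the colloid-porosity SCR — the
pairing with only moderate sensitivity to the particulate concentration and
no floc-size dependence, which is the observed behaviour of anaerobic
sludge filterability — and a non-compressible cake (the filtration-curve
shape of anaerobic sludges indicates a mostly non-compressible cake).

**Joint calibration of the filterability defaults.** Four defaults were
chosen together, before the control studies, to make the environment
self-consistent with its own setpoints: `f_X_c = 0.26`, `f_C_c = 0.5`,
`k_c = 2.62·10¹⁶ m⁻²`, `Y_fe_C = 40`. They encode three conditions:
(i) the nominal undosed sludge (cX = 9.6 kg m⁻³, cC = 0.45 kg m⁻³) reads
ΔR20 ≈ 13·10¹² m⁻¹, between the undosed and dosed regimes; (ii) raising the
FE inventory to the concentration setpoint 8.7·10⁻³ kgCOD m⁻³ flocculates
enough colloids to land ΔR20 ≈ 10·10¹² m⁻¹ — the defining property of that
setpoint; (iii) the dead-end/colloid-porosity pairing is the least
cX-sensitive of the candidate filterability models (porosity feedback
partially offsets the deposit mass when cX changes at fixed cC), which is
why it is the default.

## Control tools and closed-loop scenario

Five dosing tools (proportional filterability feedback toward
10·10¹² m⁻¹; on/off feedback with an 8–12·10¹² m⁻¹ hysteresis band;
proportional feedback on total FE concentration; feedforward compensation
of waste-sludge FE losses after an initial pulse; feedforward proportional
to influent flow) plus an undosed reference. The influent-proportional
ratio is, by its definition, the dose-to-influent-volume ratio of the
filterability-feedback tool over its first 100 days; the scenario derives
it from that run (flag `derive_Y_fe_inf`), falling back to the configured
constant otherwise. ΔR20 enters the control laws
in units of 10¹² m⁻¹ and the gains produce kgCOD s⁻¹ (converted to
kgCOD d⁻¹ at the module boundary); both conventions are switches. A
proportional TSS loop (gain 0.05 m³ d⁻¹ per kg m⁻³, deliberately slow,
wastage clamped at zero) manipulates the waste flow; the reactor volume is
closed at constant level, the influent making up the balance of permeate,
wastage and FE stock flow (stock strength 30 kgCOD m⁻³).

The synthetic influent emulates blackwater: constant temperature (35 °C),
pH 7.2, flux (1.94·10⁻⁶ m³ m⁻² s⁻¹ ≈ 7 L m⁻² h⁻¹ over 3 m² membrane, i.e.
~0.5 m³ d⁻¹ through a 0.8 m³ reactor), gas sparging 0.003 m s⁻¹, ammonium
and alkalinity; total COD uniform in 6–16 kgCOD m⁻³ and submicron COD
uniform in 0.02–0.09 kgCOD m⁻³, redrawn and held each reporting step, and
fractionated into ADM1 components by configurable ratios. The submicron
range was set so that at nominal wastage the colloid influx roughly equals
the removal the setpoint FE concentration can sustain — the balance implied
by defining that setpoint as the dose achieving target filterability. The
generator does **not** emulate real blackwater's correlated composition
swings, temperature/pH excursions, or sensor noise and dead time (the
ΔR20 "sensor" is a virtual instantaneous evaluation once per reporting
step, although the real test takes 1200 s); conclusions about controller
ranking therefore concern disturbance rejection under idealised
measurement, not sensor-limited performance.

Disturbance protocol (400 days): TSS setpoint steps 9.6 → 5.5 kg m⁻³ on
day 100 and → 16.0 on day 200 (the mean/min/max of the emulated system);
colloid waste-enrichment step 0.22 → 1.0 on day 300 (better mixing before
wastage). FE cost is annualised at 6 € kg⁻¹.

## Numerics

* Biochemistry integrates in days with LSODA (closed-loop runs,
  rtol 10⁻⁶/atol 10⁻⁹, multistep history restarted at each input
  discontinuity) or BDF (single runs, rtol 10⁻⁸/atol 10⁻¹², reporting grid
  0.01 d). State is clamped at zero after each control step; values below
  10⁻²⁰ are flushed to exact zero.
* The closed-loop reporting/control step is 0.1 d — a realistic cadence
  for a 20-minute filterability test — which keeps the six-tool 400-day
  comparison near ten minutes on one core.
* Membrane cycling uses explicit midpoint at ≤10 s. In the closed loop the
  cycle-resolved fouling rate is evaluated every 10th reporting step from
  the cycle-averaged steady cake (bracketed root of attachment =
  detachment, colloid deposit from the linearity of its detachment term)
  followed by one simulated filtration cycle.
* The dead-end ΔR20 model is algebraic in the permeate volume; the virtual
  sensor therefore steps it coarsely, which is exact for that model.
* Langmuir equilibrium: closed-form quadratic root, clipped to
  [0, min(cfe, q_m·cX)]; degenerate inputs (no FE or no adsorbent) return
  zero.
* Morris elementary-effects screening uses r random trajectories on a
  4-level grid with Δ = L/(2(L−1)), effects scaled per unit of the physical
  parameter; deterministic under a fixed seed.
* Least-squares standard errors come from the Gauss–Newton covariance
  `s²(JᵀJ)⁻¹`; structurally insensitive parameters (zero Jacobian column)
  receive infinite standard error and a "poor" quality label
  (< 0.1 good, > 0.5 poor, moderate between).

## Known limitations

* The canonical benchmark ADM1 parameter set stands in for a
  system-specific calibration; absolute dosing masses and costs are
  desk-scale figures, not predictions for any particular plant.
* Colloids are inert only; biodegradable colloidal fractions and
  population-balance particle-size dynamics are out of scope.
* pH prediction, ion balance, irreversible/chemical fouling, backflushing
  and the filterability sensor's dead time are not modelled.
* The compressible SCR variants and the Cho-type forms are computable but
  not part of any default model selection; the force-balance deposition
  submodel deposits orders of magnitude less material than the drag-only
  one and pairs poorly with porosity-sensitive SCR forms at reactor-scale
  cakes (the compression transform then approaches its pole, which raises
  a dedicated error rather than returning NaN).
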