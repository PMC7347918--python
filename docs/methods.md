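# Methods

`dialybind` simulates hemodialysis (HD) of a patient poisoned with a
strongly albumin-bound drug, with or without extracorporeal infusion of a
*binding competitor* — a second drug that shares the toxin's Sudlow site on
albumin, displaces it, and thereby raises the free (dialyzable) fraction in
the extracorporeal circuit. This note records the model, its assumptions,
the defaults, and the numerical choices.

## Model structure

Three coupled sub-models, integrated as one stiff ODE system.

**Binding.** Both drugs bind a single shared site on albumin by mass action,

    P + T ⇌ PT,   K_T = k_on,T / k_off,T
    P + D ⇌ PD,   K_D = k_on,D / k_off,D

with k_on = 1e8 M⁻¹min⁻¹ for every drug and k_off derived from the
affinity. Secondary albumin sites, cooperativity and direct drug–drug
interaction are not modelled. Toxin affinities are recomputed from their
therapeutic binding data (20 mg/L phenytoin 90% bound → 1.555e4 M⁻¹;
12 mg/L carbamazepine 75% bound → 4.90e3 M⁻¹, at 650 µM albumin);
competitor affinities are literature constants (aspirin 1.90e5, ibuprofen
1.76e5 M⁻¹). Equilibria are solved algebraically: single ligand by the
stable quadratic root, two ligands by monotone bracketing on free albumin
in [0, P_tot] — the objective is strictly increasing, so the root is unique
and the solver cannot mis-bracket.

**Patient.** Three well-mixed pools: plasma (3.5 L, 650 µM albumin),
interstitium (14 L, 260 µM albumin), intracellular water (28 L, no
albumin, free drug only). Free drug exchanges plasma↔interstitium with
K_ip = 1200 mL/min and interstitium↔cells with K_ic = 100 mL/min (same for
both drugs, diffusion being size-dominated); protein and complexes stay in
their pool (no lymphatic transport). Endogenous elimination is first order
on *free plasma* drug only, rate λ. Compartment volumes are constant: the
patient is not ultrafiltered, and the infused diluent is removed along the
dialyzer instead.

**Extracorporeal circuit.** Plasma flow Q_pl = Q_blood·(1 − Hct)
(162.5 mL/min at the reference prescription of 250/500 mL/min blood/
dialysate). The competitor (dose dissolved in a diluent volume) is infused
at constant rate Q_D = volume/duration into the arterial line; the
inlet boundary is flow-weighted mixing, with only free competitor present
in the infusate. The tube segment (150 cm × 4 mm line) is a plug-flow
advection–reaction PDE without axial diffusion: re-equilibration toward a
higher free-toxin fraction happens in transit. The counter-current
hollow-fiber dialyzer carries a linearly decreasing plasma flow and a
linearly increasing dialysate flow, the difference being exactly Q_D
(ultrafiltration of the infused volume). Free solutes cross the membrane
diffusively (KoA = 800 mL/min, corrected by the Péclet factor
Pe/(e^Pe − 1), Pe = Q_D(1−σ)/KoA — with Q_D of order 1 mL/min the factor is
≈ 0.999, i.e. nearly pure diffusion) and convectively with σ = 0; protein
species have KoA = 0 and σ = 0.999. Fresh single-pass dialysate enters
drug-free.

## Free half-life calibration

Published half-lives are defined on total serum concentration, but the
model eliminates only free plasma drug. λ is chosen so that, starting from
a fully equilibrated peak, total plasma concentration first halves exactly
at the conventional half-life (event-located crossing, Brent root in λ;
the crossing time is strictly decreasing in λ, so the root is unique).
Calibration peaks: the intoxication concentration for the toxins (70 and
35 mg/L — the "peak concentration" of the patients actually simulated) and
20 / 50 mg/L for aspirin / ibuprofen. With these choices the calibrated
free half-lives are phenytoin 0.996 h, carbamazepine 1.216 h, aspirin
0.174 min, ibuprofen 0.959 min. Binding nonlinearity makes λ weakly
dependent on the chosen peak; the peak is therefore stored per drug and
configurable.

The interstitial albumin level is not a measured input here; 260 µM (40% of
plasma, the typical interstitial-to-plasma albumin ratio) is the default.
The calibrated free half-lives are the most sensitive published quantities
to this choice and are consistent with it to within a few percent, which is
why 40% rather than a 50% guess is the default; it remains a config field.

## Session simulation and treatment-time search

The full coupled system (patient 12 states, tube 16 cells × 5 species,
dialyzer 64 cells × 2 sides × 5 species, plus 8 cumulative bookkeeping
states; 740 states total) is integrated with BDF (rtol 1e−6, atol 1e−9 µM
for sessions; 1e−8/1e−10 for patient-only runs) using a precomputed
Jacobian sparsity pattern. All spatial operators are first-order upwind in
conservative flux form; the scheme is monotone, so concentrations stay
non-negative (asserted, never clipped), and total solute is a *linear*
invariant of the right-hand side, which linear multistep methods preserve
to solver precision — session mass audits close to ~1e−13 relative and
abort the run above 1e−6. The circuit starts primed with drug-free fluid.

Grid defaults n_tube = 16, n_dz = 64: doubling n_dz changes one hour's
removal by well under 0.5%, and the discrete steady-state clearance of an
unbound tracer matches the closed-form counter-current formula
K = Q_p(e^θ−1)/(e^θ−Q_p/Q_d), θ = KoA(1/Q_p−1/Q_d), within 1%
(158.5 mL/min at the reference flows). Fiber geometry (200 µm × 23 cm,
~12 455 fibers for 1.8 m²) only sets residence volumes; perturbing it ±20%
at fixed KoA moves session summaries by < 0.2%.

**Minimal duration.** A treatment duration is acceptable when the
end-of-session total plasma toxin *and* the post-dialytic rebound peak
(patient-only follow-up, default horizon 720 min) are at or below the
maximum therapeutic concentration (MTC; the window's lower bound is
reported but not enforced — ongoing elimination makes it a non-binding
constraint). The infusion rate is recomputed per candidate duration so the
full dose is always delivered. Acceptability is monotone in duration, so
the smallest acceptable point on a 5-min grid is found by bisection;
failure at the 720-min cap is reported as censored, not raised. Rebound
peaks occur ≈ 5 h post-HD, so the minimal durations are identical for
horizons of 360, 720 and 1440 min in both reference scenarios.

Reference results at defaults: phenytoin 70 mg/L needs 480 min of
conventional HD, 345 min with 2000 mg aspirin; carbamazepine 35 mg/L needs
275 min conventional, 240 min with 800 mg ibuprofen. In both infusion runs
the free plasma toxin never exceeds its pre-dialysis value (asserted per
run), and the benefit is larger for the more strongly bound toxin.

## Known limitations

- The competitor half-life sweep recalibrates λ for each swept
  *conventional* half-life. Under that definition the competitor's total
  body burden decays at the conventional rate by construction, so minimal
  duration keeps creeping down (≈ 15 min per half-life doubling) well past
  a 2 h half-life instead of hitting a hard plateau; a plateau appears only
  if the swept value is interpreted directly as the free half-life, which
  would contradict the 20-min base case. The sweep ships with the
  recalibrating semantics and a monotonicity guarantee only.
- Aspirin is modelled as the parent drug with a fixed 20-min half-life; the
  salicylate metabolite (longer-lived, same Sudlow site) is out of scope,
  so the aspirin scenario is conservative.
- No metabolite chains, organ-level PK, intradialytic fluid gain, membrane
  adsorption, or time-varying (optimized) infusion profiles.
- Rinse-back is not modelled: drug held up in the circuit at session end is
  counted as removed from the patient in the audit.
- The therapeutic ranges stored for the competitors are bookkeeping only;
  no pharmacodynamic safety model of the competitor is included.
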