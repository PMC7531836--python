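# Methods

`altcomp` simulates the alternative pathway (AP) of the complement system
as a deterministic reaction network, from the spontaneous "tick-over"
hydrolysis of C3 to the assembly of the membrane attack complex (MAC) on
erythrocyte membranes, and couples pathway output to cell lysis, in-vivo
turnover, clinical biomarkers and anti-C5 pharmacology. This note records
the model, its assumptions, the numerical choices and the known
limitations.

## Model structure

The full network has 97 molecular species and 226 reactions in six blocks:

1. **Fluid phase (reactions 1–36).** Tick-over (C3 → C3(H₂O)), assembly of
   the initial convertase C3(H₂O)Bb via factor B (FB) and factor D (FD),
   the fluid C3 convertase C3bBb with properdin (P) stabilization, a weak
   fluid C5 convertase, terminal complex intermediates up to C5b-7 with
   vitronectin/clusterin scavenging, and the fluid regulators factor H
   (FH), factor I (FI) and soluble CR1. Bimolecular steps follow mass
   action; enzymatic steps (FD cleavage of proconvertases, convertase
   cleavage of C3 and C5, FI cleavage of C3b derivatives) follow
   Michaelis–Menten kinetics `v = kcat·[E]·[S]/(Km+[S])`.
2. **Surface phase (37–111).** Attachment of nascent C3b to the cell
   membrane, the membrane amplification loop (C3bBb_s regenerating
   deposited C3b), C5 convertase assembly (C3bBbC3b), C5 cleavage, release
   and re-insertion of C5b-7, stepwise C9 polymerization to the complete
   18-C9 pore, and the membrane regulators CR1, DAF and CD59 plus
   surface-bound FH.
3. **Lysis (Hill response).** Percent hemolysis
   `H = 100/(1+(MAC50/MAC)^γ)` with γ = 1.60 and MAC50 = 1.15 pores/cell;
   only complete 18-C9 pores count.
4. **Erythrocyte turnover (112–113).** Zero-order production balancing a
   physiological elimination `k_s = ln2/60 d⁻¹`; the total elimination of
   cells and everything bound to them is `k_el,S = k_s + k_H` with
   `k_H = −ln(1−H/100)/τ` evaluated from the instantaneous MAC density
   inside the derivative function.
5. **Protein turnover (114–223).** Zero-order synthesis of 13 plasma
   proteins and 3 membrane regulators; first-order elimination (or
   des-Arg conversion, for the anaphylatoxins) of every species.
6. **Eculizumab (224–226).** Reversible C5 binding (KD 120 pM, on-rate
   20 nM⁻¹d⁻¹), with drug and drug–C5 complex cleared at the antibody's
   14.3-day elimination half-life. Drug-bound C5 takes part in no
   convertase reaction.

All species, including membrane-bound complexes, are tracked as molar
concentrations in the suspension/plasma volume. Per-cell pore counts are
derived as `[MAC]·N_A / (cells per liter)`.

### The unsaturable-membrane convention

Attachment of nascent C3b and insertion of C5b-7 are second-order in the
free species and in a membrane site pool proportional to the cell
concentration with a fixed structural capacity of 3×10⁵ sites per cell.
The pool is not consumed: at lytic pore densities (~1 MAC/cell) occupancy
is negligible against this capacity. The site factor makes deposition
scale with cell density, as in hemolytic assays, while leaving the
attachment rate constant in its published molar units.

### Structural choices inside the fixed reaction listing

* The 60 µs thioester hydrolysis of nascent C3b competes with surface
  attachment as two first-order sinks; the partitioning emerges from rate
  competition, with no explicit partition coefficient.
* The initial convertase C3(H₂O)Bb decays to an inactivated product
  (iC3b + Bb) rather than regenerating C3(H₂O). The listing carries no
  FH/FI control over C3(H₂O) species, and with regeneration the catalytic
  recycling of C3(H₂O) would consume the entire C3 pool at homeostasis;
  decay-with-inactivation lumps the missing fluid regulation into one
  step.
* Properdin stabilization is a duty cycle: P binds convertases and slows
  their decay tenfold while bound, and cycles off at 0.05 s⁻¹. DAF acts by
  occupancy (fast binding at the published 2.53×10¹⁰ M⁻¹s⁻¹, cycling at
  0.5 s⁻¹) plus the published decay of the DAF-bound convertase; CD59
  captures nascent C5b-8/C5b-9 stoichiometrically, competing with C9
  recruitment.

## Parameters

The catalog has 121 entries: 70 kinetic constants, 39 turnover constants
(16 synthesis, 22 elimination, antibody clearance), 2 drug-binding
constants and 10 lysis/biomarker parameters. Each entry carries a
provenance tag:

* `Table1_final` — the eight constants re-estimated in the published
  fitting procedure, stored bit-exact as printed (e.g. nascent-C3b surface
  attachment 2.16×10⁹ M⁻¹s⁻¹, CD59–C5b9 association 6.03×10¹¹ M⁻¹s⁻¹).
* `literature_baseline` — constants carried from the published baseline
  parameterization of AP biochemistry and standard serum concentrations
  (C3 7.1 µM, FB 2.2 µM, FH 3.2 µM, C5 0.37 µM, …; CR1/DAF/CD59 at
  700/3000/25000 copies per healthy human erythrocyte).
* `derived` — quantities computed from others or calibrated within this
  package (below).

Two constants are context-dependent, as the in-vivo parameterization
prescribes: in vivo the tick-over constant is reduced 10²-fold and the
surface-attachment constant 10⁵-fold relative to the (more reactive)
in-vitro setting.

### Calibrated constants

About ten kinetic constants that govern the surface amplification loop are
not printed in the main text (C9 recruitment, C5b-7 insertion, surface C5
convertase assembly and turnover, DAF/properdin cycling, surface FH
binding, the weak fluid C5 convertase). These were calibrated once, by
coordinate search, against the published predictions of the model itself:
the rabbit-cell assay (~100% lysis at 20% serum in 30 min), the single and
pairwise regulator-knockout grid on human cells, and quiescence of intact
serum on autologous cells. They carry `derived` provenance. The resulting
severity ordering

FH_total ≥ FI > CD59+DAF > FH_surface+DAF > CD59 > FH_surface > DAF ≈ CR1 ≈ Vn ≈ Cn ≈ 0

holds with clear margins, and the single knockouts land close to the
published values (CD59 30%, FH-surface 27%, FI ~100%). The *pairwise*
DAF-combination magnitudes are compressed relative to the published grid
(CD59+DAF 36% vs 88%): in this reaction listing DAF-bound convertases
cannot simultaneously be attacked by FH (no ternary complexes), which caps
how much extra lysis DAF removal can add on top of CD59 or FH-surface
suppression. This is a known limitation of the scheme, not of the fit.

### Synthesis rates and τ

Synthesis rates hold the homeostatic plasma levels against both clearance
and baseline tick-over consumption; they are the fixed point of the
healthy steady state (a 1.49× uplift for C3 and 1.07× for FB over the
pure-clearance values — comfortably inside the several-fold synthesis
discrepancies the source model itself reports). Elimination constants use
literature values for C3a/C5a/C3dg and a size-based estimate (hours for
small fragments, days for large proteins) elsewhere; fluid C3b- and
C5b-containing complexes clear at the C3 and C5 rates respectively, and
everything cell-bound clears with the cell.

τ, the scaling constant of the hemolytic elimination rate, is calibrated
(6.5×10⁻³ day) so that the PNH type-3 steady state reproduces the
severe-anemia boundary of the published biomarker table (Hb ≈ 4 g/dL, LDH
≈ 1760 U/L, Hct ≈ 13%). τ is small because sustained in-vivo pore
densities in this parameterization are of order 10⁻³ MAC/cell — far below
the in-vitro lytic range — so the Hill response must be rescaled steeply
to produce clinically realistic elimination rates.

## Scenarios

* **Fluid-phase assays** use reactions 1–36 only, as a closed system;
  purified-protein experiments replace the serum composition entirely.
* **Hemolytic assays** use the AP reactions (1–111) as a closed system;
  serum dilution scales every serum-derived initial concentration; lysed
  cells are *not* removed (the lysis readout is evaluated from the MAC
  density at readout, 30 min by default). Standard conditions: rabbit
  cells 10¹¹ L⁻¹ at 20% serum; human cells 10¹¹ L⁻¹ at 25% serum;
  PNH inhibition assays at 86% (acidified) serum on type-2 cells, with
  acidified-serum activation represented by the in-vitro parameterization
  itself. Knockouts are total; FH suppression can be restricted to the
  surface (zeroing only the FH-to-membrane-C3b association).
* **In-vivo scenarios** use all 226 reactions. Healthy homeostasis is
  computed once (two-stage: biochemistry equilibrated with the hemolytic
  coupling frozen, then with full coupling, then a Newton polish of the
  right-hand side); disease runs start from that state with the membrane
  regulators switched to the PNH phenotype (type 3: absent; type 2: 10%
  of normal, applied to levels and synthesis). Doses are instantaneous
  boluses of `dose/(MW·V_d)` molar.

## Numerics

The timescales span ~10 orders of magnitude (60 µs thioester hydrolysis
against 60-day cell turnover), so the right-hand side is compiled to
vectorized array operations and integrated with BDF using an analytic
Jacobian (including the MAC-density dependence of the elimination rate).
Defaults: rtol 10⁻⁸, atol 10⁻¹⁶ M. In-vivo runs tighten atol to 10⁻²² M
because the physically meaningful MAC scale (10⁻⁶–10⁻³ pores/cell on
8×10⁻¹² M of cells) sits below the default floor; with the looser floor,
integrator noise in the MAC pool feeds back through the elimination rate.
Steady states are found by horizon-length integration (10× the slowest
half-life, extended adaptively) plus a Newton polish, and checked by a
drift criterion: no species may be projected to change by more than 50% of
its level *and* more than 10⁻¹³ M over another full horizon. Negative
excursions are clipped at −atol; rates evaluate on the non-negative part
of the state. Halving both tolerances changes in-vitro endpoints by less
than 10⁻³ relative.

The iterative estimator mirrors the published procedure: every free
parameter is minimized alone by bounded scalar search over ±7 decades on a
log₁₀ scale (absolute tolerance 0.01 on the log coordinate, the analogue
of TolX = 0.01; TolFun enters as the floor below which objective
differences count as converged); only the single best update is applied
per iteration; iteration stops when the objective improves by less than
1%. The full multi-study literature refit is out of scope; the optimizer
is verified on separable toy objectives and on seeded synthetic-data
recovery (Hill steepness within 5%).

## Synthetic data

The fixtures module generates seeded datasets emulating the *structure* of
the digitized literature data (Hill lysis curves, assay time courses,
inhibitor dose-response curves, paired hemoglobin/LDH patient values) with
additive Gaussian noise expressed as a percentage of full scale, clipped
to valid ranges. A packaged synthetic stand-in for the digitized
lysis-versus-pore-density curve ships with the package (generated from the
Hill model with γ = 1.60, MAC50 = 1.15, 2.5% noise, fixed seed; clearly
labeled as synthetic). These fixtures share none of the fitting code they
exercise, but they also carry none of the systematic errors of real
digitized data — passing recovery tests demonstrates estimator
correctness, not robustness to experimental artifacts.

## Known limitations

* Classical and lectin pathways, extravascular hemolysis, transfusions and
  density-dependent C5-convertase kinetics are out of scope.
* PNH type-2 in-vivo severity is under-predicted (hemoglobin near normal):
  10% residual CD59 still captures nearly every nascent pore under the
  steep capture-versus-C9 competition, so the type-2/type-3 contrast is
  sharper than reported clinically. Type 3 reproduces the published
  boundary values.
* The pairwise DAF-combination lysis magnitudes are compressed (see
  above); the severity ordering is unaffected.
* FB is in kinetic excess in this catalog, so rabbit-assay sensitivity to
  FB is weaker than the published ranking suggests; C3, FH and FD dominate
  as published.
* Free hemoglobin released by lysis is not tracked; LDH is an algebraic
  function of hemoglobin with no clearance delay.
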