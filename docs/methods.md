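# Model and methods

## Scope and structure

The package implements a deterministic kinetic ODE model of isolated
heart mitochondria in an assay medium, as a two-compartment system
(matrix and extra-matrix, default volume ratio 10:1) connected by the
inner membrane. Dynamic species (~70, mM) comprise the four central
redox couples (NADH/NAD⁺, NADPH/NADP⁺, GSH/GSSG, Trx(SH)₂/TrxSS — the
thiol couples in both compartments), ROS (O₂·⁻, H₂O₂, both
compartments), the full β-oxidation intermediate set (acyl-, 2-enoyl-,
3-hydroxyacyl- and 3-ketoacyl-CoA at chain lengths C16…C4), the
carnitine shuttle species, ETF-FAD/FADH₂, AcCoA/CoASH, a lumped TCA
span (OAA, CIT, AKG, SUC, MAL, PYR, glutamate), adenine nucleotides and
phosphate, ion baselines, and the membrane potential ΔΨ_m (mV).

Every process is a named rate law with an explicit stoichiometry map;
the ODE right-hand side is assembled as a stoichiometry-weighted sum
with volume-ratio scaling for cross-membrane transport, and
dΔΨ_m/dt = (Σ charge-translocating fluxes)/C_m with C_m = 1.812·10⁻³
mM mV⁻¹. Conservation of every moiety pool (NAD, NADP, CoA, carnitine,
ETF, thiols, matrix adenine nucleotides) therefore holds to machine
precision by construction. Clamped species (protocol boundary
conditions) keep their value by zeroing their derivative, so rate laws
read the clamp transparently.

## β-oxidation

The carnitine shuttle imports only the C16 ester: CPT1 (cytoplasmic
side) forms palmitoyl-carnitine from the clamped cytoplasmic PCoA, a
reversible mass-action antiporter (CACT) exchanges it against matrix
carnitine, and CPT2 regenerates matrix palmitoyl-CoA from CoASH.
Intermediate-chain acyl-carnitines are not shuttled and do not compete
at CPT1/CPT2. CPT1 carries non-competitive product inhibition by
palmitoyl-carnitine (Ki 5 µM); this is the steady-state throttle that
matches import to the demand-limited disposal rate — without it a
clamped substrate overruns the spiral and traps the CoA pool.

The spiral uses four dehydrogenase chain-length classes (very-long
{16,14,12}, long {16,14,12,10,8}, medium {12,10,8,6}, short {6,4});
where classes overlap their fluxes add. Hydratase, HADH and thiolase
are single lumped activities applied per chain length with
irreversible Michaelis–Menten kinetics (no cross-chain-length substrate
competition); the C4 thiolase step yields two AcCoA. A stoichiometric
audit of the assembled matrix (tests and `full_oxidation_net`) confirms
7 cycles, 8 AcCoA / 7 NADH / 7 ETF-FADH₂ per palmitoyl and element
balance of every column.

## Energetics

The respiratory chain is reduced to three electron-entry channels in
two-electron units — complex I (NADH, +10 H⁺/2e⁻), succinate
dehydrogenase and ETF-ubiquinone oxidoreductase (+6 H⁺/2e⁻ each) — with
saturating substrate kinetics and a logistic protonmotive-force
back-pressure term 1/(1+exp((Δp−Δp₀)/k)). This phenomenological form
replaces the parent-style multi-state complex models; it preserves the
operative feedbacks (reduction pressure, Δp throttling) at much lower
stiffness. Oxygen is non-limiting; VO₂ = ½·Σ channel flux.

Phosphorylation: ATP synthase (3 H⁺ charge/ATP, logistic Δp
activation), electrogenic ANT (1 charge), electroneutral Pi carrier,
and the proton-translocating transhydrogenase (NNT, 1 charge) that
links NADH to NADPH regeneration. Proton leak is ohmic in Δp with the
lipid-dependent conductance g_H = g_H0 + k_PCoA·[PCoA]⁴ read from the
clamped cytoplasmic PCoA. Respiratory states follow the simulated
convention: state 4 ≡ ADP_e = 5·10⁻⁴ mM, state 3 ≡ 0.1 mM.

The TCA span is deliberately compact: CS, NAD- and NADP-linked
isocitrate dehydrogenase, KGDH (with succinate product inhibition),
SDH, reversible MDH, NAD-linked malic enzyme + PDH (so malate alone can
prime the cycle with AcCoA — the model's counterpart of the
experimental malate requirement), glutamate dehydrogenase for
anaplerosis, a reversible dicarboxylate carrier, and small cataplerotic
effluxes of citrate, 2-oxoglutarate and pyruvate. The effluxes are a
structural necessity, not a tuning device: a chain of irreversible
saturating reactions under a clamped substrate has no bounded steady
state unless every span has either product feedback or an exit.

ΔpH is held constant (matrix pH 7.8 vs 7.2 outside; H⁺ clamped), so
Δp = ΔΨ_m + Z·ΔpH ≈ ΔΨ_m + 37 mV. Ca²⁺ and Na⁺ are carried as clamped
states: none of the shipped protocols perturbs them, and their
transporters are outside the questions this model addresses.

## ROS generation, scavenging and emission

Superoxide production is a fixed fraction (shunt, 1.5%) of total
electron flux multiplied by a logistic function of ΔΨ_m (half-point
185 mV, slope 12 mV); 80% is released to the matrix and 20% outward.
The ΔΨ dependence is the mechanism behind the high-lipid emission
plateau: uncoupling collapses ΔΨ_m and lowers generation per electron.
Scavenging: SOD in both compartments (first-order), GPx/GR and Prx/TrxR
arms in both compartments (GR and TrxR Vmax carry the `GR_scale` /
`TrxR_scale` activity factors in both compartments), catalase
extra-matrix only. Matrix NADPH is dynamic (NNT + NADP-IDH sources);
extra-matrix NADPH is a clamped boundary pool. Transport: first-order
O₂·⁻ efflux, bidirectional H₂O₂ diffusion, a slow equilibrative GSH
exchange, and a first-order H₂O₂ clearance from the extra-matrix
compartment into an external sink.

`V_H2O2` (µM s⁻¹, matrix-volume basis) is by default that outer-boundary
clearance flux — the emission net of all scavenging, which is what the
Amplex-red assay detects; `h2o2_emission(..., "matrix_efflux")` reports
the raw matrix efflux instead.

## Parameter provenance and calibration

No single published table covers this exact reduced structure, so the
shipped defaults (`src/mitobetaox/data/params_default.yml`) were set in
two steps. Scales and pool sizes come from standard mitochondrial
physiology (NAD pool 1 mM, GSH 1 mM, Trx 20 µM, adenine 10 mM,
capacitance 1.812·10⁻³ mM/mV, carnitine-shuttle and spiral Km values in
the µM–tens-of-µM range typical of the liver β-oxidation kinetics this
pathway representation descends from). The free gains — chain and
shuttle Vmax values, g_H0, k_PCoA, the ROS shunt and its ΔΨ half-point,
scavenger Vmax values — were then calibrated once against the target
behaviors of the modeled system: state-3 VO₂ ≈ 1.2–1.6 mM s⁻¹ rising
with PCoA and state-4 VO₂ ≈ 0.25–0.35 mM s⁻¹ flat below 20 µM (the
experimental scale via the 16.67 mM s⁻¹ per µmol min⁻¹ mg⁻¹ bridge); an
RCR near 4 at 10 µM PCoA falling to near 2 at 40 µM (this fixes k_PCoA
≈ 1.15·10⁴ mM⁻⁴·mM s⁻¹ mV⁻¹ given g_H0); an H₂O₂ emission threshold at
~20 µM in state 4; emission a low single-digit percentage of VO₂ with
>80% of generated ROS scavenged; and the depletion sequence in which
matrix GSH falls steeply before Trx(SH)₂ and NADPH decline. After
calibration no parameter is adjusted per experiment; every shipped
protocol runs the same default set, with only the clamps and the two
activity scales varying.

The Fig-style GR comparison uses GR Vmax multipliers ×0.5 / ×1 / ×2 in
both compartments; the inhibition condition is GR_scale = 0.15,
TrxR_scale = 0.22.

## Numerics

Stiff integration uses BDF with a fixed-relative-step dense
finite-difference Jacobian over the *free* variables only (clamped
entries excluded — adaptive FD schemes misbehave on identically-zero
columns). Defaults: rtol 1e-8, atol 1e-12 mM for timecourses. Negative
excursions beyond −1e-9 mM abort with the offending species named;
smaller ones are clipped to zero at segment boundaries, never silently
projected during integration.

Steady states are found by long integration in growing windows
(200 s → 10× per window, up to 10⁷ s of model time), declaring
convergence when the residual max |dx/dt|/max(|x|, 10⁻¹² mM) over free
variables falls below 10⁻¹⁰ s⁻¹. A Levenberg–Marquardt polish runs once
integration is within 10⁻² s⁻¹; it is accepted only if it reduces the
residual and stays within 5% of the integrated state, so it can never
substitute a different solution. Concentrations below 10⁻¹² mM (far
less than one molecule per mitochondrion) are snapped to zero: species
emptied by a protocol decay exponentially forever and would otherwise
never meet the floored relative criterion. Dose-response scans
warm-start each grid point from the previous one; warm and cold starts
agree to <0.01% in VO₂ and to a few tenths of a percent in V_H2O2
(tested), so no hysteresis is introduced in the validated 0–40 µM
range — the residual bound leaves the near-degenerate slow direction of
the inter-compartment thiol pools determined only to that looser
precision, which emission inherits.

Determinism: there is no randomness anywhere; identical inputs give
byte-identical output tables.

## Protocol conventions

PCoA is clamped, not consumed (matching the simulated, not the
experimental, protocol); a consumable mode can be emulated by omitting
the clamp. The state 4→3 timecourse applies PCoA at 100 s, glutamate
(5 mM) at 400 s and ADP (1 mM) at 700 s. The "response to ADP" metric
used in tests is the NADH excursion from the lipid-loaded (post-PCoA)
baseline to the post-ADP steady level; by this measure the transition
is blunted at 25 µM vs 10 µM. The drop measured from the post-glutamate
peak instead is *not* smaller at high PCoA in this parameterization —
glutamate largely erases the lipid-phase NADH difference; the
uncoupling signature appears before glutamate, as stronger NADH
oxidation.

## What the model does and does not capture

Reproduced qualitatively and semi-quantitatively: the flat-then-rising
state-4 VO₂ and emission profiles with a ~20 µM threshold; the
rise-then-plateau of state-3 emission vs VO₂ and its ordering by GR
activity; RCR falling from ~4 to ~2 across 10→40 µM; emission rising
under GR/TrxR inhibition with VO₂ unchanged (<0.1%); GSH-first redox
depletion. Not captured / out of scope: absolute emission differences
between state 4 and state 3 track generation (state 3 higher here,
whereas measured emission *fractions* are higher in state 4); pH and
ion dynamics; reverse electron transport; permeability transition;
odd-chain or unsaturated substrates; peroxisomal β-oxidation; fitting
to any animal-group data. Passing tests demonstrate internal
consistency and the listed system-level behaviors of this model — not
parameter-level agreement with any particular mitochondrial
preparation.
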