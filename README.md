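# mitobetaox

A two-compartment kinetic model of heart mitochondria oxidizing
long-chain fatty acids, for researchers studying how lipid supply shapes
mitochondrial respiration, redox balance and reactive-oxygen-species
(ROS) emission — e.g. in diabetic cardiomyopathy, where the heart shifts
from glucose to fatty-acid fuel.

Palmitoyl-CoA (PCoA, the CoA-activated C16 fatty acid) plays two roles
in the model. As a **fuel**, it is imported by the carnitine shuttle
(CPT1 → CACT → CPT2) and degraded by the β-oxidation spiral — four
enzymes (acyl-CoA dehydrogenases of four chain-length classes, 2-enoyl-CoA
hydratase, 3-hydroxyacyl-CoA dehydrogenase, 3-ketoacyl-CoA thiolase)
acting recursively over seven cycles:

    C16-CoA + 7 CoASH + 7 FAD(ETF) + 7 NAD⁺ → 8 AcCoA + 7 ETF-FADH₂ + 7 NADH

AcCoA feeds the TCA cycle (regenerating free CoA), and NADH / succinate /
ETF-FADH₂ feed three electron-entry channels of the respiratory chain
that pump protons against the protonmotive force Δp = ΔΨ_m + Z·ΔpH.
As an **uncoupler**, PCoA raises the inner-membrane proton conductance
cooperatively as it approaches its critical micellar concentration:

    g_H(PCoA) = g_H0 + k_PCoA · [PCoA]⁴

A fraction of electron flux, increasing with ΔΨ_m, is diverted to
superoxide; O₂·⁻ and H₂O₂ are handled by compartmentalized scavengers
(MnSOD / Cu,ZnSOD, the glutathione arm GPx/GR, the thioredoxin arm
Prx/TrxR, catalase outside the matrix), all fed by NADPH. The measured
observable `V_H2O2` is the H₂O₂ flux escaping the whole system after
extra-matrix scavenging — what an Amplex-red assay sees.

The state vector holds ~70 species (mM) across matrix and extra-matrix
compartments plus ΔΨ_m (mV); steady states are defined by a relative
time derivative below 1e-10 s⁻¹ for every free variable.

## Worked example

```python
from mitobetaox import Model, compute_rcr, find_steady_state
from mitobetaox.protocols import state3_protocol, state4_protocol

model = Model()                       # shipped default parameters
for pcoa_mM in (0.01, 0.04):          # 10 and 40 µM clamped PCoA
    s4 = find_steady_state(model, state4_protocol(pcoa_mM))
    s3 = find_steady_state(model, state3_protocol(pcoa_mM), initial=s4.state)
    print(pcoa_mM, compute_rcr(s3.fluxes["VO2_total"], s4.fluxes["VO2_total"]))
```

prints (see `examples/02_respiratory_control.py`):

```
PCoA 10 uM:  VO2 state4 = 0.333 mM/s, state3 = 1.189 mM/s, RCR = 3.57 (converged: True)
PCoA 40 uM:  VO2 state4 = 0.720 mM/s, state3 = 1.562 mM/s, RCR = 2.17 (converged: True)
```

State 4 (extra-matrix ADP clamped at 5·10⁻⁴ mM) is leak-limited
respiration; state 3 (0.1 mM ADP) is phosphorylating respiration. Their
ratio, the respiratory control ratio, falls from ~4 to ~2 as the quartic
leak term uncouples the membrane — at 40 µM the leak conductance has
roughly quadrupled, state-4 VO₂ has doubled, and H₂O₂ emission has risen
from its flat low-PCoA baseline (the rise starts at ~20 µM; run
`examples/03_dose_response.py`).

Flux units: internal VO₂ is mM s⁻¹ referenced to matrix volume and
V_H2O2 is µM s⁻¹; `convert_flux_units` bridges to the experimental
nmol·min⁻¹·mg⁻¹ scale (1 µmol min⁻¹ mg⁻¹ = 16.67 mM s⁻¹ at 1 µl matrix
volume per mg mitochondrial protein).

Other capabilities, one script each under `examples/`: the β-oxidation
stoichiometry audit, state-4 dose-response with the emission threshold,
the state 4→3 NADH transition protocol, and the GR/TrxR inhibition
experiment. A thin CLI mirrors the protocol experiments:
`mitobetaox scan|timecourse|inhibit --help`.

## Species and output naming

β-oxidation intermediates follow `C{n}{stage}CoA` with n = 16…4 and
stage ∈ {acyl, enoyl, hydroxyacyl, ketoacyl}; only the C16 carnitine
ester is shuttled (`C16carnitine_m` / `C16carnitine_e`). Trajectory
CSVs carry one column per canonical species name; flux tables use
`VO2_total`, `VO2_NADH`, `VO2_succ`, `VO2_ETF`, `V_H2O2`, `J_Hleak`,
`J_F1F0`, `J_ANT`, `g_H` and the per-reaction rate names.

See `docs/methods.md` for the model description, parameter provenance
and known limitations.
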