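# Default initial condition (mM; dpsi in mV), consistent with
# the conserved-pool totals of the default parameter set.
NADH_m: 0.3
NAD_m: 0.7
NADPH_m: 0.09
NADP_m: 0.01
GSH_m: 0.99
GSSG_m: 0.005
TrxSH2_m: 0.019
TrxSS_m: 0.001
O2neg_m: 1.0e-07
H2O2_m: 1.0e-05
O2neg_e: 1.0e-08
H2O2_e: 1.0e-06
GSH_e: 0.995
GSSG_e: 0.0025
TrxSH2_e: 0.009
TrxSS_e: 0.001
AcCoA: 0.05
CoASH: 0.94972
ETF_FAD: 0.019
ETF_FADH2: 0.001
carnitine_m: 1.0
carnitine_e: 0.5
C16carnitine_m: 1.0e-05
C16carnitine_e: 1.0e-05
C16acylCoA: 1.0e-05
C16enoylCoA: 1.0e-05
C16hydroxyacylCoA: 1.0e-05
C16ketoacylCoA: 1.0e-05
C14acylCoA: 1.0e-05
C14enoylCoA: 1.0e-05
C14hydroxyacylCoA: 1.0e-05
C14ketoacylCoA: 1.0e-05
C12acylCoA: 1.0e-05
C12enoylCoA: 1.0e-05
C12hydroxyacylCoA: 1.0e-05
C12ketoacylCoA: 1.0e-05
C10acylCoA: 1.0e-05
C10enoylCoA: 1.0e-05
C10hydroxyacylCoA: 1.0e-05
C10ketoacylCoA: 1.0e-05
C8acylCoA: 1.0e-05
C8enoylCoA: 1.0e-05
C8hydroxyacylCoA: 1.0e-05
C8ketoacylCoA: 1.0e-05
C6acylCoA: 1.0e-05
C6enoylCoA: 1.0e-05
C6hydroxyacylCoA: 1.0e-05
C6ketoacylCoA: 1.0e-05
C4acylCoA: 1.0e-05
C4enoylCoA: 1.0e-05
C4hydroxyacylCoA: 1.0e-05
C4ketoacylCoA: 1.0e-05
OAA: 0.0001
CIT: 0.2
AKG: 0.2
SUC: 0.05
MAL: 0.5
PYR: 0.01
GLU_m: 0.0
ATP_m: 4.0
ADP_m: 6.0
Pi_m: 2.0
ATP_e: 0.01
ADP_e: 0.0005
Pi_e: 2.0
Ca_m: 0.0001
Ca_e: 0.0001
Na_m: 5.0
Na_e: 5.0
H_m: 1.5849e-05
H_e: 6.3096e-05
PCoA_cyt: 0.0
MAL_e: 0.5
dpsi: 190.0
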