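"""Scavenger inhibition: GR at 15% and TrxR at 22% of control activity.

Reproduces the simulated DNCB/auranofin experiment at 40 µM clamped
PCoA: four steady states (control vs inhibited x states 4 and 3).
Inhibiting the glutathione- and thioredoxin-reductase arms raises H2O2
emission severalfold while oxygen consumption is essentially unchanged —
the scavengers shape emission, not respiration.  Runtime ~1 minute.
"""

from mitobetaox import Model, inhibition_experiment

model = Model()
table = inhibition_experiment(model)
print(table[["condition", "respiratory_state", "GR_scale", "TrxR_scale",
             "V_H2O2", "VO2_total"]].round(4).to_string(index=False))

ctrl = table[table.condition == "control"].set_index("respiratory_state")
inh = table[table.condition == "inhibited"].set_index("respiratory_state")
for state in ("state4", "state3"):
    print(f"{state}: V_H2O2 x{inh.loc[state, 'V_H2O2'] / ctrl.loc[state, 'V_H2O2']:.2f}, "
          f"VO2 change "
          f"{100 * (inh.loc[state, 'VO2_total'] / ctrl.loc[state, 'VO2_total'] - 1):+.2f}%")
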