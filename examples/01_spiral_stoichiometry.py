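"""Audit the beta-oxidation stoichiometric matrix.

Builds the carnitine-shuttle + spiral reaction network and traverses one
complete oxidation of palmitoyl-CoA (C16), printing the net species
change.  Expected: 7 acetyl-releasing cycles giving 8 acetyl-CoA, 7 NADH
and 7 ETF-FADH2 per palmitoyl, with CoA and carnitine moieties conserved.
"""

from mitobetaox import betaox_stoichiometric_matrix, full_oxidation_net
from mitobetaox.betaox import element_vectors

mat = betaox_stoichiometric_matrix()
print(f"stoichiometric matrix: {mat.shape[0]} species x "
      f"{mat.shape[1]} reactions")

cycles = [c for c in mat.columns if c.startswith("thiolase")]
print(f"acetyl-releasing cycles: {len(cycles)}  ({', '.join(cycles)})")

net = full_oxidation_net()
print("\nnet change per palmitoyl-CoA oxidized:")
for name, coeff in net.items():
    if coeff != 0:
        print(f"  {name:16s} {coeff:+.0f}")

elems = element_vectors(list(net.index))
print("\nmoiety balance of the net reaction "
      "(all zero = nothing created or destroyed):")
for moiety in ("CoA", "carnitine", "ETF", "NAD"):
    print(f"  {moiety:10s} {float(elems[moiety] @ net):+.0f}")
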