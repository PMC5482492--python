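"""Reaction framework: rate laws plus stoichiometry, assembled into one ODE.

Every process in the model is a :class:`Reaction`: a named rate law with a
stoichiometry map over canonical species names, an optional membrane
charge displacement, and a reference compartment.  Rates are expressed in
mM s⁻¹ of the reference compartment; species on the other side of the
inner membrane receive the rate scaled by the compartment volume ratio,
so that mole balance (and hence pool conservation) is exact by
construction.

The ``charge`` attribute is the number of positive charges moved from the
matrix to the extra-matrix side per unit rate; the membrane-potential
equation is the capacitance-weighted sum of those terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .species import IDX, N_SPECIES, compartment_of

RateFn = Callable[[np.ndarray, "object"], float]


@dataclass
class Reaction:
    name: str
    stoich: dict[str, float]
    rate: RateFn
    charge: float = 0.0
    volume: str = "m"  # reference compartment of the rate, 'm' or 'e'
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.volume not in ("m", "e"):
            raise ValueError(f"reaction {self.name}: volume must be 'm' or 'e'")
        for sp in self.stoich:
            if sp not in IDX:
                raise ValueError(f"reaction {self.name}: unknown species {sp!r}")


def mm(s: float, km: float) -> float:
    """Irreversible Michaelis-Menten saturation term, clipped at zero.

    Clipping guards against the tiny negative excursions a stiff solver
    may probe; genuine negative states are rejected at a higher level.
    """
    if s <= 0.0:
        return 0.0
    return s / (s + km)


def hill_inhibition(x: float, x0: float, k: float) -> float:
    """Logistic back-pressure term, 1 at x << x0 falling to 0 at x >> x0."""
    return 1.0 / (1.0 + np.exp((x - x0) / k))


def hill_activation(x: float, x0: float, k: float) -> float:
    """Logistic activation term, 0 at x << x0 rising to 1 at x >> x0."""
    return 1.0 / (1.0 + np.exp(-(x - x0) / k))


def build_stoichiometry(
    reactions: list[Reaction], volume_ratio_extra_to_matrix: float,
    membrane_capacitance: float,
) -> np.ndarray:
    """Dense (species x reactions) matrix mapping rates to concentration
    derivatives, including volume scaling and the charge-balance row."""
    r = volume_ratio_extra_to_matrix
    n_rxn = len(reactions)
    N = np.zeros((N_SPECIES, n_rxn))
    for j, rxn in enumerate(reactions):
        for sp, coeff in rxn.stoich.items():
            comp = compartment_of(sp)
            if comp == "psi":
                raise ValueError(
                    f"reaction {rxn.name}: dpsi is driven by charge, not stoich"
                )
            if comp == rxn.volume:
                factor = 1.0
            elif rxn.volume == "m":  # matrix-referenced rate acting on 'e'
                factor = 1.0 / r
            else:  # extra-referenced rate acting on 'm'
                factor = r
            N[IDX[sp], j] += coeff * factor
        if rxn.charge:
            if rxn.volume != "m":
                raise ValueError(
                    f"reaction {rxn.name}: charge-moving rates must be "
                    "matrix-referenced"
                )
            # positive charge leaving the matrix polarizes the membrane
            N[IDX["dpsi"], j] += rxn.charge / membrane_capacitance
    return N
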