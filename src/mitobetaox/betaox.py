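"""Long-chain fatty-acid beta-oxidation: carnitine shuttle and spiral.

Palmitoyl-CoA (PCoA, C16) enters as the clamped cytoplasmic substrate.
Carnitine palmitoyltransferase I (CPT1) forms palmitoyl-carnitine on the
cytoplasmic side, the carnitine/acylcarnitine translocase (CACT) antiports
it into the matrix, and CPT2 regenerates matrix palmitoyl-CoA.  Only the
C16 species is shuttled: competition of CPT1/CPT2 by intermediate
acyl-carnitines is deliberately excluded.

The spiral then shortens the acyl-CoA by two carbons per cycle through
four reactions — acyl-CoA dehydrogenase (reducing ETF-FAD), 2-enoyl-CoA
hydratase, 3-hydroxyacyl-CoA dehydrogenase (HADH, reducing NAD⁺) and
3-ketoacyl-CoA thiolase (releasing acetyl-CoA) — over seven cycles, the
last of which (C4) yields two acetyl-CoA.  Four acyl-CoA dehydrogenase
chain-length classes (very-long, long, medium, short) jointly cover
C16..C4; where classes overlap on a chain length their fluxes add.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reactions import Reaction, mm
from .species import CHAIN_LENGTHS, IDX, STAGES, acyl_name

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AcylSpecies:
    """One beta-oxidation intermediate."""

    chain_length: int
    oxidation_stage: str  # acyl | enoyl | hydroxyacyl | ketoacyl
    compartment: str = "m"
    carrier: str = "CoA"  # CoA | carnitine

    def __post_init__(self) -> None:
        if self.chain_length not in CHAIN_LENGTHS:
            raise ValueError(
                f"chain length must be even and in 4..16, "
                f"got {self.chain_length}")
        if self.oxidation_stage not in STAGES:
            raise ValueError(f"unknown stage {self.oxidation_stage!r}")
        if self.carrier == "carnitine" and self.chain_length != 16:
            raise ValueError(
                "only palmitoyl-carnitine (C16) is shuttled in this model")
        if self.carrier not in ("CoA", "carnitine"):
            raise ValueError(f"unknown carrier {self.carrier!r}")

    @property
    def name(self) -> str:
        if self.carrier == "carnitine":
            return f"C16carnitine_{self.compartment}"
        return acyl_name(self.chain_length, self.oxidation_stage)


@dataclass(frozen=True)
class DehydrogenaseClass:
    """One acyl-CoA dehydrogenase chain-length class."""

    name: str
    chain_length_specificity: frozenset[int]
    vmax_param: str
    km_param: str


DEHYDROGENASE_CLASSES: tuple[DehydrogenaseClass, ...] = (
    DehydrogenaseClass("very-long", frozenset({16, 14, 12}),
                       "Vmax_vlcad", "Km_vlcad_acyl"),
    DehydrogenaseClass("long", frozenset({16, 14, 12, 10, 8}),
                       "Vmax_lcad", "Km_lcad_acyl"),
    DehydrogenaseClass("medium", frozenset({12, 10, 8, 6}),
                       "Vmax_mcad", "Km_mcad_acyl"),
    DehydrogenaseClass("short", frozenset({6, 4}),
                       "Vmax_scad", "Km_scad_acyl"),
)

assert set().union(*(c.chain_length_specificity
                     for c in DEHYDROGENASE_CLASSES)) == set(CHAIN_LENGTHS)


# ---------------------------------------------------------------------------
# rate laws


def _cpt1_rate(y: np.ndarray, p) -> float:
    # non-competitive product inhibition by palmitoyl-carnitine throttles
    # import to the downstream (demand-limited) disposal rate
    inhib = p.Ki_cpt1_pcarn / (p.Ki_cpt1_pcarn
                               + max(y[IDX["C16carnitine_e"]], 0.0))
    return (p.Vmax_cpt1
            * mm(y[IDX["PCoA_cyt"]], p.Km_cpt1_pcoa)
            * mm(y[IDX["carnitine_e"]], p.Km_cpt1_car)
            * inhib)


def _cact_rate(y: np.ndarray, p) -> float:
    # reversible mass-action antiport across the inner membrane
    fwd = max(y[IDX["C16carnitine_e"]], 0.0) * max(y[IDX["carnitine_m"]], 0.0)
    rev = max(y[IDX["C16carnitine_m"]], 0.0) * max(y[IDX["carnitine_e"]], 0.0)
    return p.k_cact * (fwd - rev)


def _cpt2_rate(y: np.ndarray, p) -> float:
    return (p.Vmax_cpt2
            * mm(y[IDX["C16carnitine_m"]], p.Km_cpt2_acylcarnitine)
            * mm(y[IDX["CoASH"]], p.Km_cpt2_coash))


def _acd_rate_fn(cls: DehydrogenaseClass, n: int):
    i_acyl = IDX[acyl_name(n, "acyl")]
    i_etf = IDX["ETF_FAD"]

    def rate(y: np.ndarray, p) -> float:
        return (p[cls.vmax_param]
                * mm(y[i_acyl], p[cls.km_param])
                * mm(y[i_etf], p.Km_acd_etf))

    return rate


def _hydratase_rate_fn(n: int):
    i = IDX[acyl_name(n, "enoyl")]

    def rate(y: np.ndarray, p) -> float:
        return p.Vmax_hydratase * mm(y[i], p.Km_hydratase_enoyl)

    return rate


def _hadh_rate_fn(n: int):
    i = IDX[acyl_name(n, "hydroxyacyl")]
    i_nad = IDX["NAD_m"]

    def rate(y: np.ndarray, p) -> float:
        return (p.Vmax_hadh
                * mm(y[i], p.Km_hadh_hydroxyacyl)
                * mm(y[i_nad], p.Km_hadh_nad))

    return rate


def _thiolase_rate_fn(n: int):
    i = IDX[acyl_name(n, "ketoacyl")]
    i_coash = IDX["CoASH"]

    def rate(y: np.ndarray, p) -> float:
        return (p.Vmax_thiolase
                * mm(y[i], p.Km_thiolase_ketoacyl)
                * mm(y[i_coash], p.Km_thiolase_coash))

    return rate


# ---------------------------------------------------------------------------
# reaction assembly


def shuttle_reactions() -> list[Reaction]:
    """CPT1 / CACT / CPT2, all referenced to matrix volume."""
    return [
        Reaction(
            "CPT1",
            {"PCoA_cyt": -1, "carnitine_e": -1, "C16carnitine_e": +1},
            _cpt1_rate,
        ),
        Reaction(
            "CACT",
            {"C16carnitine_e": -1, "carnitine_m": -1,
             "C16carnitine_m": +1, "carnitine_e": +1},
            _cact_rate,
        ),
        Reaction(
            "CPT2",
            {"C16carnitine_m": -1, "CoASH": -1,
             "C16acylCoA": +1, "carnitine_m": +1},
            _cpt2_rate,
        ),
    ]


def spiral_reactions() -> list[Reaction]:
    """The seven-cycle chain-shortening spiral, C16 down to C4."""
    rxns: list[Reaction] = []
    for n in CHAIN_LENGTHS:
        for cls in DEHYDROGENASE_CLASSES:
            if n not in cls.chain_length_specificity:
                continue
            rxns.append(Reaction(
                f"ACD_{cls.name}_C{n}",
                {acyl_name(n, "acyl"): -1, "ETF_FAD": -1,
                 acyl_name(n, "enoyl"): +1, "ETF_FADH2": +1},
                _acd_rate_fn(cls, n),
                meta={"enzyme": "ACD", "class": cls.name, "chain_length": n},
            ))
        rxns.append(Reaction(
            f"hydratase_C{n}",
            {acyl_name(n, "enoyl"): -1, acyl_name(n, "hydroxyacyl"): +1},
            _hydratase_rate_fn(n),
            meta={"enzyme": "hydratase", "chain_length": n},
        ))
        rxns.append(Reaction(
            f"HADH_C{n}",
            {acyl_name(n, "hydroxyacyl"): -1, "NAD_m": -1,
             acyl_name(n, "ketoacyl"): +1, "NADH_m": +1},
            _hadh_rate_fn(n),
            meta={"enzyme": "HADH", "chain_length": n},
        ))
        if n > 4:
            stoich = {acyl_name(n, "ketoacyl"): -1, "CoASH": -1,
                      "AcCoA": +1, acyl_name(n - 2, "acyl"): +1}
        else:
            # terminal cycle: acetoacetyl-CoA thiolysis yields two AcCoA
            stoich = {acyl_name(4, "ketoacyl"): -1, "CoASH": -1, "AcCoA": +2}
        rxns.append(Reaction(
            f"thiolase_C{n}", stoich, _thiolase_rate_fn(n),
            meta={"enzyme": "thiolase", "chain_length": n},
        ))
    return rxns


def build_reactions(params=None) -> list[Reaction]:
    return shuttle_reactions() + spiral_reactions()


# ---------------------------------------------------------------------------
# public flux evaluation


def _check_nonnegative(state: np.ndarray, names: list[str]) -> None:
    for nm in names:
        if state[IDX[nm]] < 0:
            raise ValueError(f"negative concentration for {nm}")


def carnitine_shuttle_fluxes(
    state: np.ndarray, params, pcoa_cyto: float,
) -> tuple[float, float, float]:
    """Instantaneous CPT1, CACT and CPT2 rates (mM s⁻¹, matrix volume).

    ``pcoa_cyto`` overrides the clamped cytoplasmic PCoA entry of
    ``state`` for this evaluation.
    """
    if pcoa_cyto < 0:
        raise ValueError("pcoa_cyto must be non-negative")
    _check_nonnegative(state, [
        "carnitine_m", "carnitine_e", "C16carnitine_m", "C16carnitine_e",
        "CoASH",
    ])
    y = state.copy()
    y[IDX["PCoA_cyt"]] = pcoa_cyto
    return (_cpt1_rate(y, params), _cact_rate(y, params),
            _cpt2_rate(y, params))


def acyl_dehydrogenase_flux(species: AcylSpecies, state: np.ndarray,
                            params) -> float:
    """Total acyl-CoA dehydrogenase flux on one chain length.

    Sums the contributions of every dehydrogenase class whose specificity
    covers the chain length.
    """
    if species.oxidation_stage != "acyl":
        raise ValueError("dehydrogenase acts on the acyl-CoA stage")
    n = species.chain_length
    total = 0.0
    for cls in DEHYDROGENASE_CLASSES:
        if n in cls.chain_length_specificity:
            total += _acd_rate_fn(cls, n)(state, params)
    return total


def hydratase_hadh_thiolase_fluxes(
    state: np.ndarray, params,
) -> dict[tuple[str, int], float]:
    """Hydratase, HADH and thiolase rates keyed by (enzyme, chain length)."""
    _check_nonnegative(state, [acyl_name(n, s) for n in CHAIN_LENGTHS
                               for s in ("enoyl", "hydroxyacyl", "ketoacyl")])
    out: dict[tuple[str, int], float] = {}
    for n in CHAIN_LENGTHS:
        out[("hydratase", n)] = _hydratase_rate_fn(n)(state, params)
        out[("HADH", n)] = _hadh_rate_fn(n)(state, params)
        out[("thiolase", n)] = _thiolase_rate_fn(n)(state, params)
    return out


# ---------------------------------------------------------------------------
# stoichiometric matrix and element balances

#: pseudo-species closing the CoA balance on the cytoplasmic side (CPT1
#: releases free CoA outside the modeled compartments)
CYTO_COA = "CoASH_cyt"


def betaox_stoichiometric_matrix(params=None) -> pd.DataFrame:
    """Integer stoichiometric matrix (species x reactions) of shuttle+spiral.

    Includes the cytoplasmic pseudo-species ``CoASH_cyt`` so that every
    column balances CoA moieties exactly.
    """
    rxns = build_reactions(params)
    species: list[str] = []
    for rxn in rxns:
        for sp in rxn.stoich:
            if sp not in species:
                species.append(sp)
    species.append(CYTO_COA)
    mat = pd.DataFrame(
        0, index=species, columns=[r.name for r in rxns], dtype=int)
    for rxn in rxns:
        for sp, coeff in rxn.stoich.items():
            mat.loc[sp, rxn.name] += int(coeff)
        if rxn.name == "CPT1":
            mat.loc[CYTO_COA, rxn.name] += 1
    return mat


def element_vectors(species: list[str]) -> pd.DataFrame:
    """Conserved-moiety composition (carbon, CoA, carnitine, ETF, NAD)."""
    rows = {}
    for sp in species:
        carbon = coa = carn = etf = nad = 0
        if sp in ("PCoA_cyt",):
            carbon, coa = 16, 1
        elif sp.startswith("C16carnitine"):
            carbon, carn = 16, 1
        elif sp.startswith("carnitine"):
            carn = 1
        elif sp == "AcCoA":
            carbon, coa = 2, 1
        elif sp in ("CoASH", CYTO_COA):
            coa = 1
        elif sp.startswith("ETF_"):
            etf = 1
        elif sp in ("NAD_m", "NADH_m"):
            nad = 1
        elif sp.startswith("C") and "CoA" in sp:
            carbon = int("".join(ch for ch in sp[1:3] if ch.isdigit()))
            coa = 1
        rows[sp] = dict(carbon=carbon, CoA=coa, carnitine=carn,
                        ETF=etf, NAD=nad)
    return pd.DataFrame(rows).T


def full_oxidation_net(params=None) -> pd.Series:
    """Net species change for one complete palmitoyl-CoA oxidation.

    Traverses the shuttle once and each of the seven cycles once, routing
    each chain length through a single covering dehydrogenase class.
    """
    mat = betaox_stoichiometric_matrix(params)
    flux = pd.Series(0.0, index=mat.columns)
    for name in ("CPT1", "CACT", "CPT2"):
        flux[name] = 1.0
    for n in CHAIN_LENGTHS:
        cls = next(c for c in DEHYDROGENASE_CLASSES
                   if n in c.chain_length_specificity)
        flux[f"ACD_{cls.name}_C{n}"] = 1.0
        flux[f"hydratase_C{n}"] = 1.0
        flux[f"HADH_C{n}"] = 1.0
        flux[f"thiolase_C{n}"] = 1.0
    return mat @ flux
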