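"""Canonical state-space definition for the two-compartment mitochondrial model.

The state vector collects every dynamic concentration (mM) in the
mitochondrial matrix (``_m``) and the extra-matrix compartment (``_e``),
plus the inner-membrane potential ``dpsi`` (mV).  Species order is fixed
and public: trajectory CSV columns, stoichiometric-matrix rows and the
initial-condition file all use these names.

Beta-oxidation intermediates follow the ``C{n}{stage}CoA`` convention for
even chain lengths n = 16 .. 4 and the four oxidation stages of each
spiral turn (acyl, enoyl = 2-enoyl, hydroxyacyl = 3-hydroxyacyl,
ketoacyl = 3-ketoacyl).  Only the C16 species is carried on carnitine
(``C16carnitine_m`` / ``C16carnitine_e``); intermediate acyl-carnitines
are not shuttled in this model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CHAIN_LENGTHS: tuple[int, ...] = (16, 14, 12, 10, 8, 6, 4)
STAGES: tuple[str, ...] = ("acyl", "enoyl", "hydroxyacyl", "ketoacyl")


def acyl_name(n: int, stage: str) -> str:
    """Canonical name of a CoA-carried beta-oxidation intermediate."""
    if n not in CHAIN_LENGTHS:
        raise ValueError(f"chain length must be even and in 4..16, got {n}")
    if stage not in STAGES:
        raise ValueError(f"unknown oxidation stage {stage!r}")
    return f"C{n}{stage}CoA"


def _build_names() -> list[str]:
    names = [
        # matrix pyridine-nucleotide and thiol redox couples
        "NADH_m", "NAD_m", "NADPH_m", "NADP_m",
        "GSH_m", "GSSG_m", "TrxSH2_m", "TrxSS_m",
        # reactive oxygen species
        "O2neg_m", "H2O2_m", "O2neg_e", "H2O2_e",
        # extra-matrix thiol couples
        "GSH_e", "GSSG_e", "TrxSH2_e", "TrxSS_e",
        # beta-oxidation cofactors and carriers
        "AcCoA", "CoASH", "ETF_FAD", "ETF_FADH2",
        "carnitine_m", "carnitine_e", "C16carnitine_m", "C16carnitine_e",
    ]
    for n in CHAIN_LENGTHS:
        for stage in STAGES:
            names.append(acyl_name(n, stage))
    names += [
        # TCA-cycle intermediates (citrate pool lumps citrate + isocitrate,
        # SUC lumps succinyl-CoA + succinate, MAL lumps fumarate + malate)
        # plus pyruvate from malic enzyme and matrix glutamate
        "OAA", "CIT", "AKG", "SUC", "MAL", "PYR", "GLU_m",
        # adenine nucleotides and phosphate
        "ATP_m", "ADP_m", "Pi_m", "ATP_e", "ADP_e", "Pi_e",
        # ions (held at baseline by the shipped protocols)
        "Ca_m", "Ca_e", "Na_m", "Na_e", "H_m", "H_e",
        # boundary substrates (clamped by protocols)
        "PCoA_cyt", "MAL_e",
        # inner-membrane potential, mV
        "dpsi",
    ]
    return names


SPECIES_NAMES: tuple[str, ...] = tuple(_build_names())
N_SPECIES: int = len(SPECIES_NAMES)
IDX: dict[str, int] = {name: i for i, name in enumerate(SPECIES_NAMES)}

#: species clamped by default in every shipped protocol (boundary
#: conditions of the isolated-mitochondria assay): external adenine
#: nucleotides and phosphate, ion baselines, the two fuel feeds and
#: matrix glutamate (set by glutamate-addition events).
DEFAULT_CLAMPED: tuple[str, ...] = (
    "ATP_e", "ADP_e", "Pi_e",
    "Ca_m", "Ca_e", "Na_m", "Na_e", "H_m", "H_e",
    "PCoA_cyt", "MAL_e", "GLU_m",
)

#: matrix-compartment species (per matrix volume); everything else except
#: ``dpsi`` lives in the extra-matrix compartment.  ``PCoA_cyt`` is the
#: clamped cytoplasmic substrate and belongs to the extra-matrix side.
EXTRA_SPECIES: frozenset[str] = frozenset(
    [s for s in SPECIES_NAMES if s.endswith("_e")] + ["PCoA_cyt"]
)
MATRIX_SPECIES: frozenset[str] = frozenset(
    s for s in SPECIES_NAMES
    if s not in EXTRA_SPECIES and s != "dpsi"
)


def compartment_of(name: str) -> str:
    """Return ``'m'``, ``'e'`` or ``'psi'`` for a species name."""
    if name == "dpsi":
        return "psi"
    return "e" if name in EXTRA_SPECIES else "m"


@dataclass(frozen=True)
class StateView:
    """Read-only attribute access into a raw state array.

    Thin convenience wrapper used by rate laws in tests and examples; the
    production right-hand side uses integer indices resolved at build time.
    """

    y: np.ndarray

    def __getattr__(self, name: str) -> float:
        try:
            return self.y[IDX[name]]
        except KeyError as exc:
            raise AttributeError(name) from exc


def state_to_dict(y: np.ndarray) -> dict[str, float]:
    return {name: float(y[i]) for name, i in IDX.items()}


def dict_to_state(d: dict[str, float]) -> np.ndarray:
    """Build a state array from a complete name -> value mapping."""
    missing = set(SPECIES_NAMES) - set(d)
    if missing:
        raise ValueError(f"initial condition missing species: {sorted(missing)}")
    unknown = set(d) - set(SPECIES_NAMES)
    if unknown:
        raise ValueError(f"unknown species in initial condition: {sorted(unknown)}")
    y = np.empty(N_SPECIES)
    for name, value in d.items():
        y[IDX[name]] = float(value)
    return y
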