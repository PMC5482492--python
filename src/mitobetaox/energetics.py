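"""Oxidative phosphorylation, TCA cycle, proton circuit and transport.

The respiratory chain is represented by three electron-entry channels in
two-electron units: complex I (NADH), succinate dehydrogenase and the
ETF-ubiquinone oxidoreductase fed by the beta-oxidation dehydrogenases.
Each channel pumps protons against the protonmotive force and is slowed
by it through a logistic back-pressure term; oxygen is non-limiting.
Oxygen consumption is half the summed two-electron channel flux.

The proton circuit closes through ATP synthesis, the electrogenic
adenine-nucleotide translocase, the nicotinamide-nucleotide
transhydrogenase and the leak.  Lipid uncoupling enters as an increase of
the proton conductance proportional to the fourth power of the clamped
cytoplasmic palmitoyl-CoA concentration:

    g_H(PCoA) = g_H0 + k_PCoA * PCoA**4

a form motivated by the cooperative incorporation of PCoA molecules into
the membrane as the critical micellar concentration is approached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .reactions import Reaction, hill_activation, hill_inhibition, mm
from .species import IDX

# ---------------------------------------------------------------------------
# protonmotive force


def ph_of(h_mM: float) -> float:
    return -math.log10(h_mM * 1e-3)


def pmf(y: np.ndarray, p) -> float:
    """Protonmotive force in mV: dpsi plus the chemical (delta-pH) term."""
    dph = ph_of(y[IDX["H_m"]]) - ph_of(y[IDX["H_e"]])
    return y[IDX["dpsi"]] + p.z_temp_mV * dph


def proton_conductance(pcoa_cyto: float, p) -> float:
    """PCoA-dependent inner-membrane proton conductance (mM s⁻¹ mV⁻¹)."""
    c = max(pcoa_cyto, 0.0)
    return p.g_H0 + p.k_PCoA * c ** int(p.pcoa_uncoupling_exponent)


@dataclass(frozen=True)
class ProtonCircuit:
    """Leak pathway of the inner membrane."""

    g_H0: float
    k_PCoA: float
    exponent: int = 4
    z_temp_mV: float = 61.5

    def conductance(self, pcoa_cyto: float) -> float:
        return self.g_H0 + self.k_PCoA * max(pcoa_cyto, 0.0) ** self.exponent

    def leak_flux(self, dpsi: float, dpH: float, pcoa_cyto: float) -> float:
        return self.conductance(pcoa_cyto) * (dpsi + self.z_temp_mV * dpH)


def proton_leak_flux(dpsi: float, dpH: float, pcoa_cyto: float, p) -> float:
    """Proton leak (mM s⁻¹ charge) at the given driving force.

    ``dpH`` is pH_matrix - pH_extra.  At ``pcoa_cyto = 0`` this is exactly
    the baseline leak ``g_H0 * pmf``.
    """
    if pcoa_cyto < 0:
        raise ValueError("pcoa_cyto must be non-negative")
    circuit = ProtonCircuit(p.g_H0, p.k_PCoA,
                            int(p.pcoa_uncoupling_exponent), p.z_temp_mV)
    return circuit.leak_flux(dpsi, dpH, pcoa_cyto)


# ---------------------------------------------------------------------------
# respiratory-chain channel rates (two-electron units, mM s⁻¹)


def complex1_rate(y: np.ndarray, p) -> float:
    return (p.Vmax_C1 * mm(y[IDX["NADH_m"]], p.Km_C1_nadh)
            * hill_inhibition(pmf(y, p), p.pmf0_C1, p.kpmf_C1))


def sdh_rate(y: np.ndarray, p) -> float:
    return (p.Vmax_SDH * mm(y[IDX["SUC"]], p.Km_SDH_suc)
            * hill_inhibition(pmf(y, p), p.pmf0_SDH, p.kpmf_SDH))


def etfqo_rate(y: np.ndarray, p) -> float:
    return (p.Vmax_ETFQO * mm(y[IDX["ETF_FADH2"]], p.Km_ETFQO_etfh2)
            * hill_inhibition(pmf(y, p), p.pmf0_ETFQO, p.kpmf_ETFQO))


def _leak_rate(y: np.ndarray, p) -> float:
    return proton_conductance(y[IDX["PCoA_cyt"]], p) * pmf(y, p)


def _f1f0_rate(y: np.ndarray, p) -> float:
    return (p.Vmax_F1F0
            * mm(y[IDX["ADP_m"]], p.Km_F1_adp)
            * mm(y[IDX["Pi_m"]], p.Km_F1_pi)
            * hill_activation(pmf(y, p), p.pmf0_F1, p.kpmf_F1))


def _ant_rate(y: np.ndarray, p) -> float:
    return (p.Vmax_ANT
            * mm(y[IDX["ADP_e"]], p.Km_ANT_adp_e)
            * mm(y[IDX["ATP_m"]], p.Km_ANT_atp_m))


def _pit_rate(y: np.ndarray, p) -> float:
    return p.k_PiT * (y[IDX["Pi_e"]] - y[IDX["Pi_m"]])


def _nnt_rate(y: np.ndarray, p) -> float:
    return (p.Vmax_NNT
            * mm(y[IDX["NADH_m"]], p.Km_NNT_nadh)
            * mm(y[IDX["NADP_m"]], p.Km_NNT_nadp))


# ---------------------------------------------------------------------------
# TCA cycle and anaplerosis


def _cs_rate(y, p):
    return (p.Vmax_CS * mm(y[IDX["AcCoA"]], p.Km_CS_accoa)
            * mm(y[IDX["OAA"]], p.Km_CS_oaa))


def _idh_rate(y, p):
    return (p.Vmax_IDH * mm(y[IDX["CIT"]], p.Km_IDH_cit)
            * mm(y[IDX["NAD_m"]], p.Km_IDH_nad))


def _idh_nadp_rate(y, p):
    return (p.Vmax_IDH_nadp * mm(y[IDX["CIT"]], p.Km_IDH_cit)
            * mm(y[IDX["NADP_m"]], p.Km_IDH_nadp))


def _kgdh_rate(y, p):
    # succinate product inhibition keeps the SUC pool bounded when the
    # pmf-throttled SDH channel caps downstream disposal
    inhib = p.Ki_KGDH_suc / (p.Ki_KGDH_suc + max(y[IDX["SUC"]], 0.0))
    return (p.Vmax_KGDH * mm(y[IDX["AKG"]], p.Km_KGDH_akg)
            * mm(y[IDX["NAD_m"]], p.Km_KGDH_nad) * inhib)


def _mdh_rate(y, p):
    mal = max(y[IDX["MAL"]], 0.0)
    nad = max(y[IDX["NAD_m"]], 0.0)
    oaa = max(y[IDX["OAA"]], 0.0)
    nadh = max(y[IDX["NADH_m"]], 0.0)
    num = mal * nad - oaa * nadh / p.Keq_MDH
    return p.Vmax_MDH * num / ((p.Km_MDH_mal + mal) * (p.Km_MDH_nad + nad))


def _me_rate(y, p):
    # NAD-linked malic enzyme: lets malate alone prime the cycle with
    # acetyl-CoA (via pyruvate and PDH), as in the malate-fed assays
    return (p.Vmax_ME * mm(y[IDX["MAL"]], p.Km_ME_mal)
            * mm(y[IDX["NAD_m"]], p.Km_ME_nad))


def _pdh_rate(y, p):
    return (p.Vmax_PDH * mm(y[IDX["PYR"]], p.Km_PDH_pyr)
            * mm(y[IDX["CoASH"]], p.Km_PDH_coash)
            * mm(y[IDX["NAD_m"]], p.Km_PDH_nad))


def _gdh_rate(y, p):
    return (p.Vmax_GDH * mm(y[IDX["GLU_m"]], p.Km_GDH_glu)
            * mm(y[IDX["NAD_m"]], p.Km_GDH_nad))


def _malt_rate(y, p):
    # reversible dicarboxylate carrier; Keq_malT is the matrix/medium
    # accumulation ratio at equilibrium
    return p.k_malT * (y[IDX["MAL_e"]] - y[IDX["MAL"]] / p.Keq_malT)


def _cit_export_rate(y, p):
    # citrate efflux, the net carbon exit when the cycle runs on
    # beta-oxidation-derived AcCoA plus imported malate
    return p.k_cit_export * max(y[IDX["CIT"]], 0.0)


def _akg_export_rate(y, p):
    # small cataplerotic 2-oxoglutarate efflux; balances flux mismatches
    # between the two spans of the cycle so intermediates stay bounded
    return p.k_akg_export * max(y[IDX["AKG"]], 0.0)


def _pyr_export_rate(y, p):
    # monocarboxylate carrier efflux of surplus pyruvate
    return p.k_pyr_export * max(y[IDX["PYR"]], 0.0)


# ---------------------------------------------------------------------------
# reaction assembly


def build_reactions(params=None) -> list[Reaction]:
    return [
        # electron transport (water and CO2 are not tracked)
        Reaction("C1", {"NADH_m": -1, "NAD_m": +1}, complex1_rate,
                 charge=+10),
        Reaction("SDH", {"SUC": -1, "MAL": +1}, sdh_rate, charge=+6),
        Reaction("ETFQO", {"ETF_FADH2": -1, "ETF_FAD": +1}, etfqo_rate,
                 charge=+6),
        # proton circuit
        Reaction("Hleak", {}, _leak_rate, charge=-1),
        Reaction("F1F0", {"ADP_m": -1, "Pi_m": -1, "ATP_m": +1},
                 _f1f0_rate, charge=-3),
        Reaction("ANT", {"ADP_e": -1, "ATP_m": -1, "ADP_m": +1, "ATP_e": +1},
                 _ant_rate, charge=-1),
        Reaction("PiT", {"Pi_e": -1, "Pi_m": +1}, _pit_rate),
        Reaction("NNT", {"NADH_m": -1, "NADP_m": -1,
                         "NAD_m": +1, "NADPH_m": +1}, _nnt_rate, charge=-1),
        # TCA cycle (CO2 not tracked)
        Reaction("CS", {"AcCoA": -1, "OAA": -1, "CIT": +1, "CoASH": +1},
                 _cs_rate),
        Reaction("IDH", {"CIT": -1, "NAD_m": -1, "AKG": +1, "NADH_m": +1},
                 _idh_rate),
        Reaction("IDH_NADP", {"CIT": -1, "NADP_m": -1,
                              "AKG": +1, "NADPH_m": +1}, _idh_nadp_rate),
        Reaction("KGDH", {"AKG": -1, "NAD_m": -1, "SUC": +1, "NADH_m": +1},
                 _kgdh_rate),
        Reaction("MDH", {"MAL": -1, "NAD_m": -1, "OAA": +1, "NADH_m": +1},
                 _mdh_rate),
        Reaction("ME", {"MAL": -1, "NAD_m": -1, "PYR": +1, "NADH_m": +1},
                 _me_rate),
        Reaction("PDH", {"PYR": -1, "CoASH": -1, "NAD_m": -1,
                         "AcCoA": +1, "NADH_m": +1}, _pdh_rate),
        Reaction("GDH", {"GLU_m": -1, "NAD_m": -1, "AKG": +1, "NADH_m": +1},
                 _gdh_rate),
        Reaction("MalT", {"MAL_e": -1, "MAL": +1}, _malt_rate),
        Reaction("CITexport", {"CIT": -1}, _cit_export_rate),
        Reaction("AKGexport", {"AKG": -1}, _akg_export_rate),
        Reaction("PYRexport", {"PYR": -1}, _pyr_export_rate),
    ]


# ---------------------------------------------------------------------------
# public flux views


class RespirationFlux(NamedTuple):
    VO2_NADH: float
    VO2_succ: float
    VO2_ETF: float
    VO2_total: float


def respiration_flux(state: np.ndarray, params) -> RespirationFlux:
    """Oxygen consumption (mM s⁻¹) split by electron source.

    Each channel flux is in two-electron units; one O2 accepts four
    electrons, so VO2 per channel is half the channel rate.
    """
    v1 = 0.5 * complex1_rate(state, params)
    v2 = 0.5 * sdh_rate(state, params)
    v3 = 0.5 * etfqo_rate(state, params)
    return RespirationFlux(v1, v2, v3, v1 + v2 + v3)


def tca_glutamate_fluxes(state: np.ndarray, params,
                         protocol=None) -> dict[str, float]:
    """TCA-cycle, anaplerosis and malate-import rates (mM s⁻¹)."""
    return {
        "CS": _cs_rate(state, params),
        "IDH": _idh_rate(state, params),
        "IDH_NADP": _idh_nadp_rate(state, params),
        "KGDH": _kgdh_rate(state, params),
        "SDH": sdh_rate(state, params),
        "MDH": _mdh_rate(state, params),
        "ME": _me_rate(state, params),
        "PDH": _pdh_rate(state, params),
        "GDH": _gdh_rate(state, params),
        "MalT": _malt_rate(state, params),
        "CITexport": _cit_export_rate(state, params),
        "AKGexport": _akg_export_rate(state, params),
        "PYRexport": _pyr_export_rate(state, params),
    }


def phosphorylation_fluxes(state: np.ndarray, params) -> dict[str, float]:
    """ATP synthase, adenine-nucleotide translocase and Pi carrier rates."""
    return {
        "J_F1F0": _f1f0_rate(state, params),
        "J_ANT": _ant_rate(state, params),
        "J_PiT": _pit_rate(state, params),
        "J_Hleak": _leak_rate(state, params),
        "J_NNT": _nnt_rate(state, params),
    }
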