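"""Superoxide generation, compartmentalized scavenging and H2O2 emission.

A fraction of respiratory-chain electron flux is diverted to superoxide;
the diversion grows with membrane potential, so collapsing the potential
(for example by lipid uncoupling) lowers ROS generation per electron.
Superoxide is dismutated by MnSOD in the matrix or released and
dismutated by Cu,ZnSOD outside; H2O2 is scavenged by the glutathione
(GPx/GR) and thioredoxin (Prx/TrxR) arms in both compartments and by
catalase outside, or diffuses down its gradient.  The emitted-H2O2
observable V_H2O2 is the net outward flux across the outer boundary of
the modeled system after extra-matrix scavenging — the quantity an
Amplex-red assay sees — with a documented switch to report the raw
matrix efflux instead.

The glutathione- and thioredoxin-reductase maximal rates carry the
activity scale factors ``GR_scale`` / ``TrxR_scale`` (1 = control) in
both compartments; the DNCB / auranofin inhibition condition of the
source experiments is GR_scale = 0.15, TrxR_scale = 0.22.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .energetics import complex1_rate, etfqo_rate, sdh_rate
from .reactions import Reaction, hill_activation, mm
from .species import IDX


# ---------------------------------------------------------------------------
# superoxide generation


def superoxide_generation_total(y: np.ndarray, p) -> float:
    """Total superoxide production (mM s⁻¹ O2·⁻, matrix-volume basis)."""
    electron_flux_2e = (complex1_rate(y, p) + sdh_rate(y, p)
                        + etfqo_rate(y, p))
    redox_pressure = hill_activation(
        y[IDX["dpsi"]], p.dpsi_ros_half, p.k_ros_dpsi)
    return 2.0 * p.shunt_frac * electron_flux_2e * redox_pressure


def _rosgen_m(y, p):
    return p.ros_matrix_fraction * superoxide_generation_total(y, p)


def _rosgen_e(y, p):
    return (1.0 - p.ros_matrix_fraction) * superoxide_generation_total(y, p)


# ---------------------------------------------------------------------------
# scavenger rate laws


def _sod_m(y, p):
    return 0.5 * p.k_SOD_m * max(y[IDX["O2neg_m"]], 0.0)


def _sod_e(y, p):
    return 0.5 * p.k_SOD_e * max(y[IDX["O2neg_e"]], 0.0)


def _gpx_m(y, p):
    return (p.Vmax_GPx_m * mm(y[IDX["H2O2_m"]], p.Km_GPx_h2o2)
            * mm(y[IDX["GSH_m"]], p.Km_GPx_gsh))


def _gr_m(y, p):
    return (p.GR_scale * p.Vmax_GR_m
            * mm(y[IDX["GSSG_m"]], p.Km_GR_gssg)
            * mm(y[IDX["NADPH_m"]], p.Km_GR_nadph))


def _prx_m(y, p):
    return (p.Vmax_Prx_m * mm(y[IDX["H2O2_m"]], p.Km_Prx_h2o2)
            * mm(y[IDX["TrxSH2_m"]], p.Km_Prx_trx))


def _trxr_m(y, p):
    return (p.TrxR_scale * p.Vmax_TrxR_m
            * mm(y[IDX["TrxSS_m"]], p.Km_TrxR_trxss)
            * mm(y[IDX["NADPH_m"]], p.Km_TrxR_nadph))


def _gpx_e(y, p):
    return (p.Vmax_GPx_e * mm(y[IDX["H2O2_e"]], p.Km_GPx_h2o2)
            * mm(y[IDX["GSH_e"]], p.Km_GPx_gsh))


def _gr_e(y, p):
    # extra-matrix NADPH is a clamped boundary pool
    return (p.GR_scale * p.Vmax_GR_e
            * mm(y[IDX["GSSG_e"]], p.Km_GR_gssg)
            * mm(p.NADPH_e_fixed, p.Km_GR_nadph))


def _prx_e(y, p):
    return (p.Vmax_Prx_e * mm(y[IDX["H2O2_e"]], p.Km_Prx_h2o2)
            * mm(y[IDX["TrxSH2_e"]], p.Km_Prx_trx))


def _trxr_e(y, p):
    return (p.TrxR_scale * p.Vmax_TrxR_e
            * mm(y[IDX["TrxSS_e"]], p.Km_TrxR_trxss)
            * mm(p.NADPH_e_fixed, p.Km_TrxR_nadph))


def _cat_e(y, p):
    return p.k_CAT * max(y[IDX["H2O2_e"]], 0.0)


# ---------------------------------------------------------------------------
# inter-compartment transport


def _o2neg_efflux(y, p):
    return p.k_IMAC_o2neg * max(y[IDX["O2neg_m"]], 0.0)


def _h2o2_diffusion(y, p):
    return p.k_H2O2_diff * (y[IDX["H2O2_m"]] - y[IDX["H2O2_e"]])


def _gsh_transport(y, p):
    return p.k_GSH_transport * (y[IDX["GSH_e"]] - y[IDX["GSH_m"]])


def _h2o2_outflux(y, p):
    """Clearance across the outer boundary (the measured emission sink)."""
    return p.k_H2O2_out * max(y[IDX["H2O2_e"]], 0.0)


def build_reactions(params=None) -> list[Reaction]:
    return [
        Reaction("ROSgen_m", {"O2neg_m": +1}, _rosgen_m),
        Reaction("ROSgen_e", {"O2neg_e": +1}, _rosgen_e),
        Reaction("SOD_m", {"O2neg_m": -2, "H2O2_m": +1}, _sod_m),
        Reaction("SOD_e", {"O2neg_e": -2, "H2O2_e": +1}, _sod_e,
                 volume="e"),
        Reaction("GPx_m", {"H2O2_m": -1, "GSH_m": -2, "GSSG_m": +1}, _gpx_m),
        Reaction("GR_m", {"GSSG_m": -1, "NADPH_m": -1,
                          "GSH_m": +2, "NADP_m": +1}, _gr_m),
        Reaction("Prx_m", {"H2O2_m": -1, "TrxSH2_m": -1, "TrxSS_m": +1},
                 _prx_m),
        Reaction("TrxR_m", {"TrxSS_m": -1, "NADPH_m": -1, "TrxSH2_m": +1,
                            "NADP_m": +1}, _trxr_m),
        Reaction("GPx_e", {"H2O2_e": -1, "GSH_e": -2, "GSSG_e": +1}, _gpx_e,
                 volume="e"),
        Reaction("GR_e", {"GSSG_e": -1, "GSH_e": +2}, _gr_e, volume="e"),
        Reaction("Prx_e", {"H2O2_e": -1, "TrxSH2_e": -1, "TrxSS_e": +1},
                 _prx_e, volume="e"),
        Reaction("TrxR_e", {"TrxSS_e": -1, "TrxSH2_e": +1}, _trxr_e,
                 volume="e"),
        Reaction("CAT", {"H2O2_e": -1}, _cat_e, volume="e"),
        Reaction("O2neg_efflux", {"O2neg_m": -1, "O2neg_e": +1},
                 _o2neg_efflux),
        Reaction("H2O2_diff", {"H2O2_m": -1, "H2O2_e": +1}, _h2o2_diffusion),
        Reaction("GSH_transport", {"GSH_e": -1, "GSH_m": +1}, _gsh_transport),
        Reaction("H2O2_out", {"H2O2_e": -1}, _h2o2_outflux, volume="e"),
    ]


# ---------------------------------------------------------------------------
# public flux views


class RosGeneration(NamedTuple):
    total: float
    matrix_side: float
    extra_side: float


def ros_generation_flux(state: np.ndarray, params) -> RosGeneration:
    """Superoxide production split by release side (mM s⁻¹, matrix basis)."""
    total = superoxide_generation_total(state, params)
    m = params.ros_matrix_fraction * total
    return RosGeneration(total, m, total - m)


def scavenging_fluxes(state: np.ndarray, params) -> dict[str, float]:
    """All scavenger reaction rates, per their source compartment."""
    return {
        "J_SODm": _sod_m(state, params),
        "J_SODe": _sod_e(state, params),
        "J_GPX": _gpx_m(state, params),
        "J_GR": _gr_m(state, params),
        "J_Prx": _prx_m(state, params),
        "J_TrxR": _trxr_m(state, params),
        "J_GPXe": _gpx_e(state, params),
        "J_GRe": _gr_e(state, params),
        "J_Prxe": _prx_e(state, params),
        "J_TrxRe": _trxr_e(state, params),
        "J_CAT": _cat_e(state, params),
        "J_H2O2_diff": _h2o2_diffusion(state, params),
        "J_O2neg_efflux": _o2neg_efflux(state, params),
        "J_GSH_transport": _gsh_transport(state, params),
    }


def h2o2_emission(state: np.ndarray, params,
                  convention: str = "outer") -> float:
    """V_H2O2 in µM s⁻¹, referenced to matrix volume.

    ``convention='outer'`` (default) reports the flux crossing the outer
    boundary of the modeled system, net of extra-matrix scavenging — the
    Amplex-red-visible emission.  ``convention='matrix_efflux'`` reports
    the raw H2O2 diffusion flux out of the matrix instead.
    """
    if convention == "outer":
        per_extra = _h2o2_outflux(state, params)  # mM/s in extra volume
        per_matrix = per_extra * params.volume_ratio_extra_to_matrix
    elif convention == "matrix_efflux":
        per_matrix = _h2o2_diffusion(state, params)
    else:
        raise ValueError(f"unknown emission convention {convention!r}")
    return 1000.0 * per_matrix
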