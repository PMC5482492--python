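"""Model assembly: full right-hand side, conserved pools, flux vector.

The complete ODE system is the stoichiometry-weighted sum of every rate
law from the beta-oxidation, energetics and ROS/redox modules, with
cross-membrane fluxes scaled by the compartment volume ratio and the
membrane-potential equation given by the capacitance-weighted sum of
charge-translocating fluxes.  Clamped species (protocol boundary
conditions) have their derivative zeroed, so rate laws read the clamped
value transparently.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import betaox, energetics, redox
from .parameters import ParameterSet, default_parameters
from .reactions import build_stoichiometry
from .species import (CHAIN_LENGTHS, DEFAULT_CLAMPED, IDX,
                      SPECIES_NAMES, STAGES, acyl_name, dict_to_state)


class ModelEvaluationError(RuntimeError):
    """A rate law produced a non-finite value."""


class Model:
    """The assembled two-compartment energy-redox + beta-oxidation model."""

    def __init__(self, params: ParameterSet | None = None):
        self.params = params if params is not None else default_parameters()
        self.reactions = (betaox.build_reactions(self.params)
                          + energetics.build_reactions(self.params)
                          + redox.build_reactions(self.params))
        names = [r.name for r in self.reactions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate reaction names in model assembly")
        self.reaction_names = names
        self.rxn_index = {n: j for j, n in enumerate(names)}
        self.N = build_stoichiometry(
            self.reactions,
            self.params.volume_ratio_extra_to_matrix,
            self.params.membrane_capacitance,
        )
        self._rate_fns = [r.rate for r in self.reactions]

    def with_params(self, params: ParameterSet) -> "Model":
        return Model(params)

    # -- evaluation ---------------------------------------------------------

    def rates(self, y: np.ndarray) -> np.ndarray:
        p = self.params
        v = np.array([f(y, p) for f in self._rate_fns])
        if not np.isfinite(v).all():
            bad = [self.reaction_names[j] for j in np.flatnonzero(
                ~np.isfinite(v))]
            involved = sorted({sp for name in bad
                               for sp in self.rxn_stoich(name)})
            state_info = {sp: float(y[IDX[sp]]) for sp in involved}
            raise ModelEvaluationError(
                f"non-finite rate in reaction(s) {bad}; "
                f"involved state entries: {state_info}")
        return v

    def rxn_stoich(self, name: str) -> dict[str, float]:
        return self.reactions[self.rxn_index[name]].stoich

    def rhs(self, t: float, y: np.ndarray,
            clamped_idx: np.ndarray | None = None) -> np.ndarray:
        dy = self.N @ self.rates(y)
        if clamped_idx is not None and len(clamped_idx):
            dy[clamped_idx] = 0.0
        return dy

    # -- observables --------------------------------------------------------

    def fluxes(self, y: np.ndarray) -> pd.Series:
        """Instantaneous FluxVector: every reaction rate plus derived
        observables (VO2 components in mM s⁻¹, V_H2O2 in µM s⁻¹, g_H)."""
        v = self.rates(y)
        out = dict(zip(self.reaction_names, v))
        resp = energetics.respiration_flux(y, self.params)
        out["VO2_NADH"] = resp.VO2_NADH
        out["VO2_succ"] = resp.VO2_succ
        out["VO2_ETF"] = resp.VO2_ETF
        out["VO2_total"] = resp.VO2_total
        out["V_H2O2"] = redox.h2o2_emission(y, self.params, "outer")
        out["V_H2O2_matrix_efflux"] = redox.h2o2_emission(
            y, self.params, "matrix_efflux")
        out["V_O2neg_gen"] = redox.superoxide_generation_total(y, self.params)
        out["g_H"] = energetics.proton_conductance(
            y[IDX["PCoA_cyt"]], self.params)
        out["pmf"] = energetics.pmf(y, self.params)
        out["J_Hleak"] = out["Hleak"]
        out["J_F1F0"] = out["F1F0"]
        out["J_ANT"] = out["ANT"]
        return pd.Series(out)

    def charge_flux_sum(self, y: np.ndarray) -> float:
        """Net outward charge flux (mM s⁻¹): the d(dpsi)/dt numerator."""
        v = self.rates(y)
        return float(sum(r.charge * v[j]
                         for j, r in enumerate(self.reactions) if r.charge))


# ---------------------------------------------------------------------------
# spec-level free functions


_MODEL_CACHE: dict[int, Model] = {}


def _cached_model(params: ParameterSet | None) -> Model:
    key = id(params)
    mdl = _MODEL_CACHE.get(key)
    if mdl is None or (params is not None and mdl.params is not params):
        mdl = Model(params)
        _MODEL_CACHE.clear()
        _MODEL_CACHE[key] = mdl
    return mdl


def assemble_rhs(state: np.ndarray, t: float, params: ParameterSet,
                 protocol=None) -> np.ndarray:
    """d(state)/dt at time ``t`` under the given protocol's clamps."""
    if (state[:-1] < 0).any():
        neg = [SPECIES_NAMES[i] for i in np.flatnonzero(state[:-1] < 0)]
        raise ValueError(f"negative concentrations in state: {neg}")
    mdl = _cached_model(params)
    clamped = clamp_indices(protocol.clamped if protocol is not None
                            else DEFAULT_CLAMPED)
    return mdl.rhs(t, state, clamped)


def clamp_indices(clamped: Iterable[str] | Mapping[str, float]) -> np.ndarray:
    names = list(clamped)
    unknown = [n for n in names if n not in IDX]
    if unknown:
        raise ValueError(f"unknown clamped species: {unknown}")
    return np.array([IDX[n] for n in names], dtype=int)


def conserved_pools(state: np.ndarray, params: ParameterSet,
                    ) -> dict[str, float]:
    """Totals of every conserved moiety pool (mM, matrix-volume basis).

    Cross-compartment pools (glutathione, carnitine) are volume-weighted
    with the extra-to-matrix volume ratio; per-compartment glutathione
    totals are also reported (they are conserved individually only when
    the GSH transport conductance is zero).
    """
    y = state
    r = params.volume_ratio_extra_to_matrix
    coa = y[IDX["CoASH"]] + y[IDX["AcCoA"]]
    for n in CHAIN_LENGTHS:
        for stage in STAGES:
            coa += y[IDX[acyl_name(n, stage)]]
    gsh_m = y[IDX["GSH_m"]] + 2 * y[IDX["GSSG_m"]]
    gsh_e = y[IDX["GSH_e"]] + 2 * y[IDX["GSSG_e"]]
    return {
        "NAD": y[IDX["NADH_m"]] + y[IDX["NAD_m"]],
        "NADP": y[IDX["NADPH_m"]] + y[IDX["NADP_m"]],
        "glutathione_m": gsh_m,
        "glutathione_e": gsh_e,
        "glutathione_total": gsh_m + r * gsh_e,
        "Trx_m": y[IDX["TrxSH2_m"]] + y[IDX["TrxSS_m"]],
        "Trx_e": y[IDX["TrxSH2_e"]] + y[IDX["TrxSS_e"]],
        "CoA": coa,
        "carnitine_total": (y[IDX["carnitine_m"]] + y[IDX["C16carnitine_m"]]
                            + r * (y[IDX["carnitine_e"]]
                                   + y[IDX["C16carnitine_e"]])),
        "ETF": y[IDX["ETF_FAD"]] + y[IDX["ETF_FADH2"]],
        "adenine_m": y[IDX["ATP_m"]] + y[IDX["ADP_m"]],
    }


def pool_targets(params: ParameterSet) -> dict[str, float]:
    """Pool totals as declared in the parameter set."""
    r = params.volume_ratio_extra_to_matrix
    return {
        "NAD": params.NAD_tot,
        "NADP": params.NADP_tot,
        "glutathione_m": params.GSH_tot_m,
        "glutathione_e": params.GSH_tot_e,
        "glutathione_total": params.GSH_tot_m + r * params.GSH_tot_e,
        "Trx_m": params.Trx_tot_m,
        "Trx_e": params.Trx_tot_e,
        "CoA": params.CoA_tot,
        "carnitine_total": params.carnitine_tot,
        "ETF": params.ETF_tot,
        "adenine_m": params.adenine_tot_m,
    }


def check_pool_consistency(state: np.ndarray, params: ParameterSet,
                           rtol: float = 1e-6) -> None:
    pools = conserved_pools(state, params)
    targets = pool_targets(params)
    for name, target in targets.items():
        if abs(pools[name] - target) > rtol * max(abs(target), 1e-12):
            raise ValueError(
                f"pool {name!r} inconsistent with declared total: "
                f"{pools[name]:.9g} vs {target:.9g}")


# ---------------------------------------------------------------------------
# initial conditions


def load_initial_state(
    source: str | Path | Mapping[str, float] | None = None,
) -> np.ndarray:
    """Initial concentrations (mM) and dpsi (mV) as a state array."""
    if source is None:
        text = resources.files("mitobetaox.data").joinpath(
            "initial_state_default.yml").read_text()
        doc = yaml.safe_load(text)
    elif isinstance(source, Mapping):
        doc = dict(source)
    else:
        doc = yaml.safe_load(Path(source).read_text())
    return dict_to_state({k: float(v) for k, v in doc.items()})


def default_initial_state() -> np.ndarray:
    return load_initial_state(None)


def trajectory_frame(times: np.ndarray, states: np.ndarray) -> pd.DataFrame:
    """Trajectory as a DataFrame, one column per canonical species."""
    df = pd.DataFrame(states, columns=list(SPECIES_NAMES))
    df.insert(0, "time_s", times)
    return df
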