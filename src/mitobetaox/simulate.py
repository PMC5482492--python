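"""Stiff integration, steady-state search and the protocol experiments.

Steady states are found the way the source simulations were run: long
stiff integration (BDF) until the relative time derivative of every
free variable falls below 1e-10 s⁻¹, with an optional Levenberg-
Marquardt polish that must agree with the integrated state.  The
residual uses |dx/dt| / max(|x|, 1e-12 mM) to avoid division blow-ups
for near-zero species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import Model, clamp_indices, default_initial_state
from .protocols import (STATE3_ADP, STATE4_ADP, ProtocolSpec,
                        state_protocol)
from .species import IDX, N_SPECIES, SPECIES_NAMES

RESIDUAL_TOL = 1e-10   # s^-1, steady-state criterion
RESIDUAL_FLOOR = 1e-12  # mM, denominator floor
NEGATIVITY_TOL = -1e-9  # mM, abort threshold for negative excursions


class IntegrationFailure(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# helpers


def steady_state_residual(model: Model, y: np.ndarray,
                          clamped_idx: np.ndarray) -> float:
    """Max over free variables of |dx/dt| / max(|x|, floor), in s⁻¹."""
    dy = model.rhs(0.0, y, clamped_idx)
    denom = np.maximum(np.abs(y), RESIDUAL_FLOOR)
    rel = np.abs(dy) / denom
    return float(rel.max())


def _apply_clamps(y: np.ndarray, clamped: dict[str, float]) -> np.ndarray:
    y = y.copy()
    for name, value in clamped.items():
        y[IDX[name]] = value
    return y


def _check_negativity(y: np.ndarray, t: float) -> None:
    conc = y[:-1]  # all but dpsi
    worst = conc.min()
    if worst < NEGATIVITY_TOL:
        i = int(np.argmin(conc))
        raise IntegrationFailure(
            f"species {SPECIES_NAMES[i]} went negative "
            f"({worst:.3e} mM) at t={t:.6g} s")


def _clip_tiny_negatives(y: np.ndarray) -> np.ndarray:
    y = y.copy()
    conc = y[:-1]
    mask = (conc < 0) & (conc > NEGATIVITY_TOL)
    conc[mask] = 0.0
    y[:-1] = conc
    return y


#: concentrations below this (mM) are treated as exactly zero when
#: searching for a steady state: species emptied by a protocol (e.g. the
#: beta-oxidation intermediates at zero PCoA) decay exponentially and
#: their floored relative derivative would otherwise never converge.
#: 1e-12 mM is far below one molecule per mitochondrion.
SNAP_TOL = 1e-12


def _snap_tiny(y: np.ndarray) -> np.ndarray:
    y = _clip_tiny_negatives(y)
    conc = y[:-1]
    conc[np.abs(conc) < SNAP_TOL] = 0.0
    y[:-1] = conc
    return y


# ---------------------------------------------------------------------------
# trajectory integration


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # (n_times, n_species)
    protocol: ProtocolSpec

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES_NAMES))
        df.insert(0, "time_s", self.times)
        return df

    def __getitem__(self, species: str) -> np.ndarray:
        return self.states[:, IDX[species]]


def integrate(model: Model, protocol: ProtocolSpec,
              t_span: tuple[float, float], initial: np.ndarray,
              rtol: float = 1e-8, atol: float = 1e-12,
              method: str = "BDF") -> Trajectory:
    """Integrate the model under a protocol, handling timed events.

    The solver restarts at every event with updated clamps and boluses;
    the state immediately after an addition event equals the state
    before plus the declared bolus (clamps excepted).
    """
    t0, t1 = t_span
    clamps = dict(protocol.clamped)
    y = _apply_clamps(np.asarray(initial, dtype=float), clamps)
    if protocol.output_times is not None:
        out_times = np.asarray(
            [t for t in protocol.output_times if t0 <= t <= t1], dtype=float)
    else:
        out_times = np.linspace(t0, t1, 201)
    if t1 == t0:
        return Trajectory(np.array([t0]), y[None, :].copy(), protocol)

    events = [e for e in protocol.events if t0 < e.time < t1]
    seg_edges = [t0] + [e.time for e in events] + [t1]

    times_acc: list[np.ndarray] = []
    states_acc: list[np.ndarray] = []
    if out_times.size and out_times[0] == t0:
        times_acc.append(np.array([t0]))
        states_acc.append(y[None, :].copy())

    for k, (ta, tb) in enumerate(zip(seg_edges[:-1], seg_edges[1:])):
        cidx = clamp_indices(clamps)
        free = np.setdiff1d(np.arange(N_SPECIES), cidx)
        template = y.copy()

        def rhs_free(t, u, _template=template, _free=free):
            _template[_free] = u
            return model.rhs(t, _template, None)[_free]

        def jac_free(t, u, _f=rhs_free):
            # fixed-relative-step dense finite differences; more robust
            # than the solver's adaptive scheme when some species are
            # inert under the current clamps (zero Jacobian columns)
            f0 = _f(t, u)
            n = u.size
            J = np.empty((n, n))
            for j in range(n):
                h = 1e-8 * max(abs(u[j]), 1e-6)
                up = u.copy()
                up[j] += h
                J[:, j] = (_f(t, up) - f0) / h
            return J

        seg_out = out_times[(out_times > ta) & (out_times <= tb)]
        t_eval = np.unique(np.concatenate([seg_out, [tb]]))
        sol = solve_ivp(rhs_free, (ta, tb), y[free], method=method,
                        rtol=rtol, atol=atol, t_eval=t_eval, jac=jac_free)
        if not sol.success:
            dy = model.rhs(tb, y, cidx)
            i = int(np.argmax(np.abs(dy)))
            raise IntegrationFailure(
                f"solver failed in segment [{ta:g}, {tb:g}] s: "
                f"{sol.message}; largest derivative on "
                f"{SPECIES_NAMES[i]} ({dy[i]:.3e})")
        seg_states = np.repeat(template[None, :], sol.t.size, axis=0)
        seg_states[:, free] = sol.y.T
        for j, tj in enumerate(sol.t):
            _check_negativity(seg_states[j], tj)
        keep = np.isin(sol.t, seg_out)
        if keep.any():
            times_acc.append(sol.t[keep])
            states_acc.append(seg_states[keep].copy())
        y = _clip_tiny_negatives(seg_states[-1])
        if k < len(events):
            ev = events[k]
            for name, bolus in ev.additions.items():
                y[IDX[name]] += bolus
            clamps.update(ev.clamp_changes)
            y = _apply_clamps(y, clamps)

    times = np.concatenate(times_acc) if times_acc else np.array([t1])
    states = (np.vstack(states_acc) if states_acc
              else y[None, :].copy())
    return Trajectory(times, states, protocol)


# ---------------------------------------------------------------------------
# steady state


@dataclass
class SteadyStateResult:
    state: np.ndarray
    fluxes: pd.Series
    converged: bool
    residual: float
    elapsed_model_time: float
    protocol: ProtocolSpec = field(repr=False, default=None)

    def __post_init__(self):
        self.converged = bool(self.residual < RESIDUAL_TOL)


def _lm_polish(model: Model, y: np.ndarray, clamped_idx: np.ndarray,
               ) -> np.ndarray | None:
    """Levenberg-Marquardt polish of the free variables; returns the
    polished state, or None if the polish moved away or failed."""
    free = np.setdiff1d(np.arange(N_SPECIES), clamped_idx)
    y_ref = y.copy()
    scale = np.maximum(np.abs(y_ref[free]), 1e-9)

    def fun(u):
        yy = y_ref.copy()
        yy[free] = u * scale
        return model.rhs(0.0, yy, clamped_idx)[free]

    try:
        sol = root(fun, y_ref[free] / scale, method="lm",
                   options={"xtol": 1e-14, "ftol": 1e-14, "maxiter": 200})
    except Exception:
        return None
    y_new = y_ref.copy()
    y_new[free] = sol.x * scale
    # reject polishes that wander off the integrated state
    rel_move = np.max(np.abs(y_new[free] - y_ref[free])
                      / np.maximum(np.abs(y_ref[free]), 1e-6))
    if rel_move > 0.05 or (y_new[:-1] < NEGATIVITY_TOL).any():
        return None
    return _clip_tiny_negatives(y_new)


def find_steady_state(model: Model, protocol: ProtocolSpec,
                      initial: np.ndarray | None = None,
                      max_time: float = 1e7,
                      tol: float = RESIDUAL_TOL) -> SteadyStateResult:
    """Integrate to steady state (residual < 1e-10 s⁻¹) under a protocol.

    Non-convergence within ``max_time`` of model time returns
    ``converged=False`` with the best state reached, not an exception.
    """
    if protocol.mode != "steady_state":
        raise ValueError("protocol mode must be 'steady_state'")
    y = (default_initial_state() if initial is None
         else np.asarray(initial, dtype=float))
    y = _apply_clamps(y, protocol.clamped)
    cidx = clamp_indices(protocol.clamped)

    def try_polish(y, res):
        polished = _lm_polish(model, y, cidx)
        if polished is not None:
            polished = _snap_tiny(polished)
            res_p = steady_state_residual(model, polished, cidx)
            if res_p < res:
                return polished, res_p
        return y, res

    res = steady_state_residual(model, y, cidx)
    elapsed = 0.0
    window = 200.0
    while res >= tol and elapsed < max_time:
        window = min(window, max_time - elapsed)
        quiet = ProtocolSpec(clamped=dict(protocol.clamped),
                             output_times=[], mode="timecourse")
        try:
            traj_model = integrate(model, quiet, (0.0, window), y,
                                   rtol=1e-8, atol=1e-11)
        except IntegrationFailure:
            y, res = try_polish(y, res)
            break
        y = _snap_tiny(traj_model.states[-1])
        elapsed += window
        window *= 10.0
        res = steady_state_residual(model, y, cidx)
        if res < 1e-2 and res >= tol:
            y, res = try_polish(y, res)

    return SteadyStateResult(
        state=y, fluxes=model.fluxes(y), converged=res < tol,
        residual=res, elapsed_model_time=elapsed, protocol=protocol)


# ---------------------------------------------------------------------------
# protocol experiments


#: steady-state observables reported by scans
_SCAN_COLUMNS = ("VO2_total", "VO2_NADH", "VO2_succ", "VO2_ETF", "V_H2O2",
                 "V_O2neg_gen", "g_H", "J_Hleak", "J_F1F0", "J_ANT")
_SCAN_STATE = ("GSH_m", "TrxSH2_m", "NADPH_m", "NADH_m", "dpsi", "H2O2_m")


def _scaled_model(model: Model, activity_scales: dict[str, float] | None,
                  ) -> Model:
    if not activity_scales:
        return model
    return model.with_params(model.params.replace(**activity_scales))


def dose_response_scan(model: Model, pcoa_grid, adp_level: float,
                       activity_scales: dict[str, float] | None = None,
                       warm_start: bool = True,
                       initial: np.ndarray | None = None,
                       max_time: float = 1e7) -> pd.DataFrame:
    """Steady-state dose-response over a clamped-PCoA grid (mM).

    One converged steady state per grid point; by default each point is
    warm-started from the previous one (continuation).  Returns one row
    per PCoA with respiration components, H2O2 emission, scavenger pools,
    membrane potential, proton conductance and convergence diagnostics.
    """
    mdl = _scaled_model(model, activity_scales)
    rows = []
    y_start = initial
    for pcoa in pcoa_grid:
        proto = state_protocol(pcoa_mM=float(pcoa), adp_mM=adp_level)
        result = find_steady_state(mdl, proto, initial=y_start,
                                   max_time=max_time)
        if warm_start and result.converged:
            y_start = result.state
        row = {"PCoA_uM": 1000.0 * float(pcoa),
               "converged": result.converged,
               "residual": result.residual}
        for cname in _SCAN_COLUMNS:
            row[cname] = float(result.fluxes[cname])
        for sname in _SCAN_STATE:
            row[sname] = float(result.state[IDX[sname]])
        rows.append(row)
    return pd.DataFrame(rows)


def compute_rcr(vo2_state3: float, vo2_state4: float) -> float:
    """Respiratory control ratio, state-3 over state-4 VO2."""
    if vo2_state4 <= 0:
        raise ValueError("state-4 VO2 must be positive")
    return vo2_state3 / vo2_state4


def rcr_at(model: Model, pcoa_mM: float,
           initial: np.ndarray | None = None,
           max_time: float = 1e7) -> tuple[float, SteadyStateResult,
                                           SteadyStateResult]:
    """RCR at one clamped PCoA: VO2(state 3) / VO2(state 4)."""
    s4 = find_steady_state(
        model, state_protocol(pcoa_mM, STATE4_ADP), initial, max_time)
    s3 = find_steady_state(
        model, state_protocol(pcoa_mM, STATE3_ADP), s4.state, max_time)
    rcr = compute_rcr(s3.fluxes["VO2_total"], s4.fluxes["VO2_total"])
    return rcr, s3, s4


#: scavenger-inhibition condition emulating DNCB (GR) and auranofin (TrxR)
INHIBITED_SCALES = {"GR_scale": 0.15, "TrxR_scale": 0.22}


def inhibition_experiment(model: Model, pcoa_mM: float = 0.04,
                          inhibited_scales: dict[str, float] | None = None,
                          max_time: float = 1e7) -> pd.DataFrame:
    """Control vs scavenger-inhibited steady states, states 4 and 3.

    Four steady states (2 activity conditions x 2 respiratory states) at
    the given clamped PCoA, reporting V_H2O2 and VO2.
    """
    scales = (INHIBITED_SCALES if inhibited_scales is None
              else inhibited_scales)
    rows = []
    for label, sc in (("control", {}), ("inhibited", scales)):
        mdl = _scaled_model(model, sc)
        warm = None
        for state_name, adp in (("state4", STATE4_ADP), ("state3",
                                                         STATE3_ADP)):
            res = find_steady_state(
                mdl, state_protocol(pcoa_mM, adp), initial=warm,
                max_time=max_time)
            warm = res.state
            rows.append({
                "condition": label, "respiratory_state": state_name,
                "GR_scale": sc.get("GR_scale", 1.0),
                "TrxR_scale": sc.get("TrxR_scale", 1.0),
                "V_H2O2": float(res.fluxes["V_H2O2"]),
                "VO2_total": float(res.fluxes["VO2_total"]),
                "converged": res.converged,
                "residual": res.residual,
            })
    return pd.DataFrame(rows)
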