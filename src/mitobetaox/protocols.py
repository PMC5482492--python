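"""Simulation protocols: clamps, timed events, respiratory states.

A protocol fixes the boundary conditions of an in-silico experiment on
isolated mitochondria: which species are clamped (cytoplasmic
palmitoyl-CoA, extra-matrix ADP, malate, glutamate, ion baselines), the
timed additions or clamp changes, and the scavenger activity scale
factors.  Respiratory states follow the convention used for the
simulated experiments: state 4 is extra-matrix ADP clamped at 5e-4 mM,
state 3 at 0.1 mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .species import IDX

#: extra-matrix ADP (mM) defining the two respiratory states
STATE4_ADP: float = 5e-4
STATE3_ADP: float = 0.1

#: baseline clamp values shared by all shipped protocols (assay medium
#: composition and ion baselines)
BASE_CLAMPS: dict[str, float] = {
    "ATP_e": 0.01,
    "ADP_e": STATE4_ADP,
    "Pi_e": 2.0,
    "Ca_m": 1e-4, "Ca_e": 1e-4,
    "Na_m": 5.0, "Na_e": 5.0,
    "H_m": 1.5849e-5, "H_e": 6.3096e-5,
    "PCoA_cyt": 0.0,
    "MAL_e": 0.5,
    "GLU_m": 0.0,
}


@dataclass(frozen=True)
class Event:
    """A timed protocol action: bolus additions and/or clamp changes."""

    time: float
    clamp_changes: dict[str, float] = field(default_factory=dict)
    additions: dict[str, float] = field(default_factory=dict)


@dataclass
class ProtocolSpec:
    clamped: dict[str, float] = field(default_factory=dict)
    events: list[Event] = field(default_factory=list)
    activity_scales: dict[str, float] = field(default_factory=dict)
    output_times: list[float] | None = None
    mode: str = "steady_state"  # steady_state | timecourse

    def __post_init__(self) -> None:
        for name, value in self.clamped.items():
            if name not in IDX:
                raise ValueError(f"unknown clamped species {name!r}")
            if value < 0:
                raise ValueError(
                    f"clamp value for {name} must be >= 0, got {value}")
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        for ev in self.events:
            for name in list(ev.clamp_changes) + list(ev.additions):
                if name not in IDX:
                    raise ValueError(f"unknown species in event: {name!r}")
            if any(v < 0 for v in ev.clamp_changes.values()):
                raise ValueError("clamp values must be >= 0")
        if self.mode not in ("steady_state", "timecourse"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")


def state_protocol(pcoa_mM: float = 0.0, adp_mM: float = STATE4_ADP,
                   glutamate_mM: float = 0.0, malate_mM: float = 0.5,
                   **scales: float) -> ProtocolSpec:
    """Steady-state protocol at fixed clamps.

    ``pcoa_mM`` is the clamped cytoplasmic palmitoyl-CoA; ``adp_mM``
    selects the respiratory state.  Keyword scale factors (``GR_scale``,
    ``TrxR_scale``) are applied to the parameter set by the simulation
    layer.
    """
    clamps = dict(BASE_CLAMPS)
    clamps["PCoA_cyt"] = pcoa_mM
    clamps["ADP_e"] = adp_mM
    clamps["MAL_e"] = malate_mM
    clamps["GLU_m"] = glutamate_mM
    return ProtocolSpec(clamped=clamps, activity_scales=dict(scales),
                        mode="steady_state")


def state4_protocol(pcoa_mM: float = 0.0, **kw) -> ProtocolSpec:
    return state_protocol(pcoa_mM, STATE4_ADP, **kw)


def state3_protocol(pcoa_mM: float = 0.0, **kw) -> ProtocolSpec:
    return state_protocol(pcoa_mM, STATE3_ADP, **kw)


def state_transition_protocol(
    pcoa_mM: float,
    t_pcoa: float = 100.0,
    t_glutamate: float = 400.0,
    t_adp: float = 700.0,
    glutamate_mM: float = 5.0,
    adp_mM: float = 1.0,
    t_end: float = 1000.0,
    n_out: int = 501,
) -> ProtocolSpec:
    """State 4 -> 3 transition timecourse.

    Mitochondria with malate alone, then clamped PCoA (beta-oxidation
    substrate), then glutamate, then an ADP step triggering state 3.
    PCoA is clamped, not consumed, mirroring the simulated (rather than
    experimental) protocol.
    """
    clamps = dict(BASE_CLAMPS)
    events = [
        Event(t_pcoa, clamp_changes={"PCoA_cyt": pcoa_mM}),
        Event(t_glutamate, clamp_changes={"GLU_m": glutamate_mM}),
        Event(t_adp, clamp_changes={"ADP_e": adp_mM}),
    ]
    out = [t_end * i / (n_out - 1) for i in range(n_out)]
    return ProtocolSpec(clamped=clamps, events=events, output_times=out,
                        mode="timecourse")
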