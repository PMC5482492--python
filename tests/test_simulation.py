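import numpy as np
import pytest

from mitobetaox.model import default_initial_state
from mitobetaox.protocols import (STATE4_ADP, Event,
                                  ProtocolSpec, state4_protocol,
                                  state_protocol,
                                  state_transition_protocol)
from mitobetaox.simulate import (RESIDUAL_TOL, compute_rcr,
                                 find_steady_state, integrate)
from mitobetaox.species import IDX


class TestProtocolSpec:
    def test_event_times_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            ProtocolSpec(events=[Event(10.0), Event(5.0)])

    def test_clamp_values_nonnegative(self):
        with pytest.raises(ValueError):
            ProtocolSpec(clamped={"PCoA_cyt": -0.01})

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ProtocolSpec(clamped={"caffeine": 1.0})


class TestIntegrate:
    def test_zero_length_span_returns_initial_state(self, model, y0):
        proto = ProtocolSpec(clamped=dict(state4_protocol(0.0).clamped),
                             mode="timecourse")
        traj = integrate(model, proto, (0.0, 0.0), y0)
        clamped_applied = y0.copy()
        for name, v in proto.clamped.items():
            clamped_applied[IDX[name]] = v
        assert traj.times.shape == (1,)
        np.testing.assert_array_equal(traj.states[0], clamped_applied)

    def test_event_addition_is_atomic(self, model, y0):
        # state just after a bolus equals state just before plus the bolus
        bolus = 0.05
        proto = ProtocolSpec(
            clamped=dict(state4_protocol(0.0).clamped),
            events=[Event(1.0, additions={"GSSG_e": bolus})],
            output_times=[0.999, 1.001],
            mode="timecourse")
        traj = integrate(model, proto, (0.0, 2.0), y0)
        jump = traj["GSSG_e"][1] - traj["GSSG_e"][0]
        assert jump == pytest.approx(bolus, rel=1e-3)

    def test_event_clamp_change_takes_effect(self, model, y0):
        proto = ProtocolSpec(
            clamped=dict(state4_protocol(0.0).clamped),
            events=[Event(1.0, clamp_changes={"PCoA_cyt": 0.02})],
            output_times=[0.5, 1.5],
            mode="timecourse")
        traj = integrate(model, proto, (0.0, 2.0), y0)
        assert traj["PCoA_cyt"][0] == 0.0
        assert traj["PCoA_cyt"][1] == 0.02


class TestFindSteadyState:
    def test_requires_steady_state_mode(self, model, y0):
        proto = ProtocolSpec(clamped={}, mode="timecourse")
        with pytest.raises(ValueError):
            find_steady_state(model, proto, y0)

    def test_already_converged_returns_immediately(self, model, steady):
        res = steady.get(0.01, STATE4_ADP)
        again = find_steady_state(model, res.protocol, res.state)
        assert again.converged
        assert again.elapsed_model_time == 0.0
        assert again.residual < RESIDUAL_TOL

    def test_nonconvergence_returns_flag_not_exception(self, model, y0):
        res = find_steady_state(model, state4_protocol(0.01), y0,
                                max_time=1.0)
        assert res.converged is False
        assert res.state.shape == y0.shape
        assert np.isfinite(res.residual)

    def test_warm_and_cold_starts_agree(self, model, steady):
        warm = steady.get(0.02, STATE4_ADP)  # warm-started via cache
        cold = find_steady_state(model, state_protocol(0.02, STATE4_ADP))
        assert cold.converged and warm.converged
        # VO2 agrees to <0.01%; emission inherits the nearly flat slow
        # manifold of the inter-compartment thiol pools at the
        # 1e-10 s^-1 residual, so its reproducibility bound is ~0.5%
        assert cold.fluxes["VO2_total"] == pytest.approx(
            warm.fluxes["VO2_total"], rel=1e-4)
        assert cold.fluxes["V_H2O2"] == pytest.approx(
            warm.fluxes["V_H2O2"], rel=5e-3)


class TestComputeRcr:
    def test_equal_fluxes_give_unity(self):
        assert compute_rcr(1.5, 1.5) == 1.0

    def test_zero_state4_rejected(self):
        with pytest.raises(ValueError):
            compute_rcr(1.0, 0.0)


@pytest.fixture(scope="module")
def trajectories(model):
    y0 = default_initial_state()
    out = {}
    for pcoa in (0.01, 0.025):
        proto = state_transition_protocol(pcoa)
        out[pcoa] = integrate(model, proto, (0.0, 1000.0), y0)
    return out


class TestStateTransitionTimecourse:
    """The simulated fluorimeter protocol: malate baseline, then clamped
    PCoA, then glutamate, then ADP (state 4 -> 3 transition)."""

    @staticmethod
    def _nadh_at(traj, t):
        return traj["NADH_m"][np.searchsorted(traj.times, t)]

    def test_glutamate_raises_then_adp_drops_nadh(self, trajectories):
        traj = trajectories[0.01]
        pre_glu = self._nadh_at(traj, 399)
        post_glu = self._nadh_at(traj, 699)
        post_adp = self._nadh_at(traj, 999)
        assert post_glu > pre_glu + 0.05
        assert post_adp < post_glu - 0.1

    def test_uncoupling_oxidizes_nadh_during_lipid_phase(self,
                                                         trajectories):
        # stronger NADH oxidation before glutamate at 25 uM than 10 uM
        low = self._nadh_at(trajectories[0.01], 399)
        high = self._nadh_at(trajectories[0.025], 399)
        assert high < low

    def test_state_transition_excursion_blunted_at_high_pcoa(
            self, trajectories):
        # total NADH excursion of the state 4 -> 3 transition, measured
        # from the lipid-loaded baseline, shrinks with uncoupling
        def excursion(traj):
            return (self._nadh_at(traj, 399) - self._nadh_at(traj, 999))
        assert excursion(trajectories[0.025]) < excursion(
            trajectories[0.01])
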