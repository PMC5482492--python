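import numpy as np
import pytest

from mitobetaox.model import (Model, ModelEvaluationError, assemble_rhs,
                              conserved_pools, check_pool_consistency,
                              pool_targets)
from mitobetaox.protocols import ProtocolSpec, state4_protocol
from mitobetaox.simulate import integrate
from mitobetaox.species import (CHAIN_LENGTHS, IDX, SPECIES_NAMES, STAGES,
                                acyl_name)


class TestConservedPools:
    def test_initial_condition_matches_declared_totals(self, model, y0):
        check_pool_consistency(y0, model.params)

    def test_stoichiometric_identity_glutathione(self, model, y0):
        # moving mass between GSH and GSSG leaves the pool total unchanged
        y = y0.copy()
        y[IDX["GSSG_m"]] *= 2
        y[IDX["GSH_m"]] -= 2 * y0[IDX["GSSG_m"]]
        pools = conserved_pools(y, model.params)
        assert pools["glutathione_m"] == pytest.approx(
            conserved_pools(y0, model.params)["glutathione_m"], rel=1e-12)

    def test_pool_sum_derivatives_are_zero(self, model, y0):
        # every conserved moiety's summed derivative vanishes identically,
        # also after shifting mass within the pool
        proto = state4_protocol(0.01)
        for y in (y0, _shift_within_pools(y0)):
            dy = assemble_rhs(y, 0.0, model.params, proto)
            r = model.params.volume_ratio_extra_to_matrix
            assert abs(dy[IDX["NADH_m"]] + dy[IDX["NAD_m"]]) < 1e-12
            assert abs(dy[IDX["NADPH_m"]] + dy[IDX["NADP_m"]]) < 1e-12
            assert abs(dy[IDX["ETF_FAD"]] + dy[IDX["ETF_FADH2"]]) < 1e-12
            assert abs(dy[IDX["ATP_m"]] + dy[IDX["ADP_m"]]) < 1e-12
            carn = (dy[IDX["carnitine_m"]] + dy[IDX["C16carnitine_m"]]
                    + r * (dy[IDX["carnitine_e"]]
                           + dy[IDX["C16carnitine_e"]]))
            assert abs(carn) < 1e-12
            coa = dy[IDX["CoASH"]] + dy[IDX["AcCoA"]] + sum(
                dy[IDX[acyl_name(n, s)]]
                for n in CHAIN_LENGTHS for s in STAGES)
            assert abs(coa) < 1e-12
            gsh = (dy[IDX["GSH_m"]] + 2 * dy[IDX["GSSG_m"]]
                   + r * (dy[IDX["GSH_e"]] + 2 * dy[IDX["GSSG_e"]]))
            assert abs(gsh) < 1e-10

    def test_pool_drift_along_trajectory(self, model, y0):
        proto = ProtocolSpec(clamped=dict(state4_protocol(0.01).clamped),
                             mode="timecourse")
        traj = integrate(model, proto, (0.0, 100.0), y0)
        before = conserved_pools(traj.states[0], model.params)
        after = conserved_pools(traj.states[-1], model.params)
        for name, v0 in before.items():
            if name in ("glutathione_m", "glutathione_e"):
                continue  # exchanged between compartments
            assert after[name] == pytest.approx(v0, rel=1e-8), name


def _shift_within_pools(y0):
    y = y0.copy()
    y[IDX["NADH_m"]] += 0.05
    y[IDX["NAD_m"]] -= 0.05
    y[IDX["ETF_FADH2"]] += 0.002
    y[IDX["ETF_FAD"]] -= 0.002
    return y


class TestAssembleRhs:
    def test_no_substrate_means_inert_spiral(self, model, y0):
        y = y0.copy()
        for n in CHAIN_LENGTHS:
            for s in STAGES:
                y[IDX[acyl_name(n, s)]] = 0.0
        y[IDX["C16carnitine_m"]] = 0.0
        y[IDX["C16carnitine_e"]] = 0.0
        proto = state4_protocol(0.0)  # PCoA clamp = 0
        dy = assemble_rhs(y, 0.0, model.params, proto)
        for n in CHAIN_LENGTHS:
            for s in STAGES:
                assert dy[IDX[acyl_name(n, s)]] == 0.0
        assert dy[IDX["C16carnitine_m"]] == 0.0

    def test_clamped_species_have_zero_derivative(self, model, y0):
        proto = state4_protocol(0.02)
        dy = assemble_rhs(y0, 0.0, model.params, proto)
        for name in proto.clamped:
            assert dy[IDX[name]] == 0.0

    def test_negative_state_rejected_with_names(self, model, y0):
        y = y0.copy()
        y[IDX["GSH_m"]] = -0.1
        with pytest.raises(ValueError, match="GSH_m"):
            assemble_rhs(y, 0.0, model.params, state4_protocol(0.0))

    def test_nonfinite_rate_names_reaction_and_state(self, model, y0):
        y = y0.copy()
        y[IDX["NADH_m"]] = np.nan
        with pytest.raises(ModelEvaluationError, match="C1"):
            model.rates(y)

    def test_charge_balance_matches_hand_summed_oracle(self, model, y0):
        # dpsi equation must equal the hand-audited sum of charge movers:
        # +10 per complex-I turnover, +6 per SDH and ETF-QO turnover,
        # -1 leak, -3 ATP synthase, -1 ANT, -1 transhydrogenase
        f = model.fluxes(y0)
        hand = (10 * f["C1"] + 6 * f["SDH"] + 6 * f["ETFQO"]
                - f["Hleak"] - 3 * f["F1F0"] - f["ANT"] - f["NNT"])
        dy = model.rhs(0.0, y0)
        assert dy[IDX["dpsi"]] == pytest.approx(
            hand / model.params.membrane_capacitance, rel=1e-12)
        assert model.charge_flux_sum(y0) == pytest.approx(hand, rel=1e-12)


class TestClampContract:
    def test_clamped_values_bit_identical_after_integration(self, model,
                                                            y0):
        proto = ProtocolSpec(clamped=dict(state4_protocol(0.015).clamped),
                             mode="timecourse")
        traj = integrate(model, proto, (0.0, 50.0), y0)
        for name, value in proto.clamped.items():
            col = traj.states[:, IDX[name]]
            assert (col == value).all(), name

    def test_trajectory_frame_has_canonical_columns(self, model, y0):
        proto = ProtocolSpec(clamped=dict(state4_protocol(0.0).clamped),
                             mode="timecourse")
        traj = integrate(model, proto, (0.0, 1.0), y0)
        frame = traj.frame()
        assert list(frame.columns) == ["time_s"] + list(SPECIES_NAMES)


class TestPoolTargets:
    def test_targets_cover_all_reported_pools(self, model, y0):
        pools = conserved_pools(y0, model.params)
        targets = pool_targets(model.params)
        assert set(targets) == set(pools)
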