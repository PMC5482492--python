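import numpy as np
import pytest

from mitobetaox.betaox import (AcylSpecies, DEHYDROGENASE_CLASSES,
                               acyl_dehydrogenase_flux,
                               betaox_stoichiometric_matrix,
                               carnitine_shuttle_fluxes, element_vectors,
                               full_oxidation_net,
                               hydratase_hadh_thiolase_fluxes)
from mitobetaox.parameters import default_parameters
from mitobetaox.protocols import STATE3_ADP
from mitobetaox.species import CHAIN_LENGTHS, IDX, acyl_name


@pytest.fixture(scope="module")
def params():
    return default_parameters()


class TestAcylSpecies:
    def test_rejects_odd_or_out_of_range_chain_length(self):
        for n in (3, 5, 17, 2, 18):
            with pytest.raises(ValueError):
                AcylSpecies(chain_length=n, oxidation_stage="acyl")

    def test_carnitine_carrier_only_at_c16(self):
        AcylSpecies(16, "acyl", carrier="carnitine")  # allowed
        with pytest.raises(ValueError):
            AcylSpecies(14, "acyl", carrier="carnitine")

    def test_dehydrogenase_classes_cover_all_chain_lengths(self):
        covered = set().union(*(c.chain_length_specificity
                                for c in DEHYDROGENASE_CLASSES))
        assert covered == set(CHAIN_LENGTHS)


class TestStoichiometricMatrix:
    def test_seven_acetyl_releasing_cycles(self):
        mat = betaox_stoichiometric_matrix()
        thiolases = [c for c in mat.columns if c.startswith("thiolase")]
        assert len(thiolases) == 7
        # terminal cycle releases two acetyl-CoA
        assert mat.loc["AcCoA", "thiolase_C4"] == 2
        assert mat.loc["AcCoA", "thiolase_C6"] == 1

    def test_net_full_oxidation_of_palmitoyl_coa(self):
        net = full_oxidation_net()
        assert net["AcCoA"] == 8
        assert net["NADH_m"] == 7 and net["NAD_m"] == -7
        assert net["ETF_FADH2"] == 7 and net["ETF_FAD"] == -7
        assert net["PCoA_cyt"] == -1
        # matrix CoASH pays for 7 thiolase cleavages plus CPT2; the CoA
        # moiety itself is conserved counting the inbound thioester
        assert net["CoASH"] == -8
        assert net["CoASH_cyt"] == 1

    def test_every_reaction_conserves_elements(self):
        mat = betaox_stoichiometric_matrix()
        elems = element_vectors(list(mat.index))
        balance = elems.T @ mat  # (element x reaction)
        assert (balance.abs() < 1e-12).all().all(), balance

    def test_net_oxidation_conserves_coa_and_carnitine_moieties(self):
        net = full_oxidation_net()
        elems = element_vectors(list(net.index))
        assert float(elems["CoA"] @ net) == 0
        assert float(elems["carnitine"] @ net) == 0
        assert float(elems["ETF"] @ net) == 0
        assert float(elems["NAD"] @ net) == 0


class TestShuttle:
    def test_zero_substrate_gives_zero_fluxes(self, params, y0):
        y = y0.copy()
        y[IDX["C16carnitine_m"]] = 0.0
        y[IDX["C16carnitine_e"]] = 0.0
        assert carnitine_shuttle_fluxes(y, params, 0.0) == (0.0, 0.0, 0.0)

    def test_negative_input_rejected(self, params, y0):
        with pytest.raises(ValueError):
            carnitine_shuttle_fluxes(y0, params, -1.0)
        y = y0.copy()
        y[IDX["carnitine_m"]] = -0.1
        with pytest.raises(ValueError, match="carnitine_m"):
            carnitine_shuttle_fluxes(y, params, 0.01)

    def test_cpt1_saturates_to_analytic_limit(self, params, y0):
        # at 100x Km (and no product present) the rate is within 1% of
        # Vmax times the carnitine saturation term
        y = y0.copy()
        y[IDX["C16carnitine_e"]] = 0.0
        car_sat = (y[IDX["carnitine_e"]]
                   / (y[IDX["carnitine_e"]] + params.Km_cpt1_car))
        limit = params.Vmax_cpt1 * car_sat
        v1, _, _ = carnitine_shuttle_fluxes(
            y, params, 100 * params.Km_cpt1_pcoa)
        assert v1 == pytest.approx(limit, rel=0.01)
        assert v1 < limit

    def test_steady_state_shuttle_fluxes_are_equal(self, steady):
        res = steady.get(0.02, STATE3_ADP)
        assert res.converged
        f = res.fluxes
        assert f["CACT"] == pytest.approx(f["CPT1"], rel=1e-6)
        assert f["CPT2"] == pytest.approx(f["CPT1"], rel=1e-6)


class TestSpiralRateLaws:
    def test_dehydrogenase_zero_when_cofactor_exhausted(self, params, y0):
        y = y0.copy()
        y[IDX["ETF_FAD"]] = 0.0
        sp = AcylSpecies(16, "acyl")
        assert acyl_dehydrogenase_flux(sp, y, params) == 0.0

    def test_dehydrogenase_zero_without_substrate(self, params, y0):
        y = y0.copy()
        y[IDX[acyl_name(12, "acyl")]] = 0.0
        assert acyl_dehydrogenase_flux(AcylSpecies(12, "acyl"),
                                       y, params) == 0.0

    def test_dehydrogenase_matches_hand_evaluated_rate(self, params, y0):
        # C16 acyl-CoA at its Km, ETF-FAD at half the pool: both covering
        # classes (very-long and long chain) at half substrate saturation,
        # ETF term 0.010/0.015 -> (0.3 + 0.3) * 0.5 * (2/3) = 0.2 mM/s
        y = y0.copy()
        y[IDX["C16acylCoA"]] = params.Km_vlcad_acyl
        y[IDX["ETF_FAD"]] = 0.010
        v = acyl_dehydrogenase_flux(AcylSpecies(16, "acyl"), y, params)
        assert v == pytest.approx(0.2, rel=1e-12)

    def test_wrong_stage_rejected(self, params, y0):
        with pytest.raises(ValueError):
            acyl_dehydrogenase_flux(AcylSpecies(16, "enoyl"), y0, params)

    def test_hadh_requires_nad(self, params, y0):
        y = y0.copy()
        y[IDX["NAD_m"]] = 0.0
        fluxes = hydratase_hadh_thiolase_fluxes(y, params)
        for n in CHAIN_LENGTHS:
            assert fluxes[("HADH", n)] == 0.0

    def test_thiolase_stalls_without_coash(self, params, y0):
        y = y0.copy()
        y[IDX["CoASH"]] = 0.0
        fluxes = hydratase_hadh_thiolase_fluxes(y, params)
        for n in CHAIN_LENGTHS:
            assert fluxes[("thiolase", n)] == 0.0


@pytest.fixture(scope="module")
def flux(steady):
    res = steady.get(0.02, STATE3_ADP)
    assert res.converged
    return res.fluxes


class TestSteadyStateTelescoping:
    """With clamped PCoA at steady state no intermediate accumulates, so
    each cycle carries the same flux and per imported palmitoyl the
    spiral yields 8 AcCoA, 7 NADH and 7 ETF-FADH2."""

    def test_cycle_fluxes_telescope(self, flux):
        cpt1 = flux["CPT1"]
        for n in CHAIN_LENGTHS:
            assert flux[f"thiolase_C{n}"] == pytest.approx(cpt1, rel=1e-6)

    def test_accoa_yield_is_eight_per_palmitoyl(self, flux):
        accoa_rate = sum(
            (2 if n == 4 else 1) * flux[f"thiolase_C{n}"]
            for n in CHAIN_LENGTHS)
        assert accoa_rate / flux["CPT1"] == pytest.approx(8.0, rel=1e-6)

    def test_nadh_and_etf_yield_is_seven_per_palmitoyl(self, flux):
        hadh = sum(flux[f"HADH_C{n}"] for n in CHAIN_LENGTHS)
        acd = sum(v for name, v in flux.items()
                  if name.startswith("ACD_"))
        assert hadh / flux["CPT1"] == pytest.approx(7.0, rel=1e-6)
        assert acd / flux["CPT1"] == pytest.approx(7.0, rel=1e-6)
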