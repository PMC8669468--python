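"""Cofactor ledger: closure identities, ATP accounting, attribution,
energy charge."""

import math

import numpy as np
import pytest

import gluconeoflux as gf
from gluconeoflux.cofactors import (AdenylatePools, CofactorParams,
                                    atp_accounting, attribute_to_pathways,
                                    close_nadph, energy_charge,
                                    ledger_from_fluxes)
from gluconeoflux.errors import ConfigurationError, UnitError
from gluconeoflux.fit import FluxEstimate
from gluconeoflux.network import FluxVector


@pytest.fixture(scope="module")
def demo_abs(demo_model):
    from gluconeoflux import synth
    v = FluxVector(dict(synth.DEMO_TRUE_FLUXES))
    return v.to_absolute(12.0)  # q = 12 mmol gCDW^-1 h^-1


class TestEnergyCharge:
    @pytest.mark.parametrize("pools, expected", [
        ((1, 0, 0), 1.0),
        ((0, 1, 0), 0.5),
        ((0, 0, 1), 0.0),
        ((1, 1, 1), 0.5),
    ])
    def test_closed_form_values(self, pools, expected):
        assert energy_charge(AdenylatePools(*pools)) == pytest.approx(expected)

    def test_scale_invariance(self):
        a = energy_charge(AdenylatePools(2.0, 1.0, 0.5))
        b = energy_charge(AdenylatePools(20.0, 10.0, 5.0))
        assert a == pytest.approx(b)
        assert 0.0 <= a <= 1.0

    def test_all_zero_pools_rejected(self):
        with pytest.raises(ValueError):
            energy_charge(AdenylatePools(0, 0, 0))


class TestLedger:
    def test_zero_fluxes_zero_demand_all_zero(self, demo_model):
        fl = FluxVector({r.id: 0.0 for r in demo_model.reactions},
                        units="absolute")
        ledger = ledger_from_fluxes(fl, demo_model, {})
        assert all(v == 0.0 for v in ledger.production.values())
        assert all(v == 0.0 for v in ledger.consumption.values())

    def test_single_reaction_delta(self, demo_model):
        fl = FluxVector({"SDH": 10.0}, units="absolute")
        ledger = ledger_from_fluxes(fl, demo_model, {})
        assert ledger.production["NADH_UQH2"] == pytest.approx(10.0)

    def test_normalized_fluxes_are_rejected(self, demo_model,
                                            demo_truth_fluxes):
        with pytest.raises(UnitError):
            ledger_from_fluxes(demo_truth_fluxes, demo_model, {})

    def test_matches_per_reaction_summation_oracle(self, demo_model, demo_abs):
        demand = {"NADPH": 12.0, "ATP": 25.0, "NADH_UQH2": 0.0}
        ledger = ledger_from_fluxes(demo_abs, demo_model, demand)
        # independent spreadsheet-style tally
        exp_prod = {"NADH_UQH2": 0.0, "NADPH": 0.0, "ATP": 0.0}
        exp_cons = {"NADH_UQH2": 0.0, "NADPH": 0.0, "ATP": 0.0}
        key = {"nadh_uqh2": "NADH_UQH2", "nadph": "NADPH", "atp": "ATP"}
        for r in demo_model.reactions:
            v = demo_abs.values.get(r.id, 0.0)
            for k, d in r.cofactor_deltas.items():
                rate = v * d
                if rate >= 0:
                    exp_prod[key[k]] += rate
                else:
                    exp_cons[key[k]] += -rate
        for c in exp_cons:
            exp_cons[c] += demand.get(c, 0.0)
        assert ledger.production == pytest.approx(exp_prod)
        assert ledger.consumption == pytest.approx(exp_cons)

    def test_ledger_linearity_in_flux_scale(self, demo_model, demo_abs):
        l1 = ledger_from_fluxes(demo_abs, demo_model, {})
        scaled = FluxVector({k: 2 * v for k, v in demo_abs.values.items()},
                            units="absolute")
        l2 = ledger_from_fluxes(scaled, demo_model, {})
        for c in l1.production:
            assert l2.production[c] == pytest.approx(2 * l1.production[c])

    def test_sd_propagation_root_sum_of_squares(self, demo_model):
        entries = {"SDH": FluxEstimate("SDH", 10.0, 8.0, 12.0),
                   "MDH": FluxEstimate("MDH", 5.0, 4.0, 6.0)}
        ledger = ledger_from_fluxes(entries, demo_model, {})
        sd_sdh = (12.0 - 8.0) / (2 * 1.959963984540054)
        sd_mdh = (6.0 - 4.0) / (2 * 1.959963984540054)
        assert ledger.production_sd["NADH_UQH2"] == pytest.approx(
            math.hypot(sd_sdh, sd_mdh))


class TestClosure:
    def test_surplus_nadph_needs_no_transhydrogenase(self, demo_model):
        fl = FluxVector({"ICD": 10.0}, units="absolute")
        ledger = close_nadph(ledger_from_fluxes(fl, demo_model, {"NADPH": 5.0}))
        assert ledger.transhydrogenase_flux == 0.0

    def test_deficit_closure_matches_hand_arithmetic(self, demo_model):
        """Production 4.76 vs consumption 14.01 -> thd 9.25, ~66% of NADPH."""
        fl = FluxVector({"ICD": 4.76}, units="absolute")
        ledger = close_nadph(ledger_from_fluxes(fl, demo_model,
                                                {"NADPH": 14.01}))
        assert ledger.transhydrogenase_flux == pytest.approx(9.25)
        assert ledger.fraction_nadph_from_thd == pytest.approx(9.25 / 14.01)

    def test_closure_identity_exact(self, demo_model, demo_abs):
        ledger = close_nadph(ledger_from_fluxes(demo_abs, demo_model,
                                                {"NADPH": 13.6}))
        assert ledger.production["NADPH"] == ledger.consumption["NADPH"]

    def test_thd_debits_nadh_pool_once(self, demo_model, demo_abs):
        before = ledger_from_fluxes(demo_abs, demo_model, {"NADPH": 13.6})
        nadh_cons_before = before.consumption["NADH_UQH2"]
        after = close_nadph(before)
        assert after.consumption["NADH_UQH2"] == pytest.approx(
            nadh_cons_before + after.transhydrogenase_flux)


class TestATP:
    def test_zero_respirable_nadh_zero_oxphos(self, demo_model):
        fl = FluxVector({}, units="absolute")
        ledger = close_nadph(ledger_from_fluxes(fl, demo_model, {}))
        ledger = atp_accounting(ledger)
        assert ledger.oxphos_atp == 0.0

    def test_po_ratio_multiplication(self, demo_model):
        fl = FluxVector({"SDH": 10.0}, units="absolute")
        ledger = close_nadph(ledger_from_fluxes(fl, demo_model, {}))
        ledger = atp_accounting(ledger, CofactorParams(po_ratio=1.5))
        assert ledger.oxphos_atp == pytest.approx(15.0)

    def test_requires_closure_first(self, demo_model, demo_abs):
        ledger = ledger_from_fluxes(demo_abs, demo_model, {})
        with pytest.raises(ConfigurationError):
            atp_accounting(ledger)

    def test_surplus_identity_exact(self, demo_model, demo_abs):
        demand = {"NADPH": 13.6, "ATP": 24.0}
        ledger = atp_accounting(close_nadph(
            ledger_from_fluxes(demo_abs, demo_model, demand)))
        assert ledger.atp_surplus + ledger.consumption["ATP"] == pytest.approx(
            ledger.production["ATP"], abs=1e-12)

    def test_po_scaling_is_linear(self, demo_model, demo_abs):
        demand = {"NADPH": 13.6, "ATP": 24.0}
        out = {}
        for po in (1.0, 1.5, 2.0):
            ledger = atp_accounting(
                close_nadph(ledger_from_fluxes(demo_abs, demo_model, demand)),
                CofactorParams(po_ratio=po))
            respirable = (ledger.production["NADH_UQH2"]
                          - ledger.consumption["NADH_UQH2"])
            assert ledger.oxphos_atp == pytest.approx(po * respirable)
            out[po] = ledger.oxphos_atp
        assert out[2.0] == pytest.approx(2 * out[1.0])


class TestAttribution:
    def test_all_tca_production_gives_fraction_one(self, demo_model):
        fl = FluxVector({"SDH": 10.0, "MDH": 5.0}, units="absolute")
        ledger = atp_accounting(close_nadph(
            ledger_from_fluxes(fl, demo_model, {})))
        attr = attribute_to_pathways(ledger, fl, demo_model)
        assert attr["NADH_UQH2"]["TCA"] == pytest.approx(1.0)

    def test_equal_producers_split_half(self):
        from gluconeoflux.network import NetworkModel, Reaction
        model = NetworkModel([
            Reaction("R1", {"A": 1}, {"B": 1},
                     cofactor_deltas={"nadh_uqh2": 1}, pathway="TCA"),
            Reaction("R2", {"B": 1}, {"A": 1},
                     cofactor_deltas={"nadh_uqh2": 1}, pathway="EMP"),
        ])
        fl = FluxVector({"R1": 5.0, "R2": 5.0}, units="absolute")
        ledger = atp_accounting(close_nadph(ledger_from_fluxes(fl, model, {})))
        attr = attribute_to_pathways(ledger, fl, model)
        assert attr["NADH_UQH2"]["TCA"] == pytest.approx(0.5)
        assert attr["NADH_UQH2"]["EMP"] == pytest.approx(0.5)

    def test_thd_nadph_follows_nadh_pathways(self, demo_model, demo_abs):
        """With a NADPH deficit, transhydrogenase-derived NADPH is credited
        to the pathways producing the NADH, so the TCA share of NADPH rises
        toward the TCA share of NADH."""
        demand = {"NADPH": 13.6, "ATP": 24.0}
        ledger = atp_accounting(close_nadph(
            ledger_from_fluxes(demo_abs, demo_model, demand)))
        attr = attribute_to_pathways(ledger, demo_abs, demo_model)
        for cof in ("NADH_UQH2", "NADPH", "ATP"):
            assert sum(attr[cof].values()) == pytest.approx(1.0)
        # manual tally oracle: direct ICD share plus thd credited by the
        # (all-TCA) NADH production shares
        icd = demo_abs.values["ICD"]
        me = demo_abs.values["ME"]
        total = icd + me + ledger.transhydrogenase_flux
        assert ledger.transhydrogenase_flux > 0
        assert attr["NADH_UQH2"]["TCA"] == pytest.approx(1.0)
        assert attr["NADPH"]["TCA"] == pytest.approx(
            (icd + ledger.transhydrogenase_flux) / total)
        # the thd credit strictly raises the TCA share of NADPH
        assert attr["NADPH"]["TCA"] > icd / (icd + me)

    def test_untagged_producer_is_configuration_error(self):
        from gluconeoflux.network import NetworkModel, Reaction
        model = NetworkModel([
            Reaction("R1", {"A": 1}, {"B": 1},
                     cofactor_deltas={"nadh_uqh2": 1}, pathway=""),
        ])
        fl = FluxVector({"R1": 5.0}, units="absolute")
        ledger = atp_accounting(close_nadph(ledger_from_fluxes(fl, model, {})))
        with pytest.raises(ConfigurationError):
            attribute_to_pathways(ledger, fl, model)
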