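"""Scale-up and salary-substitution scenarios."""

from dataclasses import replace

import pytest

import costkit as ck
from costkit.model import (
    Activity,
    Arm,
    CostIngredient,
    CostNature,
    CostingConfig,
    FacilityOutput,
    InputCategory,
    PROJECT,
    SharedScope,
)
from costkit.scenarios import Scenario, apply_scenario, substitute_salaries


def mini_tables():
    """One facility, one arm: a shared fixed line plus facility recurrents."""
    cfg = CostingConfig()
    ings = [
        CostIngredient(
            id="sysdev", facility_id=PROJECT, arm=Arm.TWO_WAY,
            activity=Activity.SYSTEM_DEVELOPMENT,
            input_category=InputCategory.STARTUP,
            cost_nature=CostNature.ONE_TIME, quantity=1.0,
            quantity_unit="lump sum", unit_price=5000.0, currency="USD",
            useful_life_years=5, shared_scope=SharedScope.PROJECT,
        ).validate(),
        CostIngredient(
            id="nurse__study_nurse", facility_id="F1", arm=Arm.TWO_WAY,
            activity=Activity.SERVICE_DELIVERY,
            input_category=InputCategory.PERSONNEL,
            cost_nature=CostNature.RECURRENT, quantity=12.0,
            quantity_unit="person-month", unit_price=100.0, currency="USD",
        ).validate(),
        CostIngredient(
            id="sms", facility_id="F1", arm=Arm.TWO_WAY,
            activity=Activity.COMMUNICATION_DELIVERY,
            input_category=InputCategory.COMMUNICATION,
            cost_nature=CostNature.RECURRENT, quantity=1000.0,
            quantity_unit="message", unit_price=0.05, currency="USD",
        ).validate(),
    ]
    outs = [
        FacilityOutput("F1", Arm.TWO_WAY, 50, 1000, 0, clients_served_annual=500)
    ]
    return ings, outs, cfg


class TestApplyScenario:
    def test_identity_scenario_returns_equal_tables(self, fx):
        sc = Scenario(name="identity")
        ings, outs = apply_scenario(fx.ingredients, fx.outputs, sc)
        assert ings == fx.ingredients
        assert outs == fx.outputs
        # idempotence: applying again changes nothing
        again = apply_scenario(ings, outs, sc)
        assert again == (ings, outs)

    def test_baseline_is_not_mutated(self, fx):
        before = list(fx.ingredients), list(fx.outputs)
        apply_scenario(fx.ingredients, fx.outputs, fx.scenarios["scale6"])
        assert (list(fx.ingredients), list(fx.outputs)) == before

    def test_doubling_facilities_halves_fixed_share(self):
        """A clone facility halves the per-facility fixed-cost share while the
        per-facility recurrent costs stay unchanged."""
        ings, outs, cfg = mini_tables()
        base = ck.run_costing(ings, outs, cfg)
        sc = Scenario(
            name="double",
            facility_beneficiaries={"F1": 50, "F2": 50},
            template_facility="F1",
        )
        s_ings, s_outs = apply_scenario(ings, outs, sc)
        res = ck.run_costing(s_ings, s_outs, cfg)
        for fac in ("F1", "F2"):
            s = res.summaries[(fac, Arm.TWO_WAY)]
            b = base.summaries[("F1", Arm.TWO_WAY)]
            assert s.fixed_total_usd == pytest.approx(b.fixed_total_usd / 2)
            assert s.variable_total_usd == pytest.approx(b.variable_total_usd)

    def test_scale_up_never_raises_cost_per_beneficiary(self, fx, baseline):
        """Shared fixed costs over more beneficiaries cannot raise unit cost."""
        for name in ("scale6", "moh"):
            sc = fx.scenarios[name]
            s_ings, s_outs = apply_scenario(fx.ingredients, fx.outputs, sc)
            res = ck.run_costing(s_ings, s_outs, ck.scenario_config(fx.config, sc))
            assert (
                res.weighted_units[Arm.TWO_WAY].cost_per_beneficiary_usd
                < baseline.weighted_units[Arm.TWO_WAY].cost_per_beneficiary_usd
            )

    def test_added_facility_requires_template(self):
        ings, outs, cfg = mini_tables()
        sc = Scenario(name="bad", facility_beneficiaries={"F1": 50, "F9": 50})
        with pytest.raises(ck.CostModelError, match="template"):
            apply_scenario(ings, outs, sc)

    def test_nonpositive_beneficiaries_rejected(self):
        with pytest.raises(ck.CostModelError, match="positive"):
            Scenario(name="bad", facility_beneficiaries={"F1": 0}).validate()

    def test_commutes_with_currency_conversion(self, fx):
        """Converting KES lines to USD first leaves scenario totals unchanged."""
        rate = fx.config.exchange_rate_kes_per_usd
        usd_ings = [
            replace(r, unit_price=r.unit_price / rate, currency="USD")
            if r.currency == "KES"
            else r
            for r in fx.ingredients
        ]
        sc = fx.scenarios["scale6"]
        cfg = ck.scenario_config(fx.config, sc)
        a = ck.run_costing(*apply_scenario(fx.ingredients, fx.outputs, sc), cfg)
        b = ck.run_costing(*apply_scenario(usd_ings, fx.outputs, sc), cfg)
        assert a.grand_total_usd() == pytest.approx(b.grand_total_usd(), rel=1e-12)

    def test_message_volume_scales_with_beneficiaries(self, fx):
        """Facility SMS/airtime lines grow with enrolment; personnel do not."""
        sc = fx.scenarios["scale6"]
        s_ings, _ = apply_scenario(fx.ingredients, fx.outputs, sc)
        base_sms = next(
            r for r in fx.ingredients if r.id == "facility_A-two_way-sms-airtime"
        )
        scen_sms = next(
            r for r in s_ings if r.id == "facility_A-two_way-sms-airtime"
        )
        assert scen_sms.quantity == pytest.approx(base_sms.quantity * 152 / 76)
        base_nurse = next(
            r for r in fx.ingredients
            if r.id == "facility_A-two_way-service-delivery__study_nurse"
        )
        scen_nurse = next(
            r for r in s_ings
            if r.id == "facility_A-two_way-service-delivery__study_nurse"
        )
        assert scen_nurse.quantity == base_nurse.quantity


class TestSalarySubstitution:
    def test_unknown_role_is_warned_noop(self, fx, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="costkit"):
            result = substitute_salaries(fx.ingredients, {"astronaut": 1.0}, "x")
        assert result == list(fx.ingredients)
        assert "astronaut" in caplog.text

    def test_only_service_delivery_personnel_changed(self, fx):
        table = {"study_nurse": 1200.0}
        result = substitute_salaries(fx.ingredients, table)
        for old, new in zip(fx.ingredients, result):
            if (
                old.role == "study_nurse"
                and old.activity is Activity.SERVICE_DELIVERY
                and old.input_category is InputCategory.PERSONNEL
            ):
                assert new.unit_price == pytest.approx(100.0)
                assert new.currency == "USD"
                assert new.quantity == old.quantity  # person-time preserved
            else:
                assert new == old


class TestCompareRuns:
    def rec(self, cpb, cpc=1.0, total=1000.0):
        from costkit.model import UnitCostRecord

        return UnitCostRecord(
            facility_id="W", arm=Arm.TWO_WAY, total_annual_usd=total,
            beneficiaries=100, contacts=1000,
            cost_per_beneficiary_usd=cpb, cost_per_contact_usd=cpc,
        )

    @pytest.mark.parametrize("base,alt,expected", [(62, 43, 31), (62, 31, 50)])
    def test_reported_percent_decreases(self, base, alt, expected):
        cmp = ck.compare_runs(self.rec(base), self.rec(alt))
        assert cmp.pct_decrease_per_beneficiary_int == expected

    def test_identical_runs_show_zero_change(self):
        cmp = ck.compare_runs(self.rec(62), self.rec(62))
        assert cmp.pct_decrease_per_beneficiary == pytest.approx(0.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ck.CostModelError):
            ck.compare_runs(self.rec(0.0), self.rec(1.0))
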