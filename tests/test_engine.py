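"""Annualization, shared-cost allocation and aggregation."""

import random

import pytest
from hypothesis import given, strategies as st

import costkit as ck
from costkit.model import (
    Activity,
    Arm,
    CostIngredient,
    CostLine,
    CostNature,
    CostingConfig,
    FacilityOutput,
    InputCategory,
    PROJECT,
)

from conftest import discount_sum

CFG = CostingConfig()


class TestAnnuityFactor:
    @pytest.mark.parametrize(
        "rate,life,expected",
        [(0.03, 10, 8.5302), (0.0, 10, 10.0), (0.03, 1, 0.9709)],
    )
    def test_reference_values(self, rate, life, expected):
        assert ck.annuity_factor(rate, life) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize("rate", [0.0, 0.01, 0.03, 0.05, 0.1, 0.2])
    @pytest.mark.parametrize("life", [1, 2, 3, 5, 7, 10, 15, 20, 30])
    def test_matches_brute_force_discount_sum(self, rate, life):
        assert ck.annuity_factor(rate, life) == pytest.approx(
            discount_sum(rate, life), rel=1e-12
        )

    def test_monotone_in_life_and_rate(self):
        lives = [1, 2, 5, 10, 20]
        factors = [ck.annuity_factor(0.03, n) for n in lives]
        assert factors == sorted(factors)
        rates = [0.0, 0.01, 0.03, 0.1]
        by_rate = [ck.annuity_factor(r, 10) for r in rates]
        assert by_rate == sorted(by_rate, reverse=True)

    def test_nonpositive_life_rejected(self):
        with pytest.raises(ck.CostModelError):
            ck.annuity_factor(0.03, 0)


def make_ingredient(**kw):
    defaults = dict(
        id="x",
        facility_id="F1",
        arm=Arm.TWO_WAY,
        activity=Activity.SERVICE_DELIVERY,
        input_category=InputCategory.PERSONNEL,
        cost_nature=CostNature.RECURRENT,
        quantity=1.0,
        quantity_unit="unit",
        unit_price=1.0,
        currency="USD",
    )
    defaults.update(kw)
    return CostIngredient(**defaults).validate()


class TestAnnualize:
    def test_equipment_annuitized(self):
        ing = make_ingredient(
            input_category=InputCategory.EQUIPMENT,
            cost_nature=CostNature.ONE_TIME,
            unit_price=1000.0,
            useful_life_years=10,
        )
        assert ck.annualize(ing, CFG) == pytest.approx(117.23, abs=0.01)
        assert ck.annualize(ing, CFG) < 1000.0  # always below purchase price

    def test_startup_straight_line(self):
        ing = make_ingredient(
            activity=Activity.PLANNING,
            input_category=InputCategory.STARTUP,
            cost_nature=CostNature.ONE_TIME,
            unit_price=500.0,
            useful_life_years=5,
        )
        assert ck.annualize(ing, CFG) == pytest.approx(100.0)

    def test_startup_annuitized_switch(self):
        ing = make_ingredient(
            activity=Activity.PLANNING,
            input_category=InputCategory.STARTUP,
            cost_nature=CostNature.ONE_TIME,
            unit_price=500.0,
            useful_life_years=5,
        )
        annuitized = ck.annualize(
            ing, CostingConfig(startup_amortization="annuitized")
        )
        assert annuitized == pytest.approx(500.0 / discount_sum(0.03, 5), rel=1e-12)
        assert annuitized > 100.0  # discounting raises the equivalent annual cost

    def test_recurrent_monthly_fee(self):
        # a 48 USD/month room fee costs 576 USD over the analytic year
        ing = make_ingredient(
            activity=Activity.OVERHEAD_ADMIN,
            input_category=InputCategory.OVERHEAD,
            quantity=12.0,
            unit_price=48.0,
        )
        assert ck.annualize(ing, CFG) == pytest.approx(576.0)

    def test_kes_line_converted(self):
        ing = make_ingredient(quantity=1.0, unit_price=10325.0, currency="KES")
        assert ck.annualize(ing, CFG) == pytest.approx(100.0)

    def test_equipment_life_defaults_to_config(self):
        ing = make_ingredient(
            input_category=InputCategory.EQUIPMENT,
            cost_nature=CostNature.ONE_TIME,
            unit_price=1000.0,
        )
        assert ck.annualize(ing, CFG) == pytest.approx(1000.0 / 8.5302, abs=0.01)


def outputs_for(weights):
    return [
        FacilityOutput(
            facility_id=f,
            arm=Arm.TWO_WAY,
            beneficiaries=10,
            automated_messages=100,
            nurse_messages=0,
            clients_served_annual=w,
        )
        for f, w in weights.items()
    ]


def project_line(annual):
    return CostLine(
        facility_id=PROJECT,
        arm=Arm.TWO_WAY,
        activity=Activity.SUPERVISION_COORDINATION,
        input_category=InputCategory.PERSONNEL,
        annual_usd=annual,
        source_id="shared",
    )


class TestAllocateShared:
    def test_client_share_allocation_with_remainder(self):
        """100 USD over facility weights 152 and 80 out of 548 project clients."""
        allocated, remainder = ck.allocate_shared(
            [project_line(100.0)],
            outputs_for({"A": 152, "B": 80}),
            project_total_clients=548,
        )
        by_fac = {l.facility_id: l.annual_usd for l in allocated}
        assert by_fac["A"] == pytest.approx(27.74, abs=0.01)
        assert by_fac["B"] == pytest.approx(14.60, abs=0.01)
        assert remainder == pytest.approx(100.0 - by_fac["A"] - by_fac["B"])

    def test_equal_weights_split_evenly(self):
        allocated, remainder = ck.allocate_shared(
            [project_line(100.0)], outputs_for({f"F{i}": 50 for i in range(4)})
        )
        assert remainder == 0.0
        assert [l.annual_usd for l in allocated] == pytest.approx([25.0] * 4)

    @given(
        weights=st.lists(st.integers(1, 10000), min_size=1, max_size=8),
        amount=st.floats(0.0, 1e6),
    )
    def test_conservation(self, weights, amount):
        """Allocated shares always sum back to the source amount."""
        outs = outputs_for({f"F{i}": w for i, w in enumerate(weights)})
        allocated, remainder = ck.allocate_shared([project_line(amount)], outs)
        assert remainder == 0.0
        assert sum(l.annual_usd for l in allocated) == pytest.approx(
            amount, rel=1e-9, abs=1e-9
        )
        assert sum(l.allocation_fraction for l in allocated) == pytest.approx(1.0)

    def test_zero_weights_rejected(self):
        outs = [
            FacilityOutput("A", Arm.TWO_WAY, 0, 0, 0, clients_served_annual=0)
        ]
        with pytest.raises(ck.CostModelError, match="zero"):
            ck.allocate_shared([project_line(1.0)], outs)

    def test_beneficiary_fallback_when_clients_missing(self):
        outs = [
            FacilityOutput("A", Arm.TWO_WAY, 30, 10, 0),
            FacilityOutput("B", Arm.TWO_WAY, 10, 10, 0),
        ]
        allocated, _ = ck.allocate_shared([project_line(100.0)], outs)
        by_fac = {l.facility_id: l.annual_usd for l in allocated}
        assert by_fac == pytest.approx({"A": 75.0, "B": 25.0})


class TestSplitBothArms:
    def test_split_by_per_arm_beneficiaries(self):
        outs = [
            FacilityOutput("A", Arm.TWO_WAY, 76, 1, 0, 152),
            FacilityOutput("A", Arm.ONE_WAY, 76, 1, 0, 152),
        ]
        line = CostLine(
            "A", Arm.BOTH, Activity.OVERHEAD_ADMIN, InputCategory.OVERHEAD,
            576.0, "room",
        )
        split = ck.split_both_arms([line], outs)
        assert {l.arm: l.annual_usd for l in split} == pytest.approx(
            {Arm.TWO_WAY: 288.0, Arm.ONE_WAY: 288.0}
        )

    def test_conserves_total_under_unequal_arms(self):
        outs = [
            FacilityOutput("B", Arm.TWO_WAY, 39, 1, 0),
            FacilityOutput("B", Arm.ONE_WAY, 41, 1, 0),
        ]
        line = CostLine(
            "B", Arm.BOTH, Activity.OVERHEAD_ADMIN, InputCategory.OVERHEAD,
            100.0, "room",
        )
        split = ck.split_both_arms([line], outs)
        assert sum(l.annual_usd for l in split) == pytest.approx(100.0)
        two = next(l for l in split if l.arm is Arm.TWO_WAY)
        assert two.annual_usd == pytest.approx(100.0 * 39 / 80)


def line(fac, arm, act, cat, usd, src="s"):
    return CostLine(fac, arm, act, cat, usd, src)


#: The eight published facility-weighted two-way component costs (USD/yr).
PRINTED_TWO_WAY = [
    (Activity.SERVICE_DELIVERY, InputCategory.PERSONNEL, 1794.0),
    (Activity.SYSTEM_DEVELOPMENT, InputCategory.STARTUP, 573.0),
    (Activity.COMMUNICATION_DELIVERY, InputCategory.COMMUNICATION, 470.0),
    (Activity.SERVICE_DELIVERY, InputCategory.EQUIPMENT, 381.0),
    (Activity.OVERHEAD_ADMIN, InputCategory.OVERHEAD, 291.0),
    (Activity.INITIAL_TRAINING, InputCategory.STARTUP, 98.0),
    (Activity.SENSITIZATION, InputCategory.STARTUP, 64.0),
    (Activity.PLANNING, InputCategory.STARTUP, 54.0),
]


class TestAggregate:
    def test_published_components_total(self):
        lines = [line("W", Arm.TWO_WAY, a, c, v) for a, c, v in PRINTED_TWO_WAY]
        summary = ck.aggregate(lines)[("W", Arm.TWO_WAY)]
        assert summary.total_annual_usd == pytest.approx(3725.0)
        # the four start-up activities form the fixed subtotal
        assert summary.fixed_total_usd == pytest.approx(789.0)
        assert summary.variable_total_usd == pytest.approx(2936.0)

    def test_empty_input_yields_no_summaries(self):
        assert ck.aggregate([]) == {}

    def test_permutation_invariance_and_additivity(self):
        lines = [line("W", Arm.TWO_WAY, a, c, v) for a, c, v in PRINTED_TWO_WAY]
        shuffled = list(lines)
        random.Random(7).shuffle(shuffled)
        a = ck.aggregate(lines)[("W", Arm.TWO_WAY)]
        b = ck.aggregate(shuffled)[("W", Arm.TWO_WAY)]
        assert a.total_annual_usd == b.total_annual_usd
        assert dict(a.by_activity) == pytest.approx(dict(b.by_activity))
        half = ck.aggregate(lines[:4])[("W", Arm.TWO_WAY)]
        rest = ck.aggregate(lines[4:])[("W", Arm.TWO_WAY)]
        assert half.total_annual_usd + rest.total_annual_usd == pytest.approx(
            a.total_annual_usd
        )

    def test_matches_brute_force_loop(self, fx, baseline):
        """Per-cell totals equal an independent per-line accumulation."""
        totals = {}
        for l in baseline.lines:
            key = (l.facility_id, l.arm)
            totals[key] = totals.get(key, 0.0) + l.annual_usd
        for key, summary in baseline.summaries.items():
            assert summary.total_annual_usd == pytest.approx(totals[key], rel=1e-12)
            assert sum(summary.by_activity.values()) == pytest.approx(
                summary.total_annual_usd
            )
            assert sum(summary.by_input_category.values()) == pytest.approx(
                summary.total_annual_usd
            )
            assert summary.fixed_total_usd + summary.variable_total_usd == (
                pytest.approx(summary.total_annual_usd)
            )


def test_pipeline_conserves_ingredient_totals(fx, baseline):
    """Facility-level lines sum to the allocated share of every ingredient."""
    from conftest import brute_force_annual_usd

    by_source = {}
    for l in baseline.lines:
        by_source[l.source_id] = by_source.get(l.source_id, 0.0) + l.annual_usd
    share = 232.0 / 548.0  # costed facilities' share of project clients
    for ing in fx.ingredients:
        if ing.research_flag:
            assert ing.id not in by_source
            continue
        expected = brute_force_annual_usd(ing, fx.config)
        if ing.facility_id == PROJECT:
            expected *= share
        assert by_source[ing.id] == pytest.approx(expected, rel=1e-9)
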