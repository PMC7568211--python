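import pytest
from hypothesis import HealthCheck, settings

import costkit as ck
from costkit.model import CostNature, InputCategory, PROJECT

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fx():
    """The deterministic calibrated study fixture."""
    return ck.fixture_mobile_wachx()


@pytest.fixture(scope="session")
def baseline(fx):
    """Baseline costing run over the fixture."""
    return ck.run_costing(fx.ingredients, fx.outputs, fx.config)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (kept free of the engine's code paths)


def discount_sum(rate: float, life: int) -> float:
    """Present value of 1/year for `life` years, summed term by term."""
    return sum((1.0 + rate) ** (-t) for t in range(1, life + 1))


def brute_force_annual_usd(ing, config) -> float:
    """Per-row annual USD by direct arithmetic (integer lives only)."""
    amount = ing.quantity * ing.unit_price
    if ing.currency == "KES":
        amount = amount / config.exchange_rate_kes_per_usd
    if ing.input_category is InputCategory.EQUIPMENT:
        life = ing.useful_life_years or config.equipment_life_years
        return amount / discount_sum(config.discount_rate, int(life))
    if ing.cost_nature is CostNature.ONE_TIME:
        life = ing.useful_life_years or config.startup_life_years
        if config.startup_amortization == "annuitized":
            return amount / discount_sum(config.discount_rate, int(life))
        return amount / life
    return amount


def brute_force_grand_total(ingredients, outputs, config) -> float:
    """Project grand total allocated to the costed facilities.

    Project-shared rows count only for the share of the allocation
    denominator held by the costed facilities; everything else counts fully.
    Research-flagged rows never count.
    """
    clients = {}
    bene = {}
    for o in outputs:
        bene[o.facility_id] = bene.get(o.facility_id, 0) + o.beneficiaries
        if o.clients_served_annual is not None:
            clients[o.facility_id] = o.clients_served_annual
    weights = {f: float(clients.get(f, bene[f])) for f in bene}
    total_w = sum(weights.values())
    denom = config.project_total_clients or total_w
    share = total_w / denom
    total = 0.0
    for ing in ingredients:
        if ing.research_flag:
            continue
        annual = brute_force_annual_usd(ing, config)
        total += annual * (share if ing.facility_id == PROJECT else 1.0)
    return total
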