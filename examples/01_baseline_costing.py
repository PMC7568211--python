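"""Baseline costing of the packaged two-arm SMS-support dataset.

Loads the synthetic reconstruction of the 2017 study tables, runs the full
pipeline (annualization, shared-cost allocation, arm splitting, aggregation)
and prints the facility-weighted annual incremental costs and unit costs.
"""

import costkit as ck
from costkit.model import Arm, InputCategory
from costkit.units import round_half_up

fx = ck.fixture_mobile_wachx()
result = ck.run_costing(fx.ingredients, fx.outputs, fx.config)

for arm in (Arm.TWO_WAY, Arm.ONE_WAY):
    unit = result.weighted_units[arm]
    summary = result.weighted_summary[arm]
    print(f"\n{arm.value} SMS messaging (weighted across facilities):")
    print(f"  total annual incremental cost: {round_half_up(unit.total_annual_usd):>7.0f} USD/facility")
    print(f"  cost per beneficiary:          {round_half_up(unit.cost_per_beneficiary_usd):>7.0f} USD")
    print(f"  cost per contact:              {round_half_up(unit.cost_per_contact_usd, 2):>7.2f} USD")
    share = summary.category_total(InputCategory.PERSONNEL) / summary.total_annual_usd
    print(f"  personnel share of costs:      {100 * share:>6.1f} %")
    print(f"  one-time start-up subtotal:    {round_half_up(summary.fixed_total_usd):>7.0f} USD")

# The interactive arm costs more per beneficiary because nurses spend time
# answering participant messages; start-up (fixed) costs are nearly equal.
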