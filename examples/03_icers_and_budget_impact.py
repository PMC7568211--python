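"""Cost-effectiveness ratios and a national budget-impact projection.

Combines the programme's annual incremental cost with externally published
effect counts (viral-load suppressions, patients achieving adherence), then
projects national spending if the intervention covered all women offered
PMTCT services at 80% mobile-phone penetration.
"""

import costkit as ck
from costkit.model import EffectInput, ProjectionInput

incremental_cost = 7084.0  # two-facility two-way annual incremental cost, USD
effects = [
    EffectInput("viral_load_suppression", 11, source="two-way SMS RCT, Kenya"),
    EffectInput("medication_adherence", 15, source="SMS adherence meta-analysis"),
]
for effect in effects:
    res = ck.icer(incremental_cost, effect)
    print(f"ICER: {res.icer_usd_rounded} USD per {effect.label}")

projection = ck.budget_projection(
    ProjectionInput(
        target_population=59000,   # women offered PMTCT services nationally
        penetration=0.80,          # mobile phone penetration
        cost_per_beneficiary_usd=31.0,  # at-scale MOH-salary unit cost
        reference_budget_usd=46e6,      # national PMTCT budget
    )
)
print(f"projected national spending: {projection.total_usd / 1e6:.2f} million USD")
print(f"share of reference PMTCT budget: {projection.share_pct_rounded} %")

# Both ICERs sit far below typical per-capita GDP benchmarks, and national
# scale-up would absorb only a small slice of the existing PMTCT budget.
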