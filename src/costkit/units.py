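"""Unit costs: cost per beneficiary, cost per contact, weighted averages.

A *beneficiary* is a service user enrolled to receive the SMS intervention; a
*contact* is one message successfully delivered (automated or nurse-sent).
Cross-facility averages are weighted by per-facility beneficiary counts, which
makes the weighted cost per beneficiary algebraically identical to the pooled
ratio (pooled total / pooled beneficiaries).  For cost per contact the
beneficiary-weighted mean and the pooled ratio differ slightly; both are
reported.
"""

from __future__ import annotations

import decimal
from typing import Dict, Mapping, Optional, Sequence

from .model import (
    CostModelError,
    CostSummary,
    FacilityOutput,
    UnitCostRecord,
    WEIGHTED,
)


def contact_count(output: FacilityOutput) -> int:
    """Total points of contact for one facility x arm: automated + nurse."""
    return output.contacts


def unit_costs(summary: CostSummary, output: FacilityOutput) -> UnitCostRecord:
    """Cost per beneficiary and per contact for one facility x arm.

    Both ratios are computed on unrounded totals; rounding is applied only at
    report time.  Zero beneficiaries or contacts is an explicit error naming
    the facility (a zero *total* over positive counts is fine and yields 0).
    """
    if (summary.facility_id, summary.arm) != (output.facility_id, output.arm):
        raise CostModelError(
            f"summary {(summary.facility_id, summary.arm)} does not match "
            f"output {(output.facility_id, output.arm)}"
        )
    if output.beneficiaries <= 0:
        raise CostModelError(
            f"facility {output.facility_id} ({output.arm.value}): cannot divide "
            "by zero beneficiaries"
        )
    contacts = contact_count(output)
    if contacts <= 0:
        raise CostModelError(
            f"facility {output.facility_id} ({output.arm.value}): cannot divide "
            "by zero contacts"
        )
    total = summary.total_annual_usd
    return UnitCostRecord(
        facility_id=summary.facility_id,
        arm=summary.arm,
        total_annual_usd=total,
        beneficiaries=output.beneficiaries,
        contacts=contacts,
        cost_per_beneficiary_usd=total / output.beneficiaries,
        cost_per_contact_usd=total / contacts,
    )


def weighted_average(
    records: Sequence[UnitCostRecord],
    weights: Optional[Mapping[str, float]] = None,
) -> UnitCostRecord:
    """Beneficiary-weighted average of per-facility unit-cost records.

    ``weights`` defaults to each record's own beneficiary count.  The result
    carries the WEIGHTED sentinel facility id; totals and unit costs are the
    weighted means of the facility values, and the pooled cost-per-contact
    (pooled total / pooled contacts) is attached as a secondary field.  A
    single-facility input returns that facility's values.
    """
    if not records:
        raise CostModelError("weighted_average needs at least one record")
    arms = {r.arm for r in records}
    if len(arms) != 1:
        raise CostModelError(f"records span multiple arms: {sorted(a.value for a in arms)}")
    if weights is None:
        weights = {r.facility_id: float(r.beneficiaries) for r in records}
    rec_facs = {r.facility_id for r in records}
    if rec_facs != set(weights):
        raise CostModelError(
            f"facility sets differ between records ({sorted(rec_facs)}) and "
            f"weights ({sorted(weights)})"
        )
    w_total = sum(weights.values())
    if w_total <= 0:
        raise CostModelError("weights must sum to a positive value")

    def wmean(attr: str) -> float:
        return sum(getattr(r, attr) * weights[r.facility_id] for r in records) / w_total

    pooled_total = sum(r.total_annual_usd for r in records)
    pooled_contacts = sum(r.contacts for r in records)
    return UnitCostRecord(
        facility_id=WEIGHTED,
        arm=records[0].arm,
        total_annual_usd=wmean("total_annual_usd"),
        beneficiaries=sum(r.beneficiaries for r in records),
        contacts=pooled_contacts,
        cost_per_beneficiary_usd=wmean("cost_per_beneficiary_usd"),
        cost_per_contact_usd=wmean("cost_per_contact_usd"),
        cost_per_contact_pooled_usd=(
            pooled_total / pooled_contacts if pooled_contacts else 0.0
        ),
    )


def weighted_summary(
    summaries: Sequence[CostSummary], weights: Mapping[str, float]
) -> CostSummary:
    """Beneficiary-weighted average of facility cost summaries (componentwise)."""
    if not summaries:
        raise CostModelError("weighted_summary needs at least one summary")
    arms = {s.arm for s in summaries}
    if len(arms) != 1:
        raise CostModelError("summaries span multiple arms")
    w_total = sum(weights[s.facility_id] for s in summaries)
    if w_total <= 0:
        raise CostModelError("weights must sum to a positive value")
    acts: Dict = {}
    cats: Dict = {}
    for s in summaries:
        w = weights[s.facility_id] / w_total
        for a, v in s.by_activity.items():
            acts[a] = acts.get(a, 0.0) + w * v
        for c, v in s.by_input_category.items():
            cats[c] = cats.get(c, 0.0) + w * v
    fixed = sum(weights[s.facility_id] * s.fixed_total_usd for s in summaries) / w_total
    var = sum(weights[s.facility_id] * s.variable_total_usd for s in summaries) / w_total
    total = sum(weights[s.facility_id] * s.total_annual_usd for s in summaries) / w_total
    return CostSummary(
        facility_id=WEIGHTED,
        arm=summaries[0].arm,
        by_activity=acts,
        by_input_category=cats,
        fixed_total_usd=fixed,
        variable_total_usd=var,
        total_annual_usd=total,
    )


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding, as used for the printed report figures."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)
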