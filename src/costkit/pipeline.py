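"""End-to-end costing run: ingredients + outputs + config -> cost report."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from . import engine, units
from .model import (
    Arm,
    CostIngredient,
    CostLine,
    CostModelError,
    CostSummary,
    FacilityOutput,
    CostingConfig,
    PROJECT,
    UnitCostRecord,
)


@dataclass
class CostingResult:
    """Everything one costing run produces.

    ``summaries`` and ``units`` are keyed by (facility_id, arm); the
    ``weighted_*`` maps carry the beneficiary-weighted cross-facility rows per
    arm.  ``unallocated_usd`` is the share of project-shared costs belonging
    to facilities outside the costed set (nonzero only when the allocation
    denominator exceeds the costed facilities' weights).
    """

    summaries: Dict[Tuple[str, Arm], CostSummary]
    units: Dict[Tuple[str, Arm], UnitCostRecord]
    weighted_summary: Dict[Arm, CostSummary]
    weighted_units: Dict[Arm, UnitCostRecord]
    lines: List[CostLine] = field(default_factory=list)
    unallocated_usd: float = 0.0
    n_research_excluded: int = 0

    def facility_summaries(self) -> List[CostSummary]:
        return [self.summaries[k] for k in sorted(self.summaries, key=lambda k: (k[0], k[1].value))]

    def grand_total_usd(self) -> float:
        return sum(s.total_annual_usd for s in self.summaries.values())


def run_costing(
    ingredients: Sequence[CostIngredient],
    outputs: Sequence[FacilityOutput],
    config: CostingConfig,
) -> CostingResult:
    """Run the full costing pipeline.

    Steps: drop research-flagged rows; annualize to USD; apportion
    project-shared lines by clients served; split both-arm lines by per-arm
    beneficiaries; aggregate per facility x arm; compute unit costs and
    beneficiary-weighted averages per arm.
    """
    config.validate()
    if not outputs:
        raise CostModelError("costing requires a non-empty facility output table")
    known = {o.facility_id for o in outputs}
    for ing in ingredients:
        if ing.facility_id != PROJECT and ing.facility_id not in known:
            raise CostModelError(
                f"ingredient {ing.id!r} references facility "
                f"{ing.facility_id!r} absent from the output table"
            )

    lines, excluded = engine.to_cost_lines(ingredients, config)
    lines, remainder = engine.allocate_shared(
        lines, outputs, config.project_total_clients
    )
    lines = engine.split_both_arms(lines, outputs)
    summaries = engine.aggregate(lines)

    out_map = {(o.facility_id, o.arm): o for o in outputs}
    unit_map: Dict[Tuple[str, Arm], UnitCostRecord] = {}
    for key, summary in summaries.items():
        out = out_map.get(key)
        if out is None:
            raise CostModelError(
                f"no output row for costed cell {key[0]!r} / {key[1].value}"
            )
        unit_map[key] = units.unit_costs(summary, out)

    weighted_s: Dict[Arm, CostSummary] = {}
    weighted_u: Dict[Arm, UnitCostRecord] = {}
    for arm in sorted({k[1] for k in summaries}, key=lambda a: a.value):
        arm_summaries = [s for k, s in summaries.items() if k[1] is arm]
        arm_units = [unit_map[(s.facility_id, s.arm)] for s in arm_summaries]
        weights = {
            s.facility_id: float(out_map[(s.facility_id, arm)].beneficiaries)
            for s in arm_summaries
        }
        weighted_s[arm] = units.weighted_summary(arm_summaries, weights)
        weighted_u[arm] = units.weighted_average(arm_units, weights)

    return CostingResult(
        summaries=summaries,
        units=unit_map,
        weighted_summary=weighted_s,
        weighted_units=weighted_u,
        lines=list(lines),
        unallocated_usd=remainder,
        n_research_excluded=excluded,
    )
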