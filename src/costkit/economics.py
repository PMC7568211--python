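"""Cost-effectiveness ratios and budget-impact projections.

Effect counts are exogenous inputs with citations (efficacy is imported from
external trials/meta-analyses, not modelled here), and the incremental cost is
an explicit input.  ICERs are cost per incremental effect unit; the budget
projection multiplies a target population by an assumed coverage (mobile phone
penetration) and a cost per beneficiary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import CostModelError, EffectInput, ProjectionInput
from .units import round_half_up


@dataclass(frozen=True)
class ICERResult:
    label: str
    incremental_cost_usd: float
    incremental_effect_count: float
    icer_usd: float

    @property
    def icer_usd_rounded(self) -> int:
        """ICER rounded half-up to whole USD, the usual reporting precision."""
        return int(round_half_up(self.icer_usd))


def icer(incremental_cost_usd: float, effect: EffectInput) -> ICERResult:
    """Incremental cost-effectiveness ratio: cost per incremental effect.

    Homogeneous of degree 1 in cost.  A non-positive effect count is an error
    (dominance analysis is out of scope).
    """
    effect.validate()
    if incremental_cost_usd < 0:
        raise CostModelError("incremental cost must be >= 0")
    return ICERResult(
        label=effect.label,
        incremental_cost_usd=incremental_cost_usd,
        incremental_effect_count=effect.incremental_effect_count,
        icer_usd=incremental_cost_usd / effect.incremental_effect_count,
    )


@dataclass(frozen=True)
class ProjectionResult:
    total_usd: float
    covered_population: float
    share_of_reference_budget_pct: Optional[float] = None

    @property
    def share_pct_rounded(self) -> Optional[int]:
        if self.share_of_reference_budget_pct is None:
            return None
        return int(round_half_up(self.share_of_reference_budget_pct))


def budget_projection(p: ProjectionInput) -> ProjectionResult:
    """National spending at scale: population x penetration x cost/beneficiary.

    If a reference budget is supplied, the projected spending is also
    expressed as a percentage of it.  The projection is multiplicative and
    monotone in each argument.
    """
    p.validate()
    covered = p.target_population * p.penetration
    total = covered * p.cost_per_beneficiary_usd
    share = None
    if p.reference_budget_usd is not None:
        if p.reference_budget_usd == 0:
            raise CostModelError("reference budget must be nonzero to compute a share")
        share = total / p.reference_budget_usd * 100.0
    return ProjectionResult(
        total_usd=total,
        covered_population=covered,
        share_of_reference_budget_pct=share,
    )
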