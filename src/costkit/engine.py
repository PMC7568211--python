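"""Annualization, shared-cost allocation and aggregation.

The engine turns validated ingredient lines into annual USD cost lines:

* capital (equipment) purchases are annuitized over their useful life at the
  configured discount rate,
* one-time start-up outlays are amortized straight-line over the start-up
  life (annuitized amortization is available as a config switch),
* recurrent lines enter at quantity x unit price for the analytic year,
* project-shared lines are apportioned to facilities by each facility's share
  of annual clients served,
* lines serving both trial arms are split by per-arm beneficiary counts,

and finally aggregates them into per-facility x arm summaries with totals by
activity, by input category and a fixed (start-up) / variable (recurrent)
split.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from . import io as _io
from .model import (
    Activity,
    Arm,
    CostIngredient,
    CostingConfig,
    CostLine,
    CostModelError,
    CostNature,
    CostSummary,
    FIXED_ACTIVITIES,
    FacilityOutput,
    InputCategory,
    PROJECT,
)

log = logging.getLogger("costkit")


def annuity_factor(rate: float, life: float) -> float:
    """Present value of a 1-per-year annuity: ``(1 - (1+r)^-n) / r``.

    Dividing a purchase price by this factor gives the equivalent annual cost
    of a capital item over ``life`` years at discount rate ``rate``.  At
    ``rate == 0`` the continuity limit ``life`` is returned.
    """
    if life <= 0:
        raise CostModelError(f"useful life must be > 0, got {life}")
    if rate < 0:
        raise CostModelError(f"discount rate must be >= 0, got {rate}")
    if rate == 0:
        return float(life)
    return (1.0 - (1.0 + rate) ** (-life)) / rate


def annualize(ingredient: CostIngredient, config: CostingConfig) -> float:
    """Annual USD cost of one ingredient line.

    Equipment: total price / annuity factor over the equipment life (the
    line's own ``useful_life_years`` wins over the config default).
    One-time start-up lines: straight-line total/life by default, or
    annuitized when ``startup_amortization == "annuitized"``.
    Recurrent lines: quantity x unit price over the analytic year.
    """
    total_usd = _io.convert_to_usd(ingredient.total_price, ingredient.currency, config)
    if ingredient.input_category is InputCategory.EQUIPMENT:
        life = ingredient.useful_life_years or config.equipment_life_years
        return total_usd / annuity_factor(config.discount_rate, life)
    if ingredient.cost_nature is CostNature.ONE_TIME:
        life = ingredient.useful_life_years or config.startup_life_years
        if config.startup_amortization == "annuitized":
            return total_usd / annuity_factor(config.discount_rate, life)
        return total_usd / life
    return total_usd


def to_cost_lines(
    ingredients: Iterable[CostIngredient], config: CostingConfig
) -> Tuple[List[CostLine], int]:
    """Annualize non-research ingredient lines into raw cost lines.

    Returns the lines plus the count of research-flagged rows excluded from
    the incremental analysis.
    """
    lines: List[CostLine] = []
    excluded = 0
    for ing in ingredients:
        if ing.research_flag:
            excluded += 1
            continue
        lines.append(
            CostLine(
                facility_id=ing.facility_id,
                arm=ing.arm,
                activity=ing.activity,
                input_category=ing.input_category,
                annual_usd=annualize(ing, config),
                source_id=ing.id,
            )
        )
    if excluded:
        log.info("excluded %d research-flagged ingredient row(s)", excluded)
    return lines, excluded


def facility_weights(
    outputs: Sequence[FacilityOutput],
) -> Dict[str, float]:
    """Allocation weight per facility: annual clients served, falling back to
    beneficiary counts for facilities that do not report client volume."""
    clients: Dict[str, Optional[int]] = {}
    bene: Dict[str, int] = defaultdict(int)
    for out in outputs:
        bene[out.facility_id] += out.beneficiaries
        prev = clients.get(out.facility_id)
        if prev is not None and out.clients_served_annual is not None \
                and prev != out.clients_served_annual:
            raise CostModelError(
                f"inconsistent clients_served_annual for {out.facility_id}"
            )
        if out.clients_served_annual is not None:
            clients[out.facility_id] = out.clients_served_annual
    weights: Dict[str, float] = {}
    for fac in bene:
        if clients.get(fac) is not None:
            weights[fac] = float(clients[fac])
        else:
            log.info(
                "facility %s lacks clients_served_annual; using beneficiaries "
                "as allocation weight", fac,
            )
            weights[fac] = float(bene[fac])
    return weights


def allocate_shared(
    lines: Sequence[CostLine],
    outputs: Sequence[FacilityOutput],
    project_total_clients: Optional[float] = None,
) -> Tuple[List[CostLine], float]:
    """Apportion project-shared cost lines to facilities.

    Each PROJECT-scoped line is split across the costed facilities in
    proportion to their annual clients served.  When ``project_total_clients``
    exceeds the summed weights of the costed facilities (the study costs a
    subset of sites), the complement of the shared line belongs to the
    uncosted facilities and is returned as the unallocated remainder in USD.
    With no external denominator the allocation is conservative: facility
    shares sum to the source amount.
    """
    if not outputs:
        raise CostModelError("cannot allocate shared costs without facility outputs")
    weights = facility_weights(outputs)
    total_w = sum(weights.values())
    if total_w <= 0:
        raise CostModelError("all facility allocation weights are zero")
    denom = float(project_total_clients) if project_total_clients else total_w
    if denom + 1e-9 < total_w:
        raise CostModelError(
            f"project_total_clients ({denom}) is smaller than the summed "
            f"facility weights ({total_w})"
        )
    allocated: List[CostLine] = []
    remainder = 0.0
    for line in lines:
        if line.facility_id != PROJECT:
            allocated.append(line)
            continue
        for fac, w in sorted(weights.items()):
            allocated.append(line.scaled(w / denom, facility_id=fac))
        remainder += line.annual_usd * (denom - total_w) / denom
    return allocated, remainder


def split_both_arms(
    lines: Sequence[CostLine], outputs: Sequence[FacilityOutput]
) -> List[CostLine]:
    """Split ``arm == both`` lines by per-arm beneficiary counts.

    The split uses the beneficiary counts of the line's own facility (lines
    must already be facility-level).  A facility with beneficiaries in only
    one arm assigns the whole line to that arm.
    """
    per_arm: Dict[str, Dict[Arm, int]] = defaultdict(dict)
    for out in outputs:
        per_arm[out.facility_id][out.arm] = out.beneficiaries
    result: List[CostLine] = []
    for line in lines:
        if line.arm is not Arm.BOTH:
            result.append(line)
            continue
        if line.facility_id == PROJECT:
            raise CostModelError(
                f"line {line.source_id!r}: allocate project-shared lines "
                "before splitting arms"
            )
        arms = per_arm.get(line.facility_id)
        if not arms:
            raise CostModelError(
                f"line {line.source_id!r} references facility "
                f"{line.facility_id!r} absent from the output table"
            )
        total = sum(arms.values())
        if total <= 0:
            raise CostModelError(
                f"facility {line.facility_id!r} has zero beneficiaries in "
                "every arm; cannot split a shared-arm line"
            )
        for arm, n in sorted(arms.items(), key=lambda kv: kv[0].value):
            if n > 0:
                result.append(line.scaled(n / total, arm=arm))
    return result


def aggregate(lines: Sequence[CostLine]) -> Dict[Tuple[str, Arm], CostSummary]:
    """Aggregate facility-level arm-specific cost lines into summaries.

    Totals by activity and by input category each sum to the grand total;
    the fixed total covers the one-time start-up activities (planning, system
    development, initial training, sensitization) and the variable total the
    recurrent input categories.  Aggregation is permutation-invariant and
    additive over disjoint line sets; an empty input yields no summaries.
    """
    by_act: Dict[Tuple[str, Arm], Dict[Activity, float]] = defaultdict(
        lambda: defaultdict(float)
    )
    by_cat: Dict[Tuple[str, Arm], Dict[InputCategory, float]] = defaultdict(
        lambda: defaultdict(float)
    )
    for line in lines:
        if line.arm is Arm.BOTH:
            raise CostModelError(
                f"line {line.source_id!r} still has arm='both'; split arms first"
            )
        key = (line.facility_id, line.arm)
        by_act[key][line.activity] += line.annual_usd
        by_cat[key][line.input_category] += line.annual_usd
    summaries: Dict[Tuple[str, Arm], CostSummary] = {}
    for key in by_act:
        acts = dict(by_act[key])
        cats = dict(by_cat[key])
        fixed = sum(v for a, v in acts.items() if a in FIXED_ACTIVITIES)
        total = sum(acts.values())
        summaries[key] = CostSummary(
            facility_id=key[0],
            arm=key[1],
            by_activity=acts,
            by_input_category=cats,
            fixed_total_usd=fixed,
            variable_total_usd=total - fixed,
            total_annual_usd=total,
        )
    return summaries
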