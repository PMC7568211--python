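"""Declarative what-if scenarios over a baseline costing run.

Two transformations cover the policy questions a scale-up analysis asks:

* **Scale-up**: run the intervention in more facilities.  One-time start-up
  investments and project-shared lines (system development, hosting platform,
  supervision/coordination) are kept once and re-allocated over the enlarged
  facility set; facility-scoped variable lines (service-delivery personnel,
  equipment, overhead, facility communication) are replicated for added
  facilities from a template facility.  Communication lines that scale with
  message volume grow with beneficiary counts rather than being replicated
  flat, since airtime and SMS fees track the number of messages exchanged.
* **Salary substitution**: replace research-project salaries of
  service-delivery roles with a government (MOH) salary table, emulating
  routine programme delivery after the pilot phase.

``apply_scenario`` is pure: it returns new tables and never mutates the
baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .model import (
    Activity,
    Arm,
    CostIngredient,
    CostingConfig,
    CostModelError,
    FacilityOutput,
    InputCategory,
    PROJECT,
    SharedScope,
    UnitCostRecord,
)
from .units import round_half_up

log = logging.getLogger("costkit")


@dataclass(frozen=True)
class Scenario:
    """A named, declarative transformation of the baseline tables.

    ``facility_beneficiaries`` maps facility id -> beneficiary count in the
    scenario (existing facilities are rescaled, new ones are added from
    ``template_facility``); ``arm`` restricts the scenario to one messaging
    arm; ``salary_table`` maps service-delivery role -> annual salary in USD;
    ``config_overrides`` are sparse CostingConfig field overrides.
    """

    name: str
    arm: Optional[Arm] = None
    facility_beneficiaries: Optional[Dict[str, int]] = None
    template_facility: Optional[str] = None
    salary_table: Optional[Dict[str, float]] = None
    config_overrides: Dict[str, object] = field(default_factory=dict)

    def validate(self) -> "Scenario":
        if self.facility_beneficiaries is not None:
            if not self.facility_beneficiaries:
                raise CostModelError(
                    f"scenario {self.name!r}: facility set must be non-empty"
                )
            for fac, n in self.facility_beneficiaries.items():
                if n <= 0:
                    raise CostModelError(
                        f"scenario {self.name!r}: facility {fac!r} must have a "
                        f"positive beneficiary count, got {n}"
                    )
        if self.salary_table is not None:
            for role, salary in self.salary_table.items():
                if salary < 0:
                    raise CostModelError(
                        f"scenario {self.name!r}: negative salary for {role!r}"
                    )
        return self

    @classmethod
    def from_dict(cls, name: str, block: dict) -> "Scenario":
        arm = block.get("arm")
        return cls(
            name=name,
            arm=Arm(arm) if arm else None,
            facility_beneficiaries=block.get("facility_beneficiaries"),
            template_facility=block.get("template_facility"),
            salary_table=block.get("salary_table"),
            config_overrides=block.get("config_overrides", {}) or {},
        ).validate()


def scenario_config(config: CostingConfig, scenario: Scenario) -> CostingConfig:
    """Apply a scenario's sparse config overrides to a baseline config."""
    if not scenario.config_overrides:
        return config
    return replace(config, **scenario.config_overrides).validate()


def _is_identity(scenario: Scenario) -> bool:
    return (
        scenario.arm is None
        and scenario.facility_beneficiaries is None
        and scenario.salary_table is None
    )


def _replicates(ing: CostIngredient) -> bool:
    """Facility-scoped variable lines replicate per added facility."""
    return (
        ing.shared_scope is SharedScope.FACILITY
        and ing.input_category is not InputCategory.STARTUP
    )


def _volume_scaled(ing: CostIngredient) -> bool:
    """Communication lines whose quantity tracks message volume."""
    return (
        ing.input_category is InputCategory.COMMUNICATION
        and ing.shared_scope is SharedScope.FACILITY
    )


def apply_scenario(
    ingredients: Sequence[CostIngredient],
    outputs: Sequence[FacilityOutput],
    scenario: Scenario,
) -> Tuple[List[CostIngredient], List[FacilityOutput]]:
    """Transform baseline tables under a scenario; the baseline is unmodified.

    Mechanics, in order: restrict to the scenario arm; rescale existing
    facilities' beneficiary and message counts; share one-time start-up lines
    project-wide; replicate the template facility's variable lines for added
    facilities (communication scaled by beneficiaries); substitute MOH
    salaries for service-delivery roles.
    """
    scenario.validate()
    if _is_identity(scenario):
        return list(ingredients), list(outputs)

    ings = list(ingredients)
    outs = list(outputs)

    if scenario.arm is not None:
        outs = [o for o in outs if o.arm is scenario.arm]
        ings = [i for i in ings if i.arm in (scenario.arm, Arm.BOTH)]
        if not outs:
            raise CostModelError(
                f"scenario {scenario.name!r}: baseline has no "
                f"{scenario.arm.value} output rows"
            )

    base_ben: Dict[Tuple[str, Arm], int] = {
        (o.facility_id, o.arm): o.beneficiaries for o in outs
    }
    base_fac_ben: Dict[str, int] = {}
    for o in outs:
        base_fac_ben[o.facility_id] = base_fac_ben.get(o.facility_id, 0) + o.beneficiaries

    if scenario.facility_beneficiaries is not None:
        targets = scenario.facility_beneficiaries
        existing = set(base_fac_ben)
        added = [f for f in targets if f not in existing]
        template = scenario.template_facility
        if added:
            if template is None or template not in existing:
                raise CostModelError(
                    f"scenario {scenario.name!r}: adding facilities requires a "
                    "template_facility present in the baseline"
                )

        # Rescale existing facilities' outputs; synthesize added facilities
        # from the template's per-beneficiary message rates.
        new_outs: List[FacilityOutput] = []
        for o in outs:
            target = targets.get(o.facility_id)
            if target is None:
                new_outs.append(o)
                continue
            ratio = target / base_fac_ben[o.facility_id]
            new_outs.append(
                replace(
                    o,
                    beneficiaries=int(round(o.beneficiaries * ratio)),
                    automated_messages=int(round(o.automated_messages * ratio)),
                    nurse_messages=int(round(o.nurse_messages * ratio)),
                )
            )
        template_rows = [o for o in outs if o.facility_id == template]
        for fac in added:
            for t in template_rows:
                ratio = targets[fac] / base_fac_ben[template]
                new_outs.append(
                    replace(
                        t,
                        facility_id=fac,
                        beneficiaries=int(round(t.beneficiaries * ratio)),
                        automated_messages=int(round(t.automated_messages * ratio)),
                        nurse_messages=int(round(t.nurse_messages * ratio)),
                        clients_served_annual=None
                        if t.clients_served_annual is None
                        else int(round(t.clients_served_annual * ratio)),
                    )
                )
        outs = new_outs

        new_ings: List[CostIngredient] = []
        for ing in ings:
            if ing.facility_id == PROJECT:
                new_ings.append(ing)
                continue
            # One-time start-up investments become shared project assets in a
            # scale-up: kept once, re-allocated over the enlarged facility set.
            if not _replicates(ing):
                new_ings.append(
                    replace(
                        ing,
                        facility_id=PROJECT,
                        shared_scope=SharedScope.PROJECT,
                        arm=ing.arm,
                    )
                )
                continue
            ratio = _scale_ratio(ing, targets, base_ben, base_fac_ben)
            if _volume_scaled(ing) and ratio != 1.0:
                ing = replace(ing, quantity=ing.quantity * ratio)
            new_ings.append(ing)
            if ing.facility_id == template:
                for fac in added:
                    rep = replace(ing, id=f"{fac}::{ing.id}", facility_id=fac)
                    if _volume_scaled(ing):
                        # replicate at the template's per-beneficiary rate,
                        # undoing the template's own rescaling first
                        rep = replace(
                            rep,
                            quantity=ing.quantity / ratio
                            * targets[fac]
                            / base_fac_ben[template],
                        )
                    new_ings.append(rep)
        ings = new_ings

    if scenario.salary_table is not None:
        ings = substitute_salaries(ings, scenario.salary_table, scenario.name)

    return ings, outs


def _scale_ratio(
    ing: CostIngredient,
    targets: Dict[str, int],
    base_ben: Dict[Tuple[str, Arm], int],
    base_fac_ben: Dict[str, int],
) -> float:
    target = targets.get(ing.facility_id)
    if target is None:
        return 1.0
    base = base_fac_ben.get(ing.facility_id, 0)
    if base <= 0:
        return 1.0
    return target / base


def substitute_salaries(
    ingredients: Sequence[CostIngredient],
    salary_table: Dict[str, float],
    scenario_name: str = "",
) -> List[CostIngredient]:
    """Replace unit prices of service-delivery personnel roles.

    Personnel lines carry person-time quantities (months) at a monthly unit
    price; substitution swaps the monthly price for ``annual_salary / 12``
    while preserving the time quantity.  Roles in the table that match no
    baseline line trigger a warning and are otherwise a no-op.
    """
    seen_roles = set()
    result: List[CostIngredient] = []
    for ing in ingredients:
        role = ing.role
        if (
            role in salary_table
            and ing.activity is Activity.SERVICE_DELIVERY
            and ing.input_category is InputCategory.PERSONNEL
        ):
            seen_roles.add(role)
            result.append(
                replace(ing, unit_price=salary_table[role] / 12.0, currency="USD")
            )
        else:
            result.append(ing)
    for role in sorted(set(salary_table) - seen_roles):
        log.warning(
            "scenario %s: salary-table role %r matches no service-delivery "
            "personnel line; ignored",
            scenario_name or "<unnamed>",
            role,
        )
    return result


@dataclass(frozen=True)
class RunComparison:
    """Relative change of an alternative run against a baseline run."""

    arm: Arm
    base_cost_per_beneficiary_usd: float
    alt_cost_per_beneficiary_usd: float
    base_cost_per_contact_usd: float
    alt_cost_per_contact_usd: float
    pct_decrease_per_beneficiary: float
    pct_decrease_per_contact: float

    @property
    def pct_decrease_per_beneficiary_int(self) -> int:
        return int(round_half_up(self.pct_decrease_per_beneficiary))

    @property
    def pct_decrease_per_contact_int(self) -> int:
        return int(round_half_up(self.pct_decrease_per_contact))


def compare_runs(base: UnitCostRecord, alt: UnitCostRecord) -> RunComparison:
    """Percent change of unit costs: ``(base - alt) / base * 100``.

    Positive values are decreases, as scale-up results are usually quoted.
    """
    if base.arm is not alt.arm:
        raise CostModelError(
            f"cannot compare runs across arms ({base.arm.value} vs {alt.arm.value})"
        )
    if base.cost_per_beneficiary_usd <= 0 or base.cost_per_contact_usd <= 0:
        raise CostModelError("baseline unit costs must be positive for comparison")
    return RunComparison(
        arm=base.arm,
        base_cost_per_beneficiary_usd=base.cost_per_beneficiary_usd,
        alt_cost_per_beneficiary_usd=alt.cost_per_beneficiary_usd,
        base_cost_per_contact_usd=base.cost_per_contact_usd,
        alt_cost_per_contact_usd=alt.cost_per_contact_usd,
        pct_decrease_per_beneficiary=(
            (base.cost_per_beneficiary_usd - alt.cost_per_beneficiary_usd)
            / base.cost_per_beneficiary_usd
            * 100.0
        ),
        pct_decrease_per_contact=(
            (base.cost_per_contact_usd - alt.cost_per_contact_usd)
            / base.cost_per_contact_usd
            * 100.0
        ),
    )
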