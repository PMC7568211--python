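"""Domain types for ingredient-based microcosting.

The data model follows the activity-based ingredients approach used in
provider-perspective costing of health programmes: every resource consumed by
the intervention is one priced line item (a :class:`CostIngredient`), tagged by
facility, trial arm, programme activity, input category and sharing scope.
Facility throughput (beneficiaries and message contacts) lives in
:class:`FacilityOutput`; run-wide parameters (discount rate, useful lives,
exchange rate) live in :class:`CostingConfig`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Mapping, Optional

#: Sentinel facility id for project-shared lines (e.g. study coordinator,
#: data manager, system hosting) that are allocated to facilities later.
PROJECT = "PROJECT"

#: Sentinel facility id for cross-facility beneficiary-weighted averages.
WEIGHTED = "WEIGHTED"


class CostModelError(ValueError):
    """Base class for validation problems in the costing data model."""


class SchemaError(CostModelError):
    """A table does not match the documented column schema."""


class RowValidationError(CostModelError):
    """A single table row violates a type invariant.

    ``row`` is the 1-based data-row number (header excluded) when known.
    """

    def __init__(self, message: str, row: Optional[int] = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class Arm(str, enum.Enum):
    """Trial arm an ingredient or output belongs to."""

    TWO_WAY = "two_way"
    ONE_WAY = "one_way"
    BOTH = "both"  # resource shared by both arms, split downstream


class Activity(str, enum.Enum):
    """Mutually exclusive programme activities (avoids double counting)."""

    PLANNING = "planning"
    SYSTEM_DEVELOPMENT = "system_development"
    INITIAL_TRAINING = "initial_training"
    SENSITIZATION = "sensitization"
    SERVICE_DELIVERY = "service_delivery"
    SUPERVISION_COORDINATION = "supervision_coordination"
    COMMUNICATION_DELIVERY = "communication_delivery"
    OVERHEAD_ADMIN = "overhead_admin"


class InputCategory(str, enum.Enum):
    PERSONNEL = "personnel"
    COMMUNICATION = "communication"
    EQUIPMENT = "equipment"
    OVERHEAD = "overhead"
    STARTUP = "startup"


class CostNature(str, enum.Enum):
    ONE_TIME = "one_time"
    RECURRENT = "recurrent"


class SharedScope(str, enum.Enum):
    FACILITY = "facility"
    PROJECT = "project"


#: One-time start-up activities; their annualized cost is the "fixed" side of
#: the fixed/variable split.  Everything else is recurrent ("variable").
FIXED_ACTIVITIES = frozenset(
    {
        Activity.PLANNING,
        Activity.SYSTEM_DEVELOPMENT,
        Activity.INITIAL_TRAINING,
        Activity.SENSITIZATION,
    }
)

#: Admissible (activity, input category) pairs of the costing taxonomy.
#: Start-up activities carry the start-up input category; recurrent input
#: categories hang off the delivery/supervision/communication/overhead
#: activities.  Equipment is purchased for service or message delivery.
ALLOWED_PAIRS = frozenset(
    {
        (Activity.PLANNING, InputCategory.STARTUP),
        (Activity.SYSTEM_DEVELOPMENT, InputCategory.STARTUP),
        (Activity.INITIAL_TRAINING, InputCategory.STARTUP),
        (Activity.SENSITIZATION, InputCategory.STARTUP),
        (Activity.SERVICE_DELIVERY, InputCategory.PERSONNEL),
        (Activity.SERVICE_DELIVERY, InputCategory.EQUIPMENT),
        (Activity.SUPERVISION_COORDINATION, InputCategory.PERSONNEL),
        (Activity.COMMUNICATION_DELIVERY, InputCategory.COMMUNICATION),
        (Activity.COMMUNICATION_DELIVERY, InputCategory.EQUIPMENT),
        (Activity.OVERHEAD_ADMIN, InputCategory.OVERHEAD),
    }
)

SUPPORTED_CURRENCIES = ("USD", "KES")


@dataclass(frozen=True)
class CostIngredient:
    """One priced resource line: ``quantity`` units at ``unit_price`` each.

    ``useful_life_years`` is required for non-equipment one-time lines;
    equipment may omit it and falls back to the configured equipment life.
    ``research_flag`` marks lines kept for documentation of the full trial
    budget but excluded from every incremental total downstream.
    """

    id: str
    facility_id: str
    arm: Arm
    activity: Activity
    input_category: InputCategory
    cost_nature: CostNature
    quantity: float
    quantity_unit: str
    unit_price: float
    currency: str
    useful_life_years: Optional[float] = None
    shared_scope: SharedScope = SharedScope.FACILITY
    research_flag: bool = False

    def validate(self, row: Optional[int] = None) -> "CostIngredient":
        if not self.id:
            raise RowValidationError("ingredient id must be non-empty", row)
        if not self.facility_id:
            raise RowValidationError("facility_id must be non-empty", row)
        if self.quantity < 0:
            raise RowValidationError(
                f"quantity must be >= 0, got {self.quantity}", row
            )
        if self.unit_price < 0:
            raise RowValidationError(
                f"unit_price must be >= 0, got {self.unit_price}", row
            )
        if self.currency not in SUPPORTED_CURRENCIES:
            raise RowValidationError(
                f"unsupported currency {self.currency!r} "
                f"(expected one of {SUPPORTED_CURRENCIES})",
                row,
            )
        if (self.activity, self.input_category) not in ALLOWED_PAIRS:
            raise RowValidationError(
                f"({self.activity.value}, {self.input_category.value}) is not an "
                "admissible activity/input-category pair",
                row,
            )
        if self.useful_life_years is not None and self.useful_life_years <= 0:
            raise RowValidationError(
                f"useful_life_years must be > 0, got {self.useful_life_years}", row
            )
        needs_life = (
            self.cost_nature is CostNature.ONE_TIME
            and self.input_category is not InputCategory.EQUIPMENT
        )
        if needs_life and self.useful_life_years is None:
            raise RowValidationError(
                f"one-time line {self.id!r} requires useful_life_years", row
            )
        if self.shared_scope is SharedScope.PROJECT and self.facility_id != PROJECT:
            raise RowValidationError(
                f"project-scoped line {self.id!r} must use facility_id "
                f"{PROJECT!r}, got {self.facility_id!r}",
                row,
            )
        if self.facility_id == PROJECT and self.shared_scope is not SharedScope.PROJECT:
            raise RowValidationError(
                f"line {self.id!r} has facility_id {PROJECT!r} but scope "
                f"{self.shared_scope.value!r}",
                row,
            )
        return self

    @property
    def total_price(self) -> float:
        """Quantity times unit price, in the line's own currency."""
        return self.quantity * self.unit_price

    @property
    def role(self) -> Optional[str]:
        """Personnel role parsed from an ``...__<role>`` id suffix, if any."""
        if "__" in self.id:
            return self.id.rsplit("__", 1)[1]
        return None


@dataclass(frozen=True)
class FacilityOutput:
    """Annual throughput of one facility x arm cell.

    ``clients_served_annual`` is the facility's total annual client volume
    (the weight used to allocate project-shared costs); it is a facility-level
    quantity repeated on each arm row.
    """

    facility_id: str
    arm: Arm
    beneficiaries: int
    automated_messages: int
    nurse_messages: int
    clients_served_annual: Optional[int] = None

    def validate(self, row: Optional[int] = None) -> "FacilityOutput":
        if not self.facility_id or self.facility_id in (PROJECT, WEIGHTED):
            raise RowValidationError(
                f"invalid facility_id {self.facility_id!r} in output table", row
            )
        if self.arm is Arm.BOTH:
            raise RowValidationError("output rows must be arm-specific", row)
        for name in ("beneficiaries", "automated_messages", "nurse_messages"):
            if getattr(self, name) < 0:
                raise RowValidationError(f"{name} must be >= 0", row)
        if self.arm is Arm.ONE_WAY and self.nurse_messages != 0:
            raise RowValidationError(
                "one-way arm cannot have nurse messages "
                f"(facility {self.facility_id})",
                row,
            )
        if self.clients_served_annual is not None and self.clients_served_annual < 0:
            raise RowValidationError("clients_served_annual must be >= 0", row)
        return self

    @property
    def contacts(self) -> int:
        """Total successful message contacts: automated plus nurse-sent."""
        return self.automated_messages + self.nurse_messages


@dataclass(frozen=True)
class CostingConfig:
    """Run-wide costing parameters.

    Defaults reflect a 2017 Kenyan provider-perspective analysis: 3%/year
    discount rate, 10-year equipment life, 5-year start-up life, and the 2017
    official exchange rate of 103.25 KES per USD.  ``project_total_clients``
    is the denominator for allocating project-shared costs; when it exceeds
    the summed weights of the costed facilities, the remainder belongs to
    uncosted facilities and stays unallocated.
    """

    discount_rate: float = 0.03
    equipment_life_years: float = 10.0
    startup_life_years: float = 5.0
    exchange_rate_kes_per_usd: float = 103.25
    startup_amortization: str = "straight_line"  # or "annuitized"
    rounding: str = "half_up"  # "none" | "half_up" | "half_even"
    project_total_clients: Optional[float] = None

    def validate(self) -> "CostingConfig":
        if self.discount_rate < 0:
            raise CostModelError("discount_rate must be >= 0")
        if self.equipment_life_years <= 0 or self.startup_life_years <= 0:
            raise CostModelError("useful lives must be > 0")
        if self.exchange_rate_kes_per_usd <= 0:
            raise CostModelError("exchange rate must be > 0")
        if self.startup_amortization not in ("straight_line", "annuitized"):
            raise CostModelError(
                f"unknown startup_amortization {self.startup_amortization!r}"
            )
        if self.rounding not in ("none", "half_up", "half_even"):
            raise CostModelError(f"unknown rounding mode {self.rounding!r}")
        if self.project_total_clients is not None and self.project_total_clients <= 0:
            raise CostModelError("project_total_clients must be > 0")
        return self


@dataclass(frozen=True)
class CostLine:
    """One annualized, USD-denominated cost attribution to a facility x arm.

    ``allocation_fraction`` records which share of the source ingredient's
    annual value this line carries (allocation of project-shared lines and
    arm-splitting both produce fractions < 1); over all lines descended from
    one ingredient the fractions sum to the allocated share of that line.
    """

    facility_id: str
    arm: Arm
    activity: Activity
    input_category: InputCategory
    annual_usd: float
    source_id: str
    allocation_fraction: float = 1.0

    def scaled(self, fraction: float, facility_id: Optional[str] = None,
               arm: Optional[Arm] = None) -> "CostLine":
        return replace(
            self,
            annual_usd=self.annual_usd * fraction,
            allocation_fraction=self.allocation_fraction * fraction,
            facility_id=self.facility_id if facility_id is None else facility_id,
            arm=self.arm if arm is None else arm,
        )


@dataclass(frozen=True)
class CostSummary:
    """Annual incremental cost totals for one facility x arm (or weighted)."""

    facility_id: str
    arm: Arm
    by_activity: Mapping[Activity, float]
    by_input_category: Mapping[InputCategory, float]
    fixed_total_usd: float
    variable_total_usd: float
    total_annual_usd: float

    def activity_total(self, activity: Activity) -> float:
        return self.by_activity.get(activity, 0.0)

    def category_total(self, category: InputCategory) -> float:
        return self.by_input_category.get(category, 0.0)


@dataclass(frozen=True)
class UnitCostRecord:
    """Total and per-unit (beneficiary, contact) costs for a facility x arm.

    The ``WEIGHTED`` sentinel row carries the beneficiary-weighted average
    across facilities; for that row ``cost_per_contact_pooled_usd`` is also
    populated (pooled cost over pooled contacts), since the two definitions
    differ slightly and neither is canonical.
    """

    facility_id: str
    arm: Arm
    total_annual_usd: float
    beneficiaries: float
    contacts: float
    cost_per_beneficiary_usd: float
    cost_per_contact_usd: float
    cost_per_contact_pooled_usd: Optional[float] = None


@dataclass(frozen=True)
class EffectInput:
    """An exogenous incremental health effect count with its citation."""

    label: str
    incremental_effect_count: float
    source: str = ""

    def validate(self) -> "EffectInput":
        if self.incremental_effect_count <= 0:
            raise CostModelError(
                f"effect count for {self.label!r} must be > 0 "
                "(dominance analysis is out of scope)"
            )
        return self


@dataclass(frozen=True)
class ProjectionInput:
    """Inputs for a national budget-impact projection."""

    target_population: float
    penetration: float
    cost_per_beneficiary_usd: float
    reference_budget_usd: Optional[float] = None

    def validate(self) -> "ProjectionInput":
        if not (0.0 <= self.penetration <= 1.0):
            raise CostModelError("penetration must be in [0, 1]")
        if self.target_population < 0 or self.cost_per_beneficiary_usd < 0:
            raise CostModelError("counts and costs must be >= 0")
        if self.reference_budget_usd is not None and self.reference_budget_usd < 0:
            raise CostModelError("reference budget must be >= 0")
        return self
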