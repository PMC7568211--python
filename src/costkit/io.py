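"""Reading and writing of ingredient tables, output tables, config and reports.

CSV dialect: UTF-8, comma-separated, header row required, decimal point, no
thousands separators.  Column names are fixed (see INGREDIENT_COLUMNS and
OUTPUT_COLUMNS) so that a table written by :func:`write_ingredients` reads
back identically.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .model import (
    Arm,
    Activity,
    CostIngredient,
    CostingConfig,
    CostModelError,
    CostNature,
    CostSummary,
    FacilityOutput,
    InputCategory,
    RowValidationError,
    SchemaError,
    SharedScope,
    UnitCostRecord,
)

log = logging.getLogger("costkit")

INGREDIENT_COLUMNS = [
    "id",
    "facility_id",
    "arm",
    "activity",
    "input_category",
    "cost_nature",
    "quantity",
    "quantity_unit",
    "unit_price",
    "currency",
    "useful_life_years",
    "shared_scope",
    "research_flag",
]

OUTPUT_COLUMNS = [
    "facility_id",
    "arm",
    "beneficiaries",
    "automated_messages",
    "nurse_messages",
    "clients_served_annual",
]


def convert_to_usd(amount: float, currency: str, config: CostingConfig) -> float:
    """Convert ``amount`` in ``currency`` to USD at the configured fixed rate.

    USD amounts pass through unchanged; KES amounts are divided by
    ``exchange_rate_kes_per_usd`` (103.25 KES/USD by default, the official
    2017 rate).  The conversion is linear and idempotent on USD.
    """
    if amount < 0:
        raise CostModelError(f"cannot convert negative amount {amount}")
    if currency == "USD":
        return amount
    if currency == "KES":
        return amount / config.exchange_rate_kes_per_usd
    raise CostModelError(f"unknown currency code {currency!r}")


def _check_columns(df: pd.DataFrame, expected: Sequence[str], what: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    unknown = [c for c in df.columns if c not in expected]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")
    if unknown:
        raise SchemaError(f"{what}: unknown column(s) {unknown}")


def _parse_enum(enum_cls, value, name: str, row: int):
    try:
        return enum_cls(str(value).strip())
    except ValueError:
        raise RowValidationError(
            f"invalid {name} {value!r} (expected one of "
            f"{[e.value for e in enum_cls]})",
            row,
        ) from None


def _parse_bool(value, name: str, row: int) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no", "", "nan"):
        return False
    raise RowValidationError(f"invalid boolean {value!r} for {name}", row)


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or (
        isinstance(value, str) and not value.strip()
    )


def read_ingredients(path) -> List[CostIngredient]:
    """Read and validate an ingredient-level cost table.

    Every row is validated against the type invariants (non-negative quantity
    and price, admissible activity/input-category pair, useful life present on
    one-time lines).  Research-flagged rows are retained but marked; they are
    excluded later, at aggregation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, INGREDIENT_COLUMNS, f"ingredient table {path.name}")
    rows: List[CostIngredient] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        try:
            life = None if _is_blank(rec["useful_life_years"]) else float(
                rec["useful_life_years"]
            )
            ing = CostIngredient(
                id=rec["id"].strip(),
                facility_id=rec["facility_id"].strip(),
                arm=_parse_enum(Arm, rec["arm"], "arm", i),
                activity=_parse_enum(Activity, rec["activity"], "activity", i),
                input_category=_parse_enum(
                    InputCategory, rec["input_category"], "input_category", i
                ),
                cost_nature=_parse_enum(
                    CostNature, rec["cost_nature"], "cost_nature", i
                ),
                quantity=float(rec["quantity"]),
                quantity_unit=rec["quantity_unit"].strip(),
                unit_price=float(rec["unit_price"]),
                currency=rec["currency"].strip(),
                useful_life_years=life,
                shared_scope=_parse_enum(
                    SharedScope, rec["shared_scope"], "shared_scope", i
                ),
                research_flag=_parse_bool(rec["research_flag"], "research_flag", i),
            )
        except (ValueError, TypeError) as exc:
            if isinstance(exc, RowValidationError):
                raise
            raise RowValidationError(str(exc), i) from exc
        rows.append(ing.validate(row=i))
    log.info("read %d ingredient rows from %s", len(rows), path)
    return rows


def write_ingredients(rows: Sequence[CostIngredient], path) -> None:
    df = pd.DataFrame(
        [
            {
                "id": r.id,
                "facility_id": r.facility_id,
                "arm": r.arm.value,
                "activity": r.activity.value,
                "input_category": r.input_category.value,
                "cost_nature": r.cost_nature.value,
                "quantity": repr(r.quantity),
                "quantity_unit": r.quantity_unit,
                "unit_price": repr(r.unit_price),
                "currency": r.currency,
                "useful_life_years": ""
                if r.useful_life_years is None
                else repr(r.useful_life_years),
                "shared_scope": r.shared_scope.value,
                "research_flag": str(r.research_flag).lower(),
            }
            for r in rows
        ],
        columns=INGREDIENT_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_outputs(path) -> List[FacilityOutput]:
    """Read and validate a facility output (throughput) table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, OUTPUT_COLUMNS, f"output table {path.name}")
    rows: List[FacilityOutput] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        try:
            clients = (
                None
                if _is_blank(rec["clients_served_annual"])
                else int(float(rec["clients_served_annual"]))
            )
            out = FacilityOutput(
                facility_id=rec["facility_id"].strip(),
                arm=_parse_enum(Arm, rec["arm"], "arm", i),
                beneficiaries=int(float(rec["beneficiaries"])),
                automated_messages=int(float(rec["automated_messages"])),
                nurse_messages=int(float(rec["nurse_messages"])),
                clients_served_annual=clients,
            )
        except (ValueError, TypeError) as exc:
            if isinstance(exc, RowValidationError):
                raise
            raise RowValidationError(str(exc), i) from exc
        rows.append(out.validate(row=i))
    seen = set()
    for r in rows:
        key = (r.facility_id, r.arm)
        if key in seen:
            raise SchemaError(f"duplicate output row for {key}")
        seen.add(key)
    log.info("read %d output rows from %s", len(rows), path)
    return rows


def write_outputs(rows: Sequence[FacilityOutput], path) -> None:
    df = pd.DataFrame(
        [
            {
                "facility_id": r.facility_id,
                "arm": r.arm.value,
                "beneficiaries": r.beneficiaries,
                "automated_messages": r.automated_messages,
                "nurse_messages": r.nurse_messages,
                "clients_served_annual": ""
                if r.clients_served_annual is None
                else r.clients_served_annual,
            }
            for r in rows
        ],
        columns=OUTPUT_COLUMNS,
    )
    df.to_csv(path, index=False)


CONFIG_FIELDS = (
    "discount_rate",
    "equipment_life_years",
    "startup_life_years",
    "exchange_rate_kes_per_usd",
    "startup_amortization",
    "rounding",
    "project_total_clients",
)


def read_config(path) -> Tuple[CostingConfig, dict]:
    """Read a YAML run configuration.

    Returns the validated :class:`CostingConfig` plus the raw mapping, which
    may carry additional blocks (``economics:``, ``scenarios:``) consumed by
    other modules.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"config {path.name} must be a YAML mapping")
    kwargs = {k: raw[k] for k in CONFIG_FIELDS if k in raw}
    config = CostingConfig(**kwargs).validate()
    return config, raw


# ---------------------------------------------------------------------------
# Report writing


def _summary_payload(summary: CostSummary, unit: Optional[UnitCostRecord]) -> dict:
    payload = {
        "facility_id": summary.facility_id,
        "arm": summary.arm.value,
        "by_activity": {a.value: summary.activity_total(a) for a in Activity},
        "by_input_category": {
            c.value: summary.category_total(c) for c in InputCategory
        },
        "fixed_total_usd": summary.fixed_total_usd,
        "variable_total_usd": summary.variable_total_usd,
        "total_annual_usd": summary.total_annual_usd,
    }
    if unit is not None:
        payload.update(
            {
                "beneficiaries": unit.beneficiaries,
                "contacts": unit.contacts,
                "cost_per_beneficiary_usd": unit.cost_per_beneficiary_usd,
                "cost_per_contact_usd": unit.cost_per_contact_usd,
            }
        )
        if unit.cost_per_contact_pooled_usd is not None:
            payload["cost_per_contact_pooled_usd"] = unit.cost_per_contact_pooled_usd
    return payload


def report_payload(result) -> dict:
    """Build the JSON-serializable report for a :class:`~costkit.pipeline.CostingResult`."""
    facilities = [
        _summary_payload(s, result.units.get((s.facility_id, s.arm)))
        for s in result.facility_summaries()
    ]
    weighted = [
        _summary_payload(result.weighted_summary[arm], result.weighted_units[arm])
        for arm in sorted(result.weighted_summary, key=lambda a: a.value, reverse=True)
    ]
    return {
        "facilities": facilities,
        "weighted": weighted,
        "research_rows_excluded": result.n_research_excluded,
    }


def write_report(result, path, format: str = "json", extras: Optional[dict] = None) -> None:
    """Write a machine-readable cost report (JSON or CSV).

    The report carries totals by activity and input category, the
    fixed/variable split, unit costs per facility x arm, and the
    beneficiary-weighted rows (always last).  An empty result is an error,
    never an empty file.
    """
    payload = report_payload(result)
    if not payload["facilities"]:
        raise CostModelError("refusing to write a report for an empty cost summary")
    if extras:
        payload.update(extras)
    path = Path(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=False)
            fh.write("\n")
    elif format == "csv":
        rows = []
        for block in (payload["facilities"], payload["weighted"]):
            for entry in block:
                flat = {
                    "facility_id": entry["facility_id"],
                    "arm": entry["arm"],
                }
                flat.update(
                    {f"activity_{k}": v for k, v in entry["by_activity"].items()}
                )
                flat.update(
                    {
                        f"category_{k}": v
                        for k, v in entry["by_input_category"].items()
                    }
                )
                for key in (
                    "fixed_total_usd",
                    "variable_total_usd",
                    "total_annual_usd",
                    "beneficiaries",
                    "contacts",
                    "cost_per_beneficiary_usd",
                    "cost_per_contact_usd",
                    "cost_per_contact_pooled_usd",
                ):
                    if key in entry:
                        flat[key] = entry[key]
                rows.append(flat)
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise CostModelError(f"unknown report format {format!r}")
    log.info("wrote %s report to %s", format, path)


def read_report(path) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
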