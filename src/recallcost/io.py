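"""CSV/JSON readers and writers for the ledger, wage, macro and timing tables.

Ledger CSV schema (one header row, UTF-8, period decimal separator; empty
string means an absent optional field)::

    id,country,modality,activity,subactivity,cost_centre,payer,currency,
    year,amount,quantity,is_capital,useful_life_years,role,person_minutes,
    variability,location

``location`` extends the core schema: it is required to re-price
international staff in the localisation scenario.  Round-tripping a ledger
through CSV reproduces every field exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

from .ledger import (
    Activity,
    CostCentre,
    CostItem,
    Country,
    InterviewTiming,
    Location,
    MacroTable,
    Modality,
    Money,
    RoleWage,
    Site,
    Variability,
    WageTable,
)

__all__ = [
    "read_ledger_csv",
    "write_ledger_csv",
    "read_wages_csv",
    "write_wages_csv",
    "read_macro_csv",
    "write_macro_csv",
    "read_timings_csv",
    "write_timings_csv",
]

_LEDGER_COLUMNS = [
    "id",
    "country",
    "modality",
    "activity",
    "subactivity",
    "cost_centre",
    "payer",
    "currency",
    "year",
    "amount",
    "quantity",
    "is_capital",
    "useful_life_years",
    "role",
    "person_minutes",
    "variability",
    "location",
]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)  # shortest round-trip representation
    return str(value)


def _opt_float(s: str) -> Optional[float]:
    return float(s) if s not in ("", None) else None


def write_ledger_csv(items: Sequence[CostItem], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_LEDGER_COLUMNS)
        for it in items:
            w.writerow(
                [
                    it.id,
                    it.country.value,
                    it.modality.value,
                    it.activity.value,
                    it.subactivity,
                    it.centre.value,
                    it.payer,
                    it.money.currency,
                    it.money.year,
                    _fmt(it.money.amount),
                    _fmt(it.quantity),
                    _fmt(it.is_capital),
                    _fmt(it.useful_life),
                    _fmt(it.role),
                    _fmt(it.person_minutes),
                    it.variability.value if it.variability else "",
                    it.location.value if it.location else "",
                ]
            )


def read_ledger_csv(path: str | Path) -> list[CostItem]:
    items: list[CostItem] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            items.append(
                CostItem(
                    id=row["id"],
                    country=Country(row["country"]),
                    modality=Modality(row["modality"]),
                    activity=Activity(row["activity"]),
                    subactivity=row["subactivity"],
                    centre=CostCentre(row["cost_centre"]),
                    payer=row["payer"],
                    money=Money(
                        float(row["amount"]), row["currency"], int(row["year"])
                    ),
                    quantity=float(row["quantity"]) if row["quantity"] else 1.0,
                    is_capital=row["is_capital"] == "true",
                    useful_life=_opt_float(row["useful_life_years"]),
                    role=row["role"] or None,
                    person_minutes=_opt_float(row["person_minutes"]),
                    variability=Variability(row["variability"])
                    if row["variability"]
                    else None,
                    location=Location(row["location"]) if row["location"] else None,
                )
            )
    return items


def write_wages_csv(wages: WageTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["role", "location", "currency", "year", "wage_per_day"])
        for rw in sorted(wages, key=lambda r: (r.role, r.location.value)):
            w.writerow(
                [rw.role, rw.location.value, rw.wage.currency, rw.wage.year, _fmt(rw.wage.amount)]
            )


def read_wages_csv(path: str | Path) -> WageTable:
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            rows.append(
                RoleWage(
                    role=row["role"],
                    location=Location(row["location"]),
                    wage=Money(
                        float(row["wage_per_day"]), row["currency"], int(row["year"])
                    ),
                )
            )
    return WageTable(rows)


def write_macro_csv(macro: MacroTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["currency", "year", "deflator", "fx_per_usd"])
        for cur, year, deflator, fx in macro.items():
            w.writerow([cur, year, _fmt(deflator), _fmt(fx)])


def read_macro_csv(path: str | Path) -> MacroTable:
    deflator: dict[tuple[str, int], float] = {}
    fx: dict[tuple[str, int], float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            key = (row["currency"], int(row["year"]))
            if row["deflator"]:
                deflator[key] = float(row["deflator"])
            if row["fx_per_usd"] and row["currency"] != "USD":
                fx[key] = float(row["fx_per_usd"])
    return MacroTable(deflator, fx)


_TIMING_COLUMNS = [
    "respondent_id",
    "country",
    "modality",
    "site",
    "pass1",
    "pass2",
    "pass3",
    "nonstd_recipe",
    "pass4",
    "menu",
    "total",
]


def write_timings_csv(records: Sequence[InterviewTiming], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_TIMING_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.respondent_id,
                    r.country.value,
                    r.modality.value,
                    r.site.value,
                    _fmt(r.pass1),
                    _fmt(r.pass2),
                    _fmt(r.pass3),
                    _fmt(r.nonstandard_recipe),
                    _fmt(r.pass4),
                    _fmt(r.menu),
                    _fmt(r.total_minutes),
                ]
            )


def read_timings_csv(path: str | Path) -> list[InterviewTiming]:
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(
                InterviewTiming(
                    respondent_id=row["respondent_id"],
                    country=Country(row["country"]),
                    modality=Modality(row["modality"]),
                    site=Site(row["site"]),
                    pass1=float(row["pass1"]),
                    pass2=float(row["pass2"]),
                    pass3=float(row["pass3"]),
                    nonstandard_recipe=float(row["nonstd_recipe"]),
                    pass4=float(row["pass4"]),
                    menu=_opt_float(row["menu"]),
                    total_minutes=_opt_float(row["total"]),
                )
            )
    return records
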