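"""Domain types for activity-based survey cost ledgers.

The costing model follows the activity/ingredients approach used in health
economics: a survey is decomposed into a closed set of activities (preparing
dietary reference data, survey preparation, training, survey execution, data
entry, data cleaning/processing, and administration), and each activity
consumes priced inputs ("ingredients") classified by cost centre (personnel,
equipment, per diem, ...).  A :class:`CostItem` is the atom of the ledger:
one priced ingredient of one subactivity, tagged with the data-collection
modality it supports (the electronic CAPI arm, the pen-and-paper PAPI arm,
or ``shared`` for inputs — chiefly dietary reference data — used by both).

Monetary amounts are :class:`Money` values carrying their currency and the
calendar year of payment; conversion to base-year US dollars is the job of
:mod:`recallcost.valuation`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Country",
    "Modality",
    "Activity",
    "CostCentre",
    "Location",
    "Variability",
    "Site",
    "Money",
    "CostItem",
    "RoleWage",
    "WageTable",
    "MacroTable",
    "InterviewTiming",
    "TimeLogEntry",
    "Violation",
    "validate_ledger",
    "MacroLookupError",
    "WageLookupError",
    "DAY_MINUTES",
    "DEFAULT_USEFUL_LIVES",
    "PERSONNEL_ROLES",
]

#: Minutes in one person-day (8-hour working day).  Configurable through
#: :class:`recallcost.valuation.ValuationParams`; this is the default.
DAY_MINUTES = 480.0

#: Useful lives (years) recognised by default for capital equipment:
#: food scales (2), tablets and computers (3), portable hard drives (4),
#: storage cabinets and standard weights (10).
DEFAULT_USEFUL_LIVES = (2, 3, 4, 10)

#: Personnel-role keys used in wage tables.
PERSONNEL_ROLES = (
    "enumerator",
    "field_supervisor",
    "data_entry_clerk",
    "data_supervisor",
    "translator",
    "coordinator",
    "researcher",
    "lead_researcher",
    "statistician",
    "administrator",
    "chef",
    "technical_advisor",
)


class Country(str, enum.Enum):
    VIETNAM = "vietnam"
    BURKINA_FASO = "burkina_faso"


class Modality(str, enum.Enum):
    """Data-collection arm a cost item belongs to.

    ``SHARED`` items (e.g. dietary reference data preparation) served both
    arms; by default they are counted at full cost in each arm's total.
    """

    INDDEX24 = "inddex24"
    PAPI = "papi"
    SHARED = "shared"


class Activity(str, enum.Enum):
    DIETARY_REFERENCE_DATA_PREP = "dietary_reference_data_prep"
    SURVEY_PREPARATION = "survey_preparation"
    TRAINING = "training"
    SURVEY_EXECUTION = "survey_execution"
    DATA_ENTRY = "data_entry"
    DATA_CLEANING_PROCESSING = "data_cleaning_processing"
    ADMINISTRATION = "administration"


class CostCentre(str, enum.Enum):
    PERSONNEL = "personnel"
    FACILITIES = "facilities"
    TRAVEL = "travel"
    TRANSPORTATION = "transportation"
    LODGING = "lodging"
    PER_DIEM = "per_diem"
    EQUIPMENT = "equipment"
    SUPPLIES = "supplies"
    OTHER = "other"


class Location(str, enum.Enum):
    IN_COUNTRY = "in_country"
    INTERNATIONAL = "international"


class Variability(str, enum.Enum):
    """How a cost item scales when the survey is projected to a new size.

    Used only by the national-scale scenario: ``fixed`` items are carried at
    base cost, the others are scaled by the ratio of effective interviews,
    enumerator FTEs, hub count or total field months, respectively.
    """

    FIXED = "fixed"
    PER_RESPONDENT = "per_respondent"
    PER_ENUMERATOR = "per_enumerator"
    PER_HUB = "per_hub"
    PER_MONTH = "per_month"


class Site(str, enum.Enum):
    URBAN = "urban"
    RURAL = "rural"


class MacroLookupError(LookupError):
    """A deflator or exchange-rate entry is missing for (currency, year)."""


class WageLookupError(LookupError):
    """No wage is configured for a (role, location) pair."""


@dataclass(frozen=True)
class Money:
    """An amount of money in a given currency paid in a given year."""

    amount: float
    currency: str = "USD"
    year: int = 2019

    def __post_init__(self) -> None:
        if not self.currency:
            raise ValueError("currency must be a non-empty ISO-4217 code")


@dataclass
class CostItem:
    """One priced ingredient of one subactivity — the atom of the ledger.

    ``money.amount`` is the unit cost; the item's raw cost is
    ``money.amount * quantity``.  Personnel items are instead valued from
    ``person_minutes`` and the applicable daily wage, so for them ``money``
    records the expenditure only informally (it may be zero).  Capital items
    (``is_capital``) are annualised over ``useful_life`` years before entering
    any total.

    ``variability`` classifies the item as fixed or variable for the
    national-scale projection; it may be left ``None`` for analyses that never
    re-scale the ledger.
    """

    id: str
    country: Country
    modality: Modality
    activity: Activity
    subactivity: str
    centre: CostCentre
    money: Money
    payer: str = "project"
    quantity: float = 1.0
    is_capital: bool = False
    useful_life: Optional[float] = None
    role: Optional[str] = None
    location: Optional[Location] = None
    person_minutes: Optional[float] = None
    variability: Optional[Variability] = None

    def copy(self, **changes) -> "CostItem":
        return replace(self, **changes)


@dataclass(frozen=True)
class RoleWage:
    """Daily wage for one personnel role at one location."""

    role: str
    location: Location
    wage: Money  # per person-day

    def __post_init__(self) -> None:
        if self.wage.amount <= 0:
            raise ValueError(f"wage for {self.role}/{self.location.value} must be > 0")


class WageTable:
    """Lookup of daily wages keyed by (role, location)."""

    def __init__(self, wages: Iterable[RoleWage]):
        self._wages: dict[tuple[str, Location], RoleWage] = {}
        for w in wages:
            key = (w.role, w.location)
            if key in self._wages:
                raise ValueError(f"duplicate wage entry for {key}")
            self._wages[key] = w

    def get(self, role: str, location: Location) -> RoleWage:
        try:
            return self._wages[(role, Location(location))]
        except KeyError:
            raise WageLookupError(
                f"no wage configured for role={role!r} location={Location(location).value!r}"
            ) from None

    def __contains__(self, key: tuple[str, Location]) -> bool:
        return (key[0], Location(key[1])) in self._wages

    def __iter__(self):
        return iter(self._wages.values())

    def __len__(self) -> int:
        return len(self._wages)


class MacroTable:
    """GDP-deflator and exchange-rate series keyed by (currency, year).

    ``fx`` entries give units of local currency per US dollar; the USD series
    is implicitly 1.  Deflators are index values on an arbitrary base (only
    ratios are used).
    """

    def __init__(
        self,
        deflator: Mapping[tuple[str, int], float],
        fx: Mapping[tuple[str, int], float],
    ):
        for (cur, year), v in deflator.items():
            if v <= 0:
                raise ValueError(f"deflator for ({cur}, {year}) must be > 0")
        for (cur, year), v in fx.items():
            if v <= 0:
                raise ValueError(f"fx for ({cur}, {year}) must be > 0")
        self._deflator = dict(deflator)
        self._fx = dict(fx)

    @property
    def currencies(self) -> set[str]:
        return {c for c, _ in self._deflator} | {c for c, _ in self._fx} | {"USD"}

    def years(self, currency: str) -> set[int]:
        return {y for c, y in self._deflator if c == currency}

    def deflator(self, currency: str, year: int) -> float:
        try:
            return self._deflator[(currency, int(year))]
        except KeyError:
            raise MacroLookupError(
                f"no GDP deflator for currency={currency!r} year={year}"
            ) from None

    def fx_per_usd(self, currency: str, year: int) -> float:
        if currency == "USD":
            return 1.0
        try:
            return self._fx[(currency, int(year))]
        except KeyError:
            raise MacroLookupError(
                f"no exchange rate for currency={currency!r} year={year}"
            ) from None

    def items(self):
        """Yield (currency, year, deflator, fx_per_usd) rows for serialisation."""
        keys = sorted(set(self._deflator) | set(self._fx))
        for cur, year in keys:
            yield (
                cur,
                year,
                self._deflator.get((cur, year)),
                self._fx.get((cur, year), 1.0 if cur == "USD" else None),
            )


@dataclass
class InterviewTiming:
    """Per-pass interview minutes for one respondent.

    The multiple-pass 24HR protocol records a quick list (pass 1), food
    details (pass 2), quantities (pass 3), an optional non-standard recipe
    pass, and a final review (pass 4).  The ``menu`` segment is time spent in
    the mobile app's home screen between passes and is defined only for the
    electronic (CAPI) modality.
    """

    respondent_id: str
    country: Country
    modality: Modality
    site: Site
    pass1: float = 0.0
    pass2: float = 0.0
    pass3: float = 0.0
    nonstandard_recipe: float = 0.0
    pass4: float = 0.0
    menu: Optional[float] = None
    total_minutes: Optional[float] = None

    SEGMENTS = ("pass1", "pass2", "pass3", "nonstandard_recipe", "pass4", "menu")

    def __post_init__(self) -> None:
        if self.modality == Modality.SHARED:
            raise ValueError("interview timings belong to a single modality")
        if self.modality == Modality.PAPI and self.menu is not None:
            raise ValueError("the menu segment is not defined for PAPI interviews")
        for seg in self.SEGMENTS:
            v = getattr(self, seg)
            if v is not None and v < 0:
                raise ValueError(f"segment {seg} must be non-negative")
        if self.total_minutes is None:
            self.total_minutes = self.segment_sum()

    def segment_sum(self) -> float:
        return sum(getattr(self, s) or 0.0 for s in self.SEGMENTS)


@dataclass(frozen=True)
class TimeLogEntry:
    """One staff time-log row: minutes spent on one activity."""

    activity: Activity
    minutes: float
    role: Optional[str] = None
    country: Optional[Country] = None
    modality: Optional[Modality] = None


@dataclass(frozen=True)
class Violation:
    """One well-formedness problem found in a ledger."""

    item_id: str
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.item_id}] {self.field}: {self.message}"


def validate_ledger(
    items: Sequence[CostItem],
    macro: Optional[MacroTable] = None,
    allowed_useful_lives: Sequence[float] = DEFAULT_USEFUL_LIVES,
) -> list[Violation]:
    """Check ledger well-formedness; return a (possibly empty) report.

    This is a reporting operation: it never raises on a malformed ledger, the
    caller decides whether to abort.  Checks, per item:

    * amounts and quantities are non-negative;
    * capital items carry a useful life from ``allowed_useful_lives``;
    * personnel items carry a role, a location and person-minutes;
    * when ``macro`` is given, the currency/year pair can be valued.
    """
    report: list[Violation] = []
    seen: set[str] = set()
    for item in items:
        if item.id in seen:
            report.append(Violation(item.id, "id", "duplicate item id"))
        seen.add(item.id)
        if item.money.amount < 0:
            report.append(Violation(item.id, "amount", "cost amounts must be >= 0"))
        if item.quantity < 0:
            report.append(Violation(item.id, "quantity", "quantity must be >= 0"))
        if item.is_capital:
            if item.useful_life is None:
                report.append(
                    Violation(item.id, "useful_life", "capital item without a useful life")
                )
            elif allowed_useful_lives and item.useful_life not in allowed_useful_lives:
                report.append(
                    Violation(
                        item.id,
                        "useful_life",
                        f"useful life {item.useful_life} not in {tuple(allowed_useful_lives)}",
                    )
                )
        if item.centre == CostCentre.PERSONNEL:
            if item.role is None:
                report.append(Violation(item.id, "role", "personnel item without a role"))
            elif item.role not in PERSONNEL_ROLES:
                report.append(
                    Violation(item.id, "role", f"unknown personnel role {item.role!r}")
                )
            if item.person_minutes is None:
                report.append(
                    Violation(
                        item.id, "person_minutes", "personnel item without person-minutes"
                    )
                )
            if item.location is None:
                report.append(
                    Violation(item.id, "location", "personnel item without a location")
                )
        if macro is not None and item.centre != CostCentre.PERSONNEL:
            cur, year = item.money.currency, item.money.year
            try:
                macro.deflator(cur, year)
            except MacroLookupError as exc:
                report.append(Violation(item.id, "currency/year", str(exc)))
    return report
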