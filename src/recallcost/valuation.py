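"""Valuation rules: deflation, currency conversion, annualisation, wages.

Every cost enters the analysis in base-year US dollars (2019 by default).
The normalisation rule is contractual and order-sensitive: amounts paid in a
local currency are first inflated/deflated *in the local currency* to the
base year using the local GDP implicit price deflator, and only then
converted to US dollars at the *base-year* average exchange rate.  Amounts
already in US dollars are deflated with the US series and never touched by
exchange rates.

Capital purchases with a useful life beyond one survey are converted to an
equivalent annual cost with the standard annuity factor

    A(r, n) = (1 - (1 + r)^-n) / r        (A = n when r = 0)

at a 3 % discount rate, and the survey is charged ``E = K / A`` prorated by
the months attributed to the survey.

Staff time is valued at the daily wage actually received by the role
(field-based and in-country staff) or at average salaries for comparable
positions (internationally based staff); respondent time is valued at the
region-specific minimum monthly wage spread over the monthly working hours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .ledger import (
    DAY_MINUTES,
    CostCentre,
    CostItem,
    MacroTable,
    Money,
    WageTable,
)

__all__ = [
    "ValuationParams",
    "deflate",
    "to_usd",
    "normalize",
    "annuity_factor",
    "annualize_capital",
    "value_personnel",
    "respondent_cost",
    "value_item",
    "value_ledger",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (not banker's rounding).

    Report-level figures use this convention: -64.5 -> -65, 64.5 -> 65.
    """
    scale = 10.0**ndigits
    scaled = x * scale
    import math

    rounded = math.floor(scaled + 0.5) if scaled >= 0 else math.ceil(scaled - 0.5)
    return rounded / scale


@dataclass(frozen=True)
class ValuationParams:
    """Parameters of the valuation rules.

    discount_rate
        Annual discount rate for the annuity factor (default 3 %).
    base_year
        Calendar year all costs are expressed in (default 2019).
    survey_duration_months
        Months of the annualised equipment cost charged to the survey.
        The default of 12 charges one full annualised year.
    day_minutes
        Minutes per person-day used to convert person-minutes to days.
    hours_per_month
        Working hours per month used to turn a monthly minimum wage into a
        per-minute rate for respondent time (default 168 = 21 days x 8 h).
    """

    discount_rate: float = 0.03
    base_year: int = 2019
    survey_duration_months: float = 12.0
    day_minutes: float = DAY_MINUTES
    hours_per_month: float = 168.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError("discount_rate must lie in [0, 1)")
        if not 0.0 < self.survey_duration_months <= 12.0:
            raise ValueError("survey_duration_months must lie in (0, 12]")
        if self.day_minutes <= 0 or self.hours_per_month <= 0:
            raise ValueError("time conventions must be positive")


def deflate(money: Money, base_year: int, macro: MacroTable) -> Money:
    """Re-express ``money`` in base-year prices of the *same* currency."""
    if money.year == base_year:
        return Money(money.amount, money.currency, base_year)
    ratio = macro.deflator(money.currency, base_year) / macro.deflator(
        money.currency, money.year
    )
    return Money(money.amount * ratio, money.currency, base_year)


def to_usd(money: Money, macro: MacroTable) -> Money:
    """Convert to US dollars at the exchange rate of ``money.year``."""
    if money.currency == "USD":
        return money
    rate = macro.fx_per_usd(money.currency, money.year)
    return Money(money.amount / rate, "USD", money.year)


def normalize(money: Money, base_year: int, macro: MacroTable) -> Money:
    """Express ``money`` in base-year US dollars.

    Local currencies are deflated to the base year in local currency first,
    then converted at the base-year exchange rate.  US-dollar amounts are
    deflated with the US series only.  Idempotent on already-normalised money.
    """
    deflated = deflate(money, base_year, macro)
    return to_usd(deflated, macro)


def annuity_factor(discount_rate: float, useful_life: float) -> float:
    """Present-value annuity factor ``A(r, n)``; equals ``n`` when r = 0."""
    if useful_life <= 0:
        raise ValueError("useful life must be positive")
    if discount_rate == 0.0:
        return float(useful_life)
    return (1.0 - (1.0 + discount_rate) ** (-useful_life)) / discount_rate


def annualize_capital(
    purchase: float, useful_life: float, params: ValuationParams = ValuationParams()
) -> float:
    """Survey-attributed equivalent annual cost of a capital purchase.

    ``purchase`` must already be in base-year USD.  The equivalent annual
    cost ``E = K / A(r, n)`` is prorated by ``survey_duration_months / 12``.
    """
    if useful_life is None or useful_life < 1:
        raise ValueError("capital items require a useful life of at least 1 year")
    annual = purchase / annuity_factor(params.discount_rate, useful_life)
    return annual * params.survey_duration_months / 12.0


def value_personnel(
    item: CostItem,
    wages: WageTable,
    macro: MacroTable,
    params: ValuationParams = ValuationParams(),
) -> float:
    """Value a personnel item as person-time at the role's daily wage.

    ``person_minutes / day_minutes * wage_per_day``, with the wage normalised
    to base-year USD.
    """
    if item.centre != CostCentre.PERSONNEL:
        raise ValueError(f"item {item.id} is not a personnel item")
    if item.role is None or item.person_minutes is None or item.location is None:
        raise ValueError(
            f"personnel item {item.id} lacks role, location or person-minutes"
        )
    wage = wages.get(item.role, item.location).wage
    wage_usd = normalize(wage, params.base_year, macro).amount
    return item.person_minutes / params.day_minutes * wage_usd * item.quantity


def respondent_cost(
    interview_minutes: float,
    consent_minutes: float = 15.0,
    monthly_wage: Money = Money(151.0, "USD", 2019),
    hours_per_month: float = 168.0,
    macro: Optional[MacroTable] = None,
    base_year: int = 2019,
) -> float:
    """Opportunity cost of one respondent's participation, in USD (cents).

    Interview time plus recruitment/consent time (about 15 min) valued at the
    region-specific minimum monthly wage, spread over ``hours_per_month``
    working hours.  Rounded to the cent for reporting.
    """
    if interview_minutes < 0 or consent_minutes < 0:
        raise ValueError("minutes must be non-negative")
    wage = monthly_wage
    if macro is not None:
        wage = normalize(wage, base_year, macro)
    elif wage.currency != "USD":
        raise ValueError("a macro table is required to value a non-USD wage")
    per_minute = wage.amount / (hours_per_month * 60.0)
    return round_half_away((interview_minutes + consent_minutes) * per_minute, 2)


def value_item(
    item: CostItem,
    wages: Optional[WageTable],
    macro: MacroTable,
    params: ValuationParams = ValuationParams(),
) -> float:
    """Base-year USD value of one ledger item.

    Personnel items: person-time at the daily wage.  Capital items: the
    normalised purchase cost of ``quantity`` units, annualised.  All other
    items: normalised ``amount * quantity``.
    """
    if item.centre == CostCentre.PERSONNEL:
        if wages is None:
            raise ValueError("a wage table is required to value personnel items")
        return value_personnel(item, wages, macro, params)
    unit = normalize(item.money, params.base_year, macro).amount
    raw = unit * item.quantity
    if item.is_capital:
        return annualize_capital(raw, item.useful_life, params)
    return raw


def value_ledger(
    items: Sequence[CostItem],
    wages: Optional[WageTable],
    macro: MacroTable,
    params: ValuationParams = ValuationParams(),
) -> pd.DataFrame:
    """Value every item; return a tidy frame with one row per item.

    Columns mirror the item attributes plus ``value_usd`` (base-year USD).
    This frame is the input to :mod:`recallcost.aggregate` and to the
    national-scale projection.
    """
    rows = []
    for item in items:
        rows.append(
            {
                "id": item.id,
                "country": item.country.value,
                "modality": item.modality.value,
                "activity": item.activity.value,
                "subactivity": item.subactivity,
                "centre": item.centre.value,
                "payer": item.payer,
                "role": item.role,
                "location": item.location.value if item.location else None,
                "is_capital": item.is_capital,
                "variability": item.variability.value if item.variability else None,
                "value_usd": value_item(item, wages, macro, params),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "country",
            "modality",
            "activity",
            "subactivity",
            "centre",
            "payer",
            "role",
            "location",
            "is_capital",
            "variability",
            "value_usd",
        ],
    )
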