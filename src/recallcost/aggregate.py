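"""Roll-ups of the valued ledger: totals, cost efficiency, disaggregations.

A :class:`LedgerSummary` is the reporting surface for one country x modality
x perspective slice: the total economic cost, cost per respondent, and the
breakdowns by activity, by cost centre, and into time (human-capital) versus
non-time costs.  Arm differences are reported as CAPI minus PAPI, so a
negative difference means the electronic modality was cheaper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import pandas as pd

from .ledger import Activity, CostCentre, Country, Modality
from .valuation import round_half_away

__all__ = [
    "LedgerSummary",
    "ArmDifference",
    "summarize",
    "cost_per_respondent",
    "arm_difference",
    "share_report",
    "summary_table",
    "time_nontime_table",
]

Perspective = Literal["societal", "respondent"]
SharedAllocation = Literal["duplicate", "split"]


@dataclass
class LedgerSummary:
    """Totals and disaggregations for one modality/country/perspective."""

    country: Country
    modality: Modality
    perspective: Perspective
    total: float
    n_respondents: int
    by_activity: dict[str, float]
    by_centre: dict[str, float]
    time_cost: float
    nontime_cost: float

    @property
    def per_respondent(self) -> float:
        """Unrounded cost per respondent; round for reporting."""
        return self.total / self.n_respondents

    @property
    def per_respondent_reported(self) -> float:
        return round_half_away(self.per_respondent)


@dataclass
class ArmDifference:
    """Element-wise CAPI minus PAPI differences for one country."""

    country: Country
    perspective: Perspective
    total: float
    by_activity: dict[str, float]
    per_respondent: float  # unrounded

    @property
    def per_respondent_reported(self) -> float:
        return round_half_away(self.per_respondent)


def _arm_weights(frame: pd.DataFrame, modality: Modality, shared: SharedAllocation) -> pd.Series:
    """Weight of every valued row in the given arm's total.

    Shared items (dietary reference data used by both arms) are counted at
    full cost in each arm by default, or at half cost under ``split``.
    """
    w = pd.Series(0.0, index=frame.index)
    w[frame["modality"] == modality.value] = 1.0
    w[frame["modality"] == Modality.SHARED.value] = 1.0 if shared == "duplicate" else 0.5
    return w


def summarize(
    valued: pd.DataFrame,
    country: Country,
    modality: Modality,
    n_respondents: int,
    perspective: Perspective = "societal",
    shared_allocation: SharedAllocation = "duplicate",
    include_respondent_costs: bool = True,
) -> LedgerSummary:
    """Summarise a valued ledger for one arm.

    The societal perspective counts all costs regardless of payer (including
    respondents' opportunity cost unless ``include_respondent_costs`` is
    disabled); the respondent perspective keeps only items whose payer is
    ``"respondent"``.
    """
    if n_respondents <= 0:
        raise ValueError("n_respondents must be positive")
    country = Country(country)
    modality = Modality(modality)
    if modality == Modality.SHARED:
        raise ValueError("summaries are per data-collection arm")

    df = valued[valued["country"] == country.value]
    if perspective == "respondent":
        df = df[df["payer"] == "respondent"]
    elif not include_respondent_costs:
        df = df[df["payer"] != "respondent"]

    w = _arm_weights(df, modality, shared_allocation)
    value = df["value_usd"] * w
    if float(value.abs().sum()) == 0.0 and len(df[w > 0]) == 0:
        warnings.warn(
            f"empty ledger slice for {country.value}/{modality.value}; zero totals",
            stacklevel=2,
        )

    by_activity = {a.value: 0.0 for a in Activity}
    for act, v in value.groupby(df["activity"]).sum().items():
        by_activity[act] = float(v)
    by_centre = {c.value: 0.0 for c in CostCentre}
    for cen, v in value.groupby(df["centre"]).sum().items():
        by_centre[cen] = float(v)
    time_cost = float(value[df["centre"] == CostCentre.PERSONNEL.value].sum())
    total = float(value.sum())
    return LedgerSummary(
        country=country,
        modality=modality,
        perspective=perspective,
        total=total,
        n_respondents=int(n_respondents),
        by_activity=by_activity,
        by_centre=by_centre,
        time_cost=time_cost,
        nontime_cost=total - time_cost,
    )


def cost_per_respondent(total: float, n: int) -> float:
    """Cost efficiency: total / n, rounded to the nearest dollar."""
    if n <= 0:
        raise ValueError("n must be positive")
    return round_half_away(total / n)


def arm_difference(capi: LedgerSummary, papi: LedgerSummary) -> ArmDifference:
    """CAPI minus PAPI differences; negative means CAPI was cheaper.

    The per-respondent difference is taken between *unrounded* per-respondent
    values and only then rounded for reporting (differencing the rounded
    per-respondent figures can be off by a dollar).
    """
    if capi.country != papi.country:
        raise ValueError("summaries must share a country")
    if capi.perspective != papi.perspective:
        raise ValueError("summaries must share a perspective")
    by_activity = {
        a: capi.by_activity.get(a, 0.0) - papi.by_activity.get(a, 0.0)
        for a in capi.by_activity
    }
    return ArmDifference(
        country=capi.country,
        perspective=capi.perspective,
        total=capi.total - papi.total,
        by_activity=by_activity,
        per_respondent=capi.per_respondent - papi.per_respondent,
    )


def share_report(summary: LedgerSummary) -> dict[str, dict[str, float]]:
    """Activity and cost-centre shares (fractions of the total)."""
    if summary.total <= 0:
        raise ValueError("shares are undefined for a non-positive total")
    return {
        "by_activity": {k: v / summary.total for k, v in summary.by_activity.items()},
        "by_centre": {k: v / summary.total for k, v in summary.by_centre.items()},
    }


_ACTIVITY_LABELS = {
    "dietary_reference_data_prep": "Preparation of dietary reference data",
    "survey_preparation": "Survey preparation",
    "training": "Training",
    "survey_execution": "Survey execution",
    "data_entry": "Data entry",
    "data_cleaning_processing": "Data cleaning and processing",
    "administration": "Administration",
}


def summary_table(capi: LedgerSummary, papi: LedgerSummary) -> pd.DataFrame:
    """Activity rows x {CAPI, PAPI, difference} columns, report-rounded.

    The layout of the published cost-efficiency tables: one row per activity,
    a total row, and a cost-per-respondent row.
    """
    diff = arm_difference(capi, papi)
    rows = []
    for key, label in _ACTIVITY_LABELS.items():
        rows.append(
            {
                "activity": label,
                "inddex24_usd": round_half_away(capi.by_activity.get(key, 0.0)),
                "papi_usd": round_half_away(papi.by_activity.get(key, 0.0)),
                "difference_usd": round_half_away(diff.by_activity.get(key, 0.0)),
            }
        )
    rows.append(
        {
            "activity": "Total",
            "inddex24_usd": round_half_away(capi.total),
            "papi_usd": round_half_away(papi.total),
            "difference_usd": round_half_away(diff.total),
        }
    )
    rows.append(
        {
            "activity": "Cost per respondent",
            "inddex24_usd": capi.per_respondent_reported,
            "papi_usd": papi.per_respondent_reported,
            "difference_usd": diff.per_respondent_reported,
        }
    )
    return pd.DataFrame(rows, columns=["activity", "inddex24_usd", "papi_usd", "difference_usd"])


def time_nontime_table(*summaries: LedgerSummary) -> pd.DataFrame:
    """Tidy time (human capital) vs. non-time cost data by activity.

    One row per (country, modality, activity, component).  This is the data
    behind the stacked time/non-time cost figures.  The activity-level split
    requires the per-item frame, so summaries here only expose arm-level
    splits; see :func:`summarize` callers for item-level exports.
    """
    rows = []
    for s in summaries:
        for comp, v in (("time", s.time_cost), ("nontime", s.nontime_cost)):
            rows.append(
                {
                    "country": s.country.value,
                    "modality": s.modality.value,
                    "component": comp,
                    "value_usd": v,
                }
            )
    return pd.DataFrame(rows)


def time_nontime_by_activity(
    valued: pd.DataFrame,
    country: Country,
    modality: Modality,
    shared_allocation: SharedAllocation = "duplicate",
) -> pd.DataFrame:
    """Item-level time/non-time split by activity for one arm (tidy)."""
    df = valued[valued["country"] == Country(country).value]
    w = _arm_weights(df, Modality(modality), shared_allocation)
    df = df.assign(weighted=df["value_usd"] * w)
    df = df[w > 0]
    df = df.assign(
        component=(df["centre"] == CostCentre.PERSONNEL.value).map(
            {True: "time", False: "nontime"}
        )
    )
    out = (
        df.groupby(["activity", "component"], as_index=False)["weighted"]
        .sum()
        .rename(columns={"weighted": "value_usd"})
    )
    out.insert(0, "modality", Modality(modality).value)
    out.insert(0, "country", Country(country).value)
    return out
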