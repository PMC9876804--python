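"""Counterfactual cost models: reference-data borrowing, localisation, scale.

Three scenario engines re-price the validation-study ledger under changed
assumptions:

1. **Reference-data borrowing** — a fraction of the dietary reference data
   (food lists, standard recipes, conversion factors, portion-size methods)
   is assumed to already exist in a shared repository, so the CAPI arm's
   reference-data preparation cost shrinks proportionally.  The PAPI arm is
   compared unchanged.
2. **Personnel localisation** — every internationally based position is
   re-priced at the wage of an equivalent in-country position; person-time
   is unchanged.
3. **National scale** — the survey is projected to a national sample with a
   hub-based field organisation.  A staffing model converts the sample size
   into enumerator/supervisor/data-entry full-time equivalents, and each
   ledger item is scaled according to its fixed/variable classification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import pandas as pd

from .aggregate import LedgerSummary, summarize
from .ledger import (
    Activity,
    CostCentre,
    CostItem,
    Country,
    Location,
    Modality,
    Variability,
    WageTable,
)
from .valuation import round_half_away

__all__ = [
    "NationalConfig",
    "ScenarioConfig",
    "Staffing",
    "apply_fmdb_borrow",
    "apply_localization",
    "staffing_requirements",
    "project_national",
    "LocalizationError",
]

#: Subactivity label whose items are dropped from national projections when
#: capacity building is excluded (a national team is assumed not to need
#: external training or support).
CAPACITY_BUILDING = "capacity_building"


class LocalizationError(ValueError):
    """An international role in the ledger has no in-country substitution."""


@dataclass(frozen=True)
class NationalConfig:
    """Assumptions of the national-scale projection.

    The national survey samples ``n_respondents`` women of reproductive age,
    with repeat recalls administered to a ``replicate_fraction`` subsample on
    non-consecutive days (effective interviews = n x (1 + fraction)).  Data
    collection runs from ``hubs`` subnational hubs, simultaneously, for
    ``months_per_hub`` months each.

    ``base_*`` fields describe the reference study the ledger comes from, so
    that variable costs can be scaled by ratios (effective interviews,
    enumerator FTEs, hubs, total field months).
    """

    n_respondents: int
    replicate_fraction: float = 0.20
    hubs: int = 1
    months_per_hub: float = 1.0
    interviews_per_enumerator_day: float = 4.0
    entries_per_clerk_day: float = 8.0
    supervisor_ratio: float = 6.0  # enumerators per field supervisor
    clerk_ratio: float = 10.0  # data entry clerks per data supervisor
    working_days_per_month: float = 22.0
    capacity_building_included: bool = False
    round_staffing: bool = True
    # reference (base-study) conditions
    base_n_respondents: int = 147
    base_replicate_fraction: float = 0.0
    base_enumerators: float = 4.0
    base_clerks: float = 1.0
    base_data_supervisors: float = 1.0
    base_hubs: int = 1
    base_field_months: float = 1.0

    def __post_init__(self) -> None:
        if self.n_respondents < 1 or self.base_n_respondents < 1:
            raise ValueError("sample sizes must be >= 1")
        if not 0.0 <= self.replicate_fraction <= 1.0:
            raise ValueError("replicate_fraction must lie in [0, 1]")
        if self.supervisor_ratio < 1 or self.clerk_ratio < 1:
            raise ValueError("staffing ratios must be >= 1")
        if self.hubs < 1 or self.base_hubs < 1:
            raise ValueError("hub counts must be >= 1")

    @property
    def effective_interviews(self) -> float:
        return self.n_respondents * (1.0 + self.replicate_fraction)

    @property
    def base_effective_interviews(self) -> float:
        return self.base_n_respondents * (1.0 + self.base_replicate_fraction)

    @property
    def total_field_months(self) -> float:
        return self.hubs * self.months_per_hub


@dataclass(frozen=True)
class ScenarioConfig:
    """One counterfactual: which engine to run and its parameters."""

    kind: str  # {"fmdb_borrow", "localize", "national"}
    borrow_fraction: Optional[float] = None
    role_substitutions: Optional[Mapping[str, str]] = None
    national: Optional[NationalConfig] = None

    def __post_init__(self) -> None:
        kinds = {"fmdb_borrow", "localize", "national"}
        if self.kind not in kinds:
            raise ValueError(f"scenario kind must be one of {sorted(kinds)}")
        if self.kind == "fmdb_borrow" and self.borrow_fraction is None:
            raise ValueError("fmdb_borrow requires a borrow_fraction")
        if self.kind == "localize" and self.role_substitutions is None:
            raise ValueError("localize requires role_substitutions")
        if self.kind == "national" and self.national is None:
            raise ValueError("national requires a NationalConfig")


@dataclass(frozen=True)
class Staffing:
    """Full-time-equivalent staffing for one arm of a national survey."""

    enumerators: float
    field_supervisors: float
    data_entry_clerks: float
    data_supervisors: float


def apply_fmdb_borrow(
    items: Sequence[CostItem], borrow_fraction: float
) -> list[CostItem]:
    """Scale the CAPI arm's reference-data preparation by (1 - fraction).

    Items with activity ``dietary_reference_data_prep`` contributing to the
    electronic arm are scaled; the PAPI arm is left unchanged, so shared
    reference-data items are split into a full-cost PAPI copy and a scaled
    CAPI copy.  Personnel items are scaled through their person-minutes
    (borrowing reduces preparation time), all others through their amount.
    """
    if not 0.0 <= borrow_fraction <= 1.0:
        raise ValueError("borrow_fraction must lie in [0, 1]")
    keep = 1.0 - borrow_fraction

    def scaled(item: CostItem, modality: Modality, suffix: str = "") -> CostItem:
        changes: dict = {"modality": modality}
        if suffix:
            changes["id"] = item.id + suffix
        if item.person_minutes is not None:
            changes["person_minutes"] = item.person_minutes * keep
        changes["money"] = replace(item.money, amount=item.money.amount * keep)
        return item.copy(**changes)

    out: list[CostItem] = []
    for item in items:
        if item.activity != Activity.DIETARY_REFERENCE_DATA_PREP:
            out.append(item)
        elif item.modality == Modality.INDDEX24:
            out.append(scaled(item, Modality.INDDEX24))
        elif item.modality == Modality.SHARED:
            out.append(item.copy(id=item.id + "@papi", modality=Modality.PAPI))
            out.append(scaled(item, Modality.INDDEX24, suffix="@inddex24"))
        else:
            out.append(item)
    return out


def apply_localization(
    items: Sequence[CostItem],
    role_substitutions: Mapping[str, str],
    wages: WageTable,
) -> list[CostItem]:
    """Replace internationally based personnel with in-country equivalents.

    Each international personnel item is re-assigned the substituted role at
    the in-country location; person-minutes are unchanged, so re-valuation
    prices the same time at the in-country wage.  Non-personnel items are
    untouched.  Raises :class:`LocalizationError` naming any international
    role without a substitution or without an in-country wage.
    """
    missing = sorted(
        {
            item.role
            for item in items
            if item.centre == CostCentre.PERSONNEL
            and item.location == Location.INTERNATIONAL
            and item.role not in role_substitutions
        }
    )
    if missing:
        raise LocalizationError(
            f"no in-country substitution for international role(s): {missing}"
        )
    out: list[CostItem] = []
    for item in items:
        if (
            item.centre == CostCentre.PERSONNEL
            and item.location == Location.INTERNATIONAL
        ):
            new_role = role_substitutions[item.role]
            if (new_role, Location.IN_COUNTRY) not in wages:
                raise LocalizationError(
                    f"no in-country wage for substituted role {new_role!r}"
                )
            out.append(item.copy(role=new_role, location=Location.IN_COUNTRY))
        else:
            out.append(item)
    return out


def _round_staff(x: float, do_round: bool) -> float:
    # Staffing figures are reported rounded to the nearest whole number
    # (not the more common budgeting ceiling).
    return round_half_away(x) if do_round else x


def staffing_requirements(cfg: NationalConfig, modality: Modality) -> Staffing:
    """FTE staffing implied by the national sampling assumptions.

    Enumerator FTEs cover the effective interviews at the configured
    interviews/day over the field window; field supervisors follow a 1:6
    supervisor:enumerator ratio.  Data entry clerks are required only for the
    paper arm (electronic capture needs none) and data supervisors follow a
    1:10 clerk:data-supervisor ratio; the electronic arm retains one data
    supervisor per hub for ongoing electronic data monitoring.
    """
    modality = Modality(modality)
    if cfg.interviews_per_enumerator_day <= 0:
        raise ValueError("interviews_per_enumerator_day must be positive")
    if cfg.entries_per_clerk_day <= 0:
        raise ValueError("entries_per_clerk_day must be positive")
    window_days = cfg.working_days_per_month * cfg.months_per_hub
    enumerators = _round_staff(
        cfg.effective_interviews / (cfg.interviews_per_enumerator_day * window_days),
        cfg.round_staffing,
    )
    supervisors = _round_staff(enumerators / cfg.supervisor_ratio, cfg.round_staffing)
    if modality == Modality.PAPI:
        clerks = _round_staff(
            cfg.effective_interviews / (cfg.entries_per_clerk_day * window_days),
            cfg.round_staffing,
        )
        data_sups = max(1.0, _round_staff(clerks / cfg.clerk_ratio, cfg.round_staffing))
    else:
        clerks = 0.0
        data_sups = float(cfg.hubs)
    return Staffing(
        enumerators=enumerators,
        field_supervisors=supervisors,
        data_entry_clerks=clerks,
        data_supervisors=data_sups,
    )


def _scaling_factors(cfg: NationalConfig, staffing: Staffing) -> dict[Variability, float]:
    return {
        Variability.FIXED: 1.0,
        Variability.PER_RESPONDENT: cfg.effective_interviews
        / cfg.base_effective_interviews,
        Variability.PER_ENUMERATOR: staffing.enumerators / cfg.base_enumerators,
        Variability.PER_HUB: cfg.hubs / cfg.base_hubs,
        Variability.PER_MONTH: cfg.total_field_months / cfg.base_field_months,
    }


def project_national(
    valued: pd.DataFrame,
    cfg: NationalConfig,
    country: Country,
    modality: Modality,
    shared_allocation: str = "duplicate",
) -> tuple[pd.DataFrame, LedgerSummary]:
    """Project a valued, localised ledger to national scale for one arm.

    Every item must carry a variability tag.  Fixed items are carried at base
    cost; variable items are scaled by the ratio of effective interviews,
    enumerator FTEs, hub count or total field months.  Data-entry personnel
    are re-derived from the staffing model instead: clerk items scale with
    the clerk-FTE ratio (zero for the electronic arm) and data-supervisor
    items with the data-supervisor ratio.  Capacity-building items (the
    ``capacity_building`` subactivity) are dropped unless included.

    Returns the scaled per-item frame and the arm summary at the national
    sample size.
    """
    country = Country(country)
    modality = Modality(modality)
    df = valued[valued["country"] == country.value].copy()
    df = df[df["modality"].isin([modality.value, Modality.SHARED.value])]

    untagged = df.loc[df["variability"].isna(), "id"].tolist()
    if untagged:
        raise ValueError(
            f"items without a variability tag cannot be projected: {untagged}"
        )

    staffing = staffing_requirements(cfg, modality)
    factors = _scaling_factors(cfg, staffing)

    def factor(row) -> float:
        if (
            not cfg.capacity_building_included
            and row["subactivity"] == CAPACITY_BUILDING
        ):
            return 0.0
        if (
            row["activity"] == Activity.DATA_ENTRY.value
            and row["centre"] == CostCentre.PERSONNEL.value
        ):
            if row["role"] == "data_entry_clerk":
                return staffing.data_entry_clerks / cfg.base_clerks
            if row["role"] == "data_supervisor":
                return staffing.data_supervisors / cfg.base_data_supervisors
        return factors[Variability(row["variability"])]

    df["scale_factor"] = df.apply(factor, axis=1)
    df["value_usd"] = df["value_usd"] * df["scale_factor"]
    summary = summarize(
        df,
        country,
        modality,
        n_respondents=cfg.n_respondents,
        shared_allocation=shared_allocation,  # type: ignore[arg-type]
    )
    return df, summary
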