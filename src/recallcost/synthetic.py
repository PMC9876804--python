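"""Seeded generators for cost ledgers, wage tables and interview timings.

Two kinds of synthetic data are produced:

* :func:`generate_ledger` draws a random but structurally realistic ledger
  from a :class:`GeneratorSpec` (activity shares, personnel share, equipment
  lists with useful lives, an international wage premium), for property
  tests and demonstrations.

* :func:`generate_paper_fixture` builds the deterministic, calibrated
  ledger pair used throughout the test-suite: item amounts are solved so
  that the valued totals of each arm equal the published study totals to
  the dollar, activity shares match the published percentages, and the
  localisation and national-scale scenarios reproduce the published scenario
  figures.  The item-level detail is synthetic — the original expenditure
  ledger is not public and no attempt is made to reconstruct it.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

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
from .scenarios import NationalConfig, apply_localization, project_national
from .valuation import ValuationParams, annuity_factor, value_ledger

__all__ = [
    "TimingParams",
    "EquipmentSpec",
    "GeneratorSpec",
    "PaperFixture",
    "default_wage_table",
    "default_macro_table",
    "generate_ledger",
    "generate_timings",
    "generate_paper_fixture",
    "RESPONDENT_PARAMS",
    "TIMING_PARAMS",
]

# ---------------------------------------------------------------------------
# Wages and macro series
# ---------------------------------------------------------------------------

#: Daily wages (USD, 2019) of in-country personnel.  Field-staff wages are
#: country-specific; the leadership roles (researcher, lead researcher,
#: statistician, administrator, technical advisor) are priced at exactly
#: 1/10 of the international rate, i.e. an international premium of 10.
_WAGES_IN_COUNTRY = {
    "vietnam": {
        "enumerator": 25.0,
        "field_supervisor": 35.0,
        "data_entry_clerk": 18.0,
        "data_supervisor": 30.0,
        "translator": 30.0,
        "coordinator": 40.0,
        "researcher": 30.0,
        "lead_researcher": 45.0,
        "statistician": 35.0,
        "administrator": 20.0,
        "chef": 20.0,
        "technical_advisor": 30.0,
    },
    "burkina_faso": {
        "enumerator": 20.0,
        "field_supervisor": 28.0,
        "data_entry_clerk": 15.0,
        "data_supervisor": 25.0,
        "translator": 25.0,
        "coordinator": 35.0,
        "researcher": 30.0,
        "lead_researcher": 45.0,
        "statistician": 35.0,
        "administrator": 20.0,
        "chef": 15.0,
        "technical_advisor": 30.0,
    },
}

#: Daily wages (USD, 2019) of internationally based personnel, from average
#: salaries of comparable research-institution positions.
_WAGES_INTERNATIONAL = {
    "researcher": 300.0,
    "lead_researcher": 450.0,
    "statistician": 350.0,
    "administrator": 200.0,
    "technical_advisor": 300.0,
}

#: Respondent-time valuation inputs: region-specific minimum monthly wage
#: (USD 2019; 3 151 000 VND ~ $151, 34 664 XOF ~ $59) and average interview
#: minutes per modality.  Recruitment/consent adds 15 minutes.
RESPONDENT_PARAMS = {
    "vietnam": {
        "monthly_wage_usd": 151.0,
        "interview_minutes": {"inddex24": 39.0, "papi": 44.0},
        "consent_minutes": 15.0,
    },
    "burkina_faso": {
        "monthly_wage_usd": 59.0,
        "interview_minutes": {"inddex24": 47.0, "papi": 50.0},
        "consent_minutes": 15.0,
    },
}


def default_wage_table(country: Country | str) -> WageTable:
    """Wage table with in-country and international rates for one country."""
    country = Country(country).value
    wages = [
        RoleWage(role, Location.IN_COUNTRY, Money(w, "USD", 2019))
        for role, w in _WAGES_IN_COUNTRY[country].items()
    ]
    wages += [
        RoleWage(role, Location.INTERNATIONAL, Money(w, "USD", 2019))
        for role, w in _WAGES_INTERNATIONAL.items()
    ]
    return WageTable(wages)


def default_macro_table() -> MacroTable:
    """Deflator and exchange-rate series covering 2018-2019.

    USD deflators follow an implicit GDP price index; local deflators are
    indexed to 100 in 2019.  Exchange rates are annual averages in local
    currency per USD.
    """
    deflator = {
        ("USD", 2018): 110.0,
        ("USD", 2019): 112.2,
        ("VND", 2018): 97.0,
        ("VND", 2019): 100.0,
        ("XOF", 2018): 98.5,
        ("XOF", 2019): 100.0,
    }
    fx = {
        ("VND", 2018): 22700.0,
        ("VND", 2019): 23000.0,
        ("XOF", 2018): 555.0,
        ("XOF", 2019): 575.0,
    }
    return MacroTable(deflator, fx)


_LOCAL_CURRENCY = {"vietnam": "VND", "burkina_faso": "XOF"}

#: International -> in-country substitution map used by the localisation
#: scenario: each leadership position maps to its in-country equivalent.
ROLE_SUBSTITUTIONS = {
    "researcher": "researcher",
    "lead_researcher": "lead_researcher",
    "statistician": "statistician",
    "administrator": "administrator",
    "technical_advisor": "technical_advisor",
}

# ---------------------------------------------------------------------------
# Interview-timing generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimingParams:
    """Distributional parameters of interview durations for one arm.

    Totals are drawn from a normal truncated at zero with the given mean/SD
    (a lognormal with matched moments is available via ``distribution``);
    segment minutes are a Dirichlet-weighted split of the total, with the
    menu-screen segment (electronic arm only) sized by ``menu_mean``.
    """

    total_mean: float
    total_sd: float
    menu_mean: Optional[float] = None
    segment_weights: tuple = (0.15, 0.32, 0.28, 0.05, 0.20)  # passes 1-3, non-std, 4
    concentration: float = 60.0
    distribution: str = "truncnorm"  # or "lognormal"


#: Calibration of the timing generator to the observed per-arm totals:
#: electronic 39 (SD 15) vs. paper 44 (SD 10) minutes in Viet Nam,
#: 47 (SD 18) vs. 50 (SD 20) in Burkina Faso; average menu-screen time of
#: 10 and 18 minutes per interview respectively.
TIMING_PARAMS = {
    ("vietnam", "inddex24"): TimingParams(39.0, 15.0, menu_mean=10.0),
    ("vietnam", "papi"): TimingParams(44.0, 10.0),
    ("burkina_faso", "inddex24"): TimingParams(47.0, 18.0, menu_mean=18.0),
    ("burkina_faso", "papi"): TimingParams(50.0, 20.0),
}


def generate_timings(
    params: TimingParams,
    n: int,
    country: Country | str,
    modality: Modality | str,
    seed: int | np.random.Generator = 0,
) -> list[InterviewTiming]:
    """Draw ``n`` per-respondent timing records for one arm.

    Deterministic given the seed.  Respondents alternate urban/rural sites.
    Totals are exact sums of their segments by construction.
    """
    if n < 2:
        raise ValueError("need at least 2 respondents per arm")
    country = Country(country)
    modality = Modality(modality)
    if modality == Modality.SHARED:
        raise ValueError("timings belong to a single modality")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mu, sd = params.total_mean, params.total_sd
    if params.distribution == "truncnorm":
        totals = stats.truncnorm.rvs(
            a=-mu / sd, b=np.inf, loc=mu, scale=sd, size=n, random_state=rng
        )
    elif params.distribution == "lognormal":
        sigma2 = math.log(1.0 + (sd / mu) ** 2)
        totals = rng.lognormal(math.log(mu) - sigma2 / 2.0, math.sqrt(sigma2), size=n)
    else:
        raise ValueError(f"unknown distribution {params.distribution!r}")

    weights = np.asarray(params.segment_weights, dtype=float)
    weights = weights / weights.sum()
    has_menu = modality == Modality.INDDEX24 and params.menu_mean is not None
    if has_menu:
        menu_w = params.menu_mean / params.total_mean
        weights = np.append(weights * (1.0 - menu_w), menu_w)
    alphas = weights * params.concentration
    shares = rng.dirichlet(alphas, size=n)

    records = []
    for i in range(n):
        segs = totals[i] * shares[i]
        records.append(
            InterviewTiming(
                respondent_id=f"{country.value[:2]}-{modality.value}-{i:04d}",
                country=country,
                modality=modality,
                site=Site.URBAN if i % 2 == 0 else Site.RURAL,
                pass1=float(segs[0]),
                pass2=float(segs[1]),
                pass3=float(segs[2]),
                nonstandard_recipe=float(segs[3]),
                pass4=float(segs[4]),
                menu=float(segs[5]) if has_menu else None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Generic random-ledger generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EquipmentSpec:
    """One equipment line: unit price (USD), useful life, base quantity."""

    name: str
    unit_price: float
    useful_life: float
    quantity: float = 1.0
    per_enumerator: bool = False


_DEFAULT_ACTIVITY_SHARES = {
    Activity.DIETARY_REFERENCE_DATA_PREP: 0.30,
    Activity.SURVEY_PREPARATION: 0.15,
    Activity.TRAINING: 0.08,
    Activity.SURVEY_EXECUTION: 0.25,
    Activity.DATA_ENTRY: 0.05,
    Activity.DATA_CLEANING_PROCESSING: 0.07,
    Activity.ADMINISTRATION: 0.10,
}

_DEFAULT_EQUIPMENT = (
    EquipmentSpec("tablet", 250.0, 3, quantity=10.0, per_enumerator=True),
    EquipmentSpec("food_scale", 40.0, 2, quantity=10.0, per_enumerator=True),
    EquipmentSpec("hard_drive", 80.0, 4, quantity=2.0),
    EquipmentSpec("storage_cabinet", 150.0, 10, quantity=1.0),
)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the random-ledger generator.

    ``activity_share_targets`` must sum to 1; realised shares stay within
    two percentage points of the targets.  ``backup_fraction`` inflates
    field-equipment quantities to cover loss and damage (several backup
    scales and tablets are normally purchased).
    """

    seed: int = 0
    country: Country = Country.VIETNAM
    n_respondents: int = 147
    total_cost: float = 100_000.0
    activity_share_targets: dict = field(
        default_factory=lambda: dict(_DEFAULT_ACTIVITY_SHARES)
    )
    personnel_share_target: float = 0.75
    equipment_list: tuple = _DEFAULT_EQUIPMENT
    international_premium: float = 10.0
    backup_fraction: float = 0.10
    timing_params: Optional[dict] = None

    def __post_init__(self) -> None:
        shares = {Activity(a): s for a, s in self.activity_share_targets.items()}
        if abs(sum(shares.values()) - 1.0) > 1e-9:
            raise ValueError("activity share targets must sum to 1")
        if any(s < 0 for s in shares.values()):
            raise ValueError("activity shares must be non-negative")
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        if not 0.0 <= self.personnel_share_target <= 1.0:
            raise ValueError("personnel_share_target must lie in [0, 1]")
        if not 0.0 <= self.backup_fraction <= 1.0:
            raise ValueError("backup_fraction must lie in [0, 1]")


_GENERIC_VARIABILITY = {
    Activity.DIETARY_REFERENCE_DATA_PREP: Variability.FIXED,
    Activity.SURVEY_PREPARATION: Variability.FIXED,
    Activity.TRAINING: Variability.PER_ENUMERATOR,
    Activity.SURVEY_EXECUTION: Variability.PER_RESPONDENT,
    Activity.DATA_ENTRY: Variability.PER_RESPONDENT,
    Activity.DATA_CLEANING_PROCESSING: Variability.PER_RESPONDENT,
    Activity.ADMINISTRATION: Variability.FIXED,
}


def generate_ledger(spec: GeneratorSpec) -> list[CostItem]:
    """Draw a random two-arm ledger with the spec's statistical structure.

    Reference-data preparation is generated once as ``shared`` items (it
    serves both arms); the remaining activities are drawn per arm with
    small multiplicative jitter, so realised activity shares stay within two
    percentage points of the targets.  Personnel items carry person-minutes
    consistent with the default wage table; a slice of non-personnel costs
    is expressed in local currency to exercise the normalisation rules.
    """
    rng = np.random.default_rng(spec.seed)
    country = Country(spec.country)
    wages = default_wage_table(country)
    macro = default_macro_table()
    local_cur = _LOCAL_CURRENCY[country.value]
    fx_2019 = macro.fx_per_usd(local_cur, 2019)
    shares = {Activity(a): s for a, s in spec.activity_share_targets.items()}
    params = ValuationParams()

    items: list[CostItem] = []

    def add_block(
        modality: Modality, activity: Activity, target: float, tag: str
    ) -> None:
        """Split one activity budget into personnel + non-personnel items."""
        pers_value = target * spec.personnel_share_target
        nonp_value = target - pers_value
        # personnel: split between a field role and a leadership role
        for frac, role in ((0.6, "enumerator"), (0.4, "researcher")):
            wage = wages.get(role, Location.IN_COUNTRY).wage.amount
            amount = pers_value * frac
            items.append(
                CostItem(
                    id=f"{tag}-{activity.value}-{role}",
                    country=country,
                    modality=modality,
                    activity=activity,
                    subactivity=f"{activity.value}_staff",
                    centre=CostCentre.PERSONNEL,
                    money=Money(0.0, "USD", 2019),
                    role=role,
                    location=Location.IN_COUNTRY,
                    person_minutes=amount / wage * params.day_minutes,
                    variability=_GENERIC_VARIABILITY[activity],
                )
            )
        # non-personnel: one USD item and one local-currency item
        for frac, cur in ((0.5, "USD"), (0.5, local_cur)):
            amount = nonp_value * frac
            if cur != "USD":
                amount *= fx_2019
            items.append(
                CostItem(
                    id=f"{tag}-{activity.value}-{cur.lower()}",
                    country=country,
                    modality=modality,
                    activity=activity,
                    subactivity=f"{activity.value}_inputs",
                    centre=CostCentre.SUPPLIES,
                    money=Money(amount, cur, 2019),
                    variability=_GENERIC_VARIABILITY[activity],
                )
            )

    ref_share = shares.get(Activity.DIETARY_REFERENCE_DATA_PREP, 0.0)
    add_block(
        Modality.SHARED,
        Activity.DIETARY_REFERENCE_DATA_PREP,
        ref_share * spec.total_cost,
        "shared",
    )

    for modality in (Modality.INDDEX24, Modality.PAPI):
        arm_activities = [a for a in shares if a != Activity.DIETARY_REFERENCE_DATA_PREP]
        raw = np.array([shares[a] for a in arm_activities], dtype=float)
        jitter = rng.normal(1.0, 0.005, size=raw.size)
        adj = raw * jitter
        adj *= raw.sum() / adj.sum()  # keep the arm total on target
        # equipment (electronic arm only for tablets) inside survey prep
        equip_value = 0.0
        if Activity.SURVEY_PREPARATION in arm_activities:
            for eq in spec.equipment_list:
                if eq.name == "tablet" and modality != Modality.INDDEX24:
                    continue
                qty = eq.quantity * (1.0 + spec.backup_fraction)
                value = (
                    eq.unit_price
                    * qty
                    / annuity_factor(params.discount_rate, eq.useful_life)
                )
                equip_value += value
                items.append(
                    CostItem(
                        id=f"{modality.value}-equip-{eq.name}",
                        country=country,
                        modality=modality,
                        activity=Activity.SURVEY_PREPARATION,
                        subactivity="equipment_purchase",
                        centre=CostCentre.EQUIPMENT,
                        money=Money(eq.unit_price, "USD", 2019),
                        quantity=qty,
                        is_capital=True,
                        useful_life=eq.useful_life,
                        variability=Variability.PER_ENUMERATOR
                        if eq.per_enumerator
                        else Variability.FIXED,
                    )
                )
        for act, sh in zip(arm_activities, adj):
            target = sh * spec.total_cost
            if act == Activity.SURVEY_PREPARATION:
                target -= equip_value
                if target < 0:
                    raise ValueError(
                        "equipment exceeds the survey-preparation share target"
                    )
            add_block(modality, act, target, modality.value)
    return items


# ---------------------------------------------------------------------------
# Calibrated study fixture
# ---------------------------------------------------------------------------

_P = CostCentre.PERSONNEL
_ACT = Activity

# Component tables, in base-year USD.  "kind" is one of personnel / capital /
# direct; amounts are the valued (annualised, normalised) contributions that
# the calibration targets.  "pool" marks the items whose fixed-vs-variable
# split is solved so the national projection lands on the published totals.
# An international personnel row with amount None is the balancing item whose
# size is solved so the localisation scenario lands on the published
# per-respondent figures.
# fmt: off
_FIXTURE = {
    "vietnam": {
        "totals": {"inddex24": 111_004.0, "papi": 120_483.0},
        "localized_totals": {"inddex24": 498.0 * 147, "papi": 448.0 * 147},
        "national_totals": {"inddex24": 477_267.0, "papi": 601_001.0},
        "n": {"inddex24": 147, "papi": 147},
        "base_field_months": 2.0,
        "hubs": 3,
        "national_n": 4_376,
        "base_clerks": {"inddex24": 1.0, "papi": 2.0},
        "shared": [
            ("ref-intl-res", _ACT.DIETARY_REFERENCE_DATA_PREP, "food_list_recipes", _P, "personnel", 18_000.0, ("researcher", "international"), "fixed"),
            ("ref-intl-lead", _ACT.DIETARY_REFERENCE_DATA_PREP, "oversight", _P, "personnel", 7_000.0, ("lead_researcher", "international"), "fixed"),
            ("ref-loc-res", _ACT.DIETARY_REFERENCE_DATA_PREP, "conversion_factors", _P, "personnel", 8_000.0, ("researcher", "in_country"), "fixed"),
            ("ref-chef", _ACT.DIETARY_REFERENCE_DATA_PREP, "standard_recipes", _P, "personnel", 3_000.0, ("chef", "in_country"), "fixed"),
            ("ref-coord", _ACT.DIETARY_REFERENCE_DATA_PREP, "coordination", _P, "personnel", 3_000.0, ("coordinator", "in_country"), "fixed"),
            ("ref-supplies", _ACT.DIETARY_REFERENCE_DATA_PREP, "photo_atlas_supplies", CostCentre.SUPPLIES, "direct", 2_900.0, None, "fixed"),
        ],
        "inddex24": [
            ("prep-tablets", _ACT.SURVEY_PREPARATION, "equipment_purchase", CostCentre.EQUIPMENT, "capital", 3_000.0, (3, 11.0), "per_enumerator"),
            ("prep-subscription", _ACT.SURVEY_PREPARATION, "mobile_platform_subscription", CostCentre.SUPPLIES, "direct", 2_500.0, None, "fixed"),
            ("prep-intl-res", _ACT.SURVEY_PREPARATION, "instrument_configuration", _P, "personnel", 4_000.0, ("researcher", "international"), "fixed"),
            ("prep-loc-res", _ACT.SURVEY_PREPARATION, "manuals_materials", _P, "personnel", 3_200.0, ("researcher", "in_country"), "fixed"),
            ("prep-supplies", _ACT.SURVEY_PREPARATION, "field_supplies", CostCentre.SUPPLIES, "direct", 2_300.0, None, "fixed"),
            ("train-staff", _ACT.TRAINING, "enumerator_training", _P, "personnel", 2_500.0, ("field_supervisor", "in_country"), "per_enumerator"),
            ("train-capacity", _ACT.TRAINING, "capacity_building", _P, "personnel", 800.0, ("technical_advisor", "in_country"), "fixed"),
            ("train-venue", _ACT.TRAINING, "training_venue", CostCentre.FACILITIES, "direct", 900.0, None, "per_hub"),
            ("train-perdiem", _ACT.TRAINING, "trainee_per_diem", CostCentre.PER_DIEM, "direct", 1_800.0, None, "per_enumerator"),
            ("exec-intl-res", _ACT.SURVEY_EXECUTION, "field_oversight", _P, "personnel", 4_000.0, ("researcher", "international"), "per_month"),
            ("exec-perdiem", _ACT.SURVEY_EXECUTION, "field_per_diem", CostCentre.PER_DIEM, "direct", 3_600.0, None, "per_month"),
            ("exec-transport", _ACT.SURVEY_EXECUTION, "field_transport", CostCentre.TRANSPORTATION, "direct", 3_200.0, None, "per_month"),
            ("exec-lodging", _ACT.SURVEY_EXECUTION, "field_lodging", CostCentre.LODGING, "direct", 1_800.0, None, "per_month"),
            ("exec-scales", _ACT.SURVEY_EXECUTION, "equipment_purchase", CostCentre.EQUIPMENT, "capital", 400.0, (2, 8.0), "per_enumerator"),
            ("exec-field-staff", _ACT.SURVEY_EXECUTION, "interviews", _P, "personnel", None, ("enumerator", "in_country"), "pool"),
            ("entry-dsup", _ACT.DATA_ENTRY, "electronic_data_monitoring", _P, "personnel", 1_200.0, ("data_supervisor", "in_country"), "fixed"),
            ("clean-intl-stat", _ACT.DATA_CLEANING_PROCESSING, "dataset_preparation", _P, "personnel", None, ("statistician", "international"), "per_month"),
            ("clean-loc", _ACT.DATA_CLEANING_PROCESSING, "data_cleaning", _P, "personnel", 3_000.0, ("researcher", "in_country"), "pool"),
            ("admin-intl-lead", _ACT.ADMINISTRATION, "management_oversight", _P, "personnel", 6_000.0, ("lead_researcher", "international"), "fixed"),
            ("admin-loc", _ACT.ADMINISTRATION, "local_administration", _P, "personnel", 3_000.0, ("administrator", "in_country"), "fixed"),
            ("admin-other", _ACT.ADMINISTRATION, "irb_overhead", CostCentre.OTHER, "direct", 4_000.0, None, "fixed"),
        ],
        "papi": [
            ("prep-intl-res", _ACT.SURVEY_PREPARATION, "instrument_design", _P, "personnel", 4_000.0, ("researcher", "international"), "fixed"),
            ("prep-printing", _ACT.SURVEY_PREPARATION, "form_printing", CostCentre.SUPPLIES, "direct", 3_500.0, None, "pool"),
            ("prep-loc-res", _ACT.SURVEY_PREPARATION, "manuals_materials", _P, "personnel", 2_500.0, ("researcher", "in_country"), "fixed"),
            ("prep-supplies", _ACT.SURVEY_PREPARATION, "field_supplies", CostCentre.SUPPLIES, "direct", 1_800.0, None, "fixed"),
            ("train-intl-res", _ACT.TRAINING, "trainer_time", _P, "personnel", 3_000.0, ("researcher", "international"), "per_enumerator"),
            ("train-staff", _ACT.TRAINING, "enumerator_training", _P, "personnel", 2_000.0, ("field_supervisor", "in_country"), "per_enumerator"),
            ("train-capacity", _ACT.TRAINING, "capacity_building", _P, "personnel", 800.0, ("technical_advisor", "in_country"), "fixed"),
            ("train-venue", _ACT.TRAINING, "training_venue", CostCentre.FACILITIES, "direct", 700.0, None, "per_hub"),
            ("train-perdiem", _ACT.TRAINING, "trainee_per_diem", CostCentre.PER_DIEM, "direct", 1_000.0, None, "per_enumerator"),
            ("exec-intl-res", _ACT.SURVEY_EXECUTION, "field_oversight", _P, "personnel", 8_000.0, ("researcher", "international"), "per_month"),
            ("exec-perdiem", _ACT.SURVEY_EXECUTION, "field_per_diem", CostCentre.PER_DIEM, "direct", 4_200.0, None, "per_month"),
            ("exec-transport", _ACT.SURVEY_EXECUTION, "field_transport", CostCentre.TRANSPORTATION, "direct", 3_500.0, None, "per_month"),
            ("exec-lodging", _ACT.SURVEY_EXECUTION, "field_lodging", CostCentre.LODGING, "direct", 2_100.0, None, "per_month"),
            ("exec-scales", _ACT.SURVEY_EXECUTION, "equipment_purchase", CostCentre.EQUIPMENT, "capital", 350.0, (2, 7.0), "per_enumerator"),
            ("exec-field-staff", _ACT.SURVEY_EXECUTION, "interviews", _P, "personnel", None, ("enumerator", "in_country"), "pool"),
            ("entry-clerks", _ACT.DATA_ENTRY, "double_data_entry", _P, "personnel", 9_000.0, ("data_entry_clerk", "in_country"), "per_respondent"),
            ("entry-dsup", _ACT.DATA_ENTRY, "entry_supervision", _P, "personnel", 1_200.0, ("data_supervisor", "in_country"), "fixed"),
            ("clean-intl-stat", _ACT.DATA_CLEANING_PROCESSING, "dataset_preparation", _P, "personnel", None, ("statistician", "international"), "per_month"),
            ("clean-loc", _ACT.DATA_CLEANING_PROCESSING, "data_cleaning", _P, "personnel", 1_700.0, ("researcher", "in_country"), "pool"),
            ("admin-intl-lead", _ACT.ADMINISTRATION, "management_oversight", _P, "personnel", 6_000.0, ("lead_researcher", "international"), "fixed"),
            ("admin-intl-adm", _ACT.ADMINISTRATION, "project_administration", _P, "personnel", 3_000.0, ("administrator", "international"), "fixed"),
            ("admin-other", _ACT.ADMINISTRATION, "irb_overhead", CostCentre.OTHER, "direct", 2_500.0, None, "fixed"),
        ],
    },
    "burkina_faso": {
        "totals": {"inddex24": 78_105.0, "papi": 79_456.0},
        "localized_totals": {"inddex24": 456.0 * 145, "papi": 410.0 * 146},
        "national_totals": {"inddex24": 802_385.0, "papi": 962_297.0},
        "n": {"inddex24": 145, "papi": 146},
        "base_field_months": 2.0,
        "hubs": 4,
        "national_n": 6_500,
        "base_clerks": {"inddex24": 1.0, "papi": 2.0},
        "shared": [
            ("ref-intl-res", _ACT.DIETARY_REFERENCE_DATA_PREP, "food_list_recipes", _P, "personnel", 6_000.0, ("researcher", "international"), "fixed"),
            ("ref-intl-lead", _ACT.DIETARY_REFERENCE_DATA_PREP, "oversight", _P, "personnel", 2_000.0, ("lead_researcher", "international"), "fixed"),
            ("ref-loc-res", _ACT.DIETARY_REFERENCE_DATA_PREP, "conversion_factors", _P, "personnel", 3_000.0, ("researcher", "in_country"), "fixed"),
            ("ref-chef", _ACT.DIETARY_REFERENCE_DATA_PREP, "standard_recipes", _P, "personnel", 1_000.0, ("chef", "in_country"), "fixed"),
            ("ref-supplies", _ACT.DIETARY_REFERENCE_DATA_PREP, "photo_book_supplies", CostCentre.SUPPLIES, "direct", 1_122.0, None, "fixed"),
        ],
        "inddex24": [
            ("prep-tablets", _ACT.SURVEY_PREPARATION, "equipment_purchase", CostCentre.EQUIPMENT, "capital", 3_000.0, (3, 11.0), "per_enumerator"),
            ("prep-subscription", _ACT.SURVEY_PREPARATION, "mobile_platform_subscription", CostCentre.SUPPLIES, "direct", 2_000.0, None, "fixed"),
            ("prep-loc-res", _ACT.SURVEY_PREPARATION, "manuals_materials", _P, "personnel", 11_500.0, ("researcher", "in_country"), "fixed"),
            ("prep-supplies", _ACT.SURVEY_PREPARATION, "field_supplies", CostCentre.SUPPLIES, "direct", 1_464.0, None, "fixed"),
            ("train-staff", _ACT.TRAINING, "enumerator_training", _P, "personnel", 2_400.0, ("field_supervisor", "in_country"), "per_enumerator"),
            ("train-capacity", _ACT.TRAINING, "capacity_building", _P, "personnel", 600.0, ("technical_advisor", "in_country"), "fixed"),
            ("train-venue", _ACT.TRAINING, "training_venue", CostCentre.FACILITIES, "direct", 600.0, None, "per_hub"),
            ("train-perdiem", _ACT.TRAINING, "trainee_per_diem", CostCentre.PER_DIEM, "direct", 1_900.0, None, "per_enumerator"),
            ("exec-perdiem", _ACT.SURVEY_EXECUTION, "field_per_diem", CostCentre.PER_DIEM, "direct", 2_400.0, None, "per_month"),
            ("exec-transport", _ACT.SURVEY_EXECUTION, "field_transport", CostCentre.TRANSPORTATION, "direct", 2_000.0, None, "per_month"),
            ("exec-lodging", _ACT.SURVEY_EXECUTION, "field_lodging", CostCentre.LODGING, "direct", 1_600.0, None, "per_month"),
            ("exec-scales", _ACT.SURVEY_EXECUTION, "equipment_purchase", CostCentre.EQUIPMENT, "capital", 300.0, (2, 8.0), "per_enumerator"),
            ("exec-field-staff", _ACT.SURVEY_EXECUTION, "interviews", _P, "personnel", None, ("enumerator", "in_country"), "pool"),
            ("entry-dsup", _ACT.DATA_ENTRY, "electronic_data_monitoring", _P, "personnel", 900.0, ("data_supervisor", "in_country"), "fixed"),
            ("clean-intl-stat", _ACT.DATA_CLEANING_PROCESSING, "dataset_preparation", _P, "personnel", None, ("statistician", "international"), "per_month"),
            ("clean-loc", _ACT.DATA_CLEANING_PROCESSING, "data_cleaning", _P, "personnel", 3_000.0, ("researcher", "in_country"), "pool"),
            ("admin-intl-lead", _ACT.ADMINISTRATION, "management_oversight", _P, "personnel", 3_000.0, ("lead_researcher", "international"), "fixed"),
            ("admin-loc", _ACT.ADMINISTRATION, "local_administration", _P, "personnel", 8_800.0, ("administrator", "in_country"), "fixed"),
            ("admin-other", _ACT.ADMINISTRATION, "irb_overhead", CostCentre.OTHER, "direct", 3_821.0, None, "fixed"),
        ],
        "papi": [
            ("prep-printing", _ACT.SURVEY_PREPARATION, "form_printing", CostCentre.SUPPLIES, "direct", 2_500.0, None, "pool"),
            ("prep-loc-res", _ACT.SURVEY_PREPARATION, "manuals_materials", _P, "personnel", 6_000.0, ("researcher", "in_country"), "fixed"),
            ("prep-supplies", _ACT.SURVEY_PREPARATION, "field_supplies", CostCentre.SUPPLIES, "direct", 1_000.0, None, "fixed"),
            ("train-staff", _ACT.TRAINING, "enumerator_training", _P, "personnel", 3_500.0, ("field_supervisor", "in_country"), "per_enumerator"),
            ("train-capacity", _ACT.TRAINING, "capacity_building", _P, "personnel", 600.0, ("technical_advisor", "in_country"), "fixed"),
            ("train-venue", _ACT.TRAINING, "training_venue", CostCentre.FACILITIES, "direct", 500.0, None, "per_hub"),
            ("train-perdiem", _ACT.TRAINING, "trainee_per_diem", CostCentre.PER_DIEM, "direct", 1_400.0, None, "per_enumerator"),
            ("exec-intl-res", _ACT.SURVEY_EXECUTION, "field_oversight", _P, "personnel", 5_000.0, ("researcher", "international"), "per_month"),
            ("exec-perdiem", _ACT.SURVEY_EXECUTION, "field_per_diem", CostCentre.PER_DIEM, "direct", 1_400.0, None, "per_month"),
            ("exec-transport", _ACT.SURVEY_EXECUTION, "field_transport", CostCentre.TRANSPORTATION, "direct", 1_200.0, None, "per_month"),
            ("exec-lodging", _ACT.SURVEY_EXECUTION, "field_lodging", CostCentre.LODGING, "direct", 800.0, None, "per_month"),
            ("exec-scales", _ACT.SURVEY_EXECUTION, "equipment_purchase", CostCentre.EQUIPMENT, "capital", 300.0, (2, 8.0), "per_enumerator"),
            ("exec-field-staff", _ACT.SURVEY_EXECUTION, "interviews", _P, "personnel", None, ("enumerator", "in_country"), "pool"),
            ("entry-clerks", _ACT.DATA_ENTRY, "double_data_entry", _P, "personnel", 9_500.0, ("data_entry_clerk", "in_country"), "per_respondent"),
            ("entry-dsup", _ACT.DATA_ENTRY, "entry_supervision", _P, "personnel", 1_200.0, ("data_supervisor", "in_country"), "fixed"),
            ("clean-intl-stat", _ACT.DATA_CLEANING_PROCESSING, "dataset_preparation", _P, "personnel", None, ("statistician", "international"), "per_month"),
            ("clean-loc", _ACT.DATA_CLEANING_PROCESSING, "data_cleaning", _P, "personnel", 8_000.0, ("researcher", "in_country"), "pool"),
            ("admin-intl-lead", _ACT.ADMINISTRATION, "management_oversight", _P, "personnel", 4_000.0, ("lead_researcher", "international"), "fixed"),
            ("admin-intl-adm", _ACT.ADMINISTRATION, "project_administration", _P, "personnel", 3_000.0, ("administrator", "international"), "fixed"),
            ("admin-loc", _ACT.ADMINISTRATION, "local_administration", _P, "personnel", 9_495.0, ("administrator", "in_country"), "fixed"),
            ("admin-other", _ACT.ADMINISTRATION, "irb_overhead", CostCentre.OTHER, "direct", 3_369.0, None, "fixed"),
        ],
    },
}
# fmt: on


@dataclass
class PaperFixture:
    """Deterministic calibrated ledgers plus everything needed to run them."""

    country: Country
    items: list[CostItem]
    wages: WageTable
    macro: MacroTable
    n_respondents: dict[str, int]
    role_substitutions: dict[str, str]
    national: dict[str, NationalConfig]
    params: ValuationParams


def _respondent_item(country: Country, modality: Modality, n: int) -> CostItem:
    rp = RESPONDENT_PARAMS[country.value]
    minutes = rp["interview_minutes"][modality.value] + rp["consent_minutes"]
    per_resp = minutes * rp["monthly_wage_usd"] / (168.0 * 60.0)
    return CostItem(
        id=f"{modality.value}-respondent-time",
        country=country,
        modality=modality,
        activity=Activity.SURVEY_EXECUTION,
        subactivity="respondent_participation",
        centre=CostCentre.OTHER,
        money=Money(per_resp * n, "USD", 2019),
        payer="respondent",
        variability=Variability.PER_RESPONDENT,
    )


def _build_item(
    country: Country,
    modality: Modality,
    row: tuple,
    wages: WageTable,
    params: ValuationParams,
    amount_override: Optional[float] = None,
) -> CostItem:
    item_id, activity, sub, centre, kind, amount, extra, var = row
    if amount_override is not None:
        amount = amount_override
    variability = None if var == "pool" else Variability(var)
    base = dict(
        id=f"{modality.value}-{item_id}" if modality != Modality.SHARED else f"shared-{item_id}",
        country=country,
        modality=modality,
        activity=activity,
        subactivity=sub,
        centre=centre,
        variability=variability,
    )
    if kind == "personnel":
        role, loc = extra
        loc = Location(loc)
        wage = wages.get(role, loc).wage.amount
        return CostItem(
            money=Money(0.0, "USD", 2019),
            role=role,
            location=loc,
            person_minutes=amount / wage * params.day_minutes,
            **base,
        )
    if kind == "capital":
        life, qty = extra
        unit = (
            amount
            * annuity_factor(params.discount_rate, life)
            / (qty * params.survey_duration_months / 12.0)
        )
        return CostItem(
            money=Money(unit, "USD", 2019),
            quantity=qty,
            is_capital=True,
            useful_life=life,
            **base,
        )
    return CostItem(money=Money(amount, "USD", 2019), **base)


def _national_config(country_cfg: dict, modality: str) -> NationalConfig:
    return NationalConfig(
        n_respondents=country_cfg["national_n"],
        replicate_fraction=0.20,
        hubs=country_cfg["hubs"],
        months_per_hub=1.0,
        interviews_per_enumerator_day=4.0,
        entries_per_clerk_day=8.0,
        supervisor_ratio=6.0,
        clerk_ratio=10.0,
        working_days_per_month=22.0,
        capacity_building_included=False,
        base_n_respondents=country_cfg["n"][modality],
        base_enumerators=4.0,
        base_clerks=country_cfg["base_clerks"][modality],
        base_data_supervisors=1.0,
        base_hubs=1,
        base_field_months=country_cfg["base_field_months"],
    )


def generate_paper_fixture(country: Country | str) -> PaperFixture:
    """Build the calibrated two-arm ledger for one country.

    The valued arm totals equal the published primary-analysis totals to the
    dollar; reference-data, survey-preparation and administration shares
    match the published percentages within one point; and the localisation
    and national-scale scenarios land on the published scenario totals.  The
    calibration works in two steps: activity budgets are allocated to items
    directly, then the split of the field-operations pool between
    respondent-driven and duration-driven components is solved so that the
    national projection reproduces the published national totals.

    Item-level amounts are synthetic allocations, not the study's actual
    (unpublished) expenditures.
    """
    country = Country(country)
    cfg = _FIXTURE[country.value]
    wages = default_wage_table(country)
    macro = default_macro_table()
    params = ValuationParams()

    national = {
        m: _national_config(cfg, m) for m in ("inddex24", "papi")
    }
    shared_total = sum(r[5] for r in cfg["shared"])

    def intl_drop(role: str, amount: float) -> float:
        """Cost reduction when one international item is localised."""
        w_int = wages.get(role, Location.INTERNATIONAL).wage.amount
        w_loc = wages.get(ROLE_SUBSTITUTIONS[role], Location.IN_COUNTRY).wage.amount
        return amount * (1.0 - w_loc / w_int)

    def _is_intl(row) -> bool:
        return row[4] == "personnel" and row[6] is not None and row[6][1] == "international"

    shared_drop = sum(intl_drop(r[6][0], r[5]) for r in cfg["shared"] if _is_intl(r))

    def resolved_rows(modality: Modality) -> list[tuple]:
        """Arm rows with the balancing international item's amount solved.

        The balance item absorbs whatever localisation saving the published
        localisation per-respondent figure still requires after the named
        international items.
        """
        rows = cfg[modality.value]
        required = (
            cfg["totals"][modality.value]
            - cfg["localized_totals"][modality.value]
            - shared_drop
        )
        named = sum(intl_drop(r[6][0], r[5]) for r in rows if _is_intl(r) and r[5] is not None)
        out = []
        for r in rows:
            if _is_intl(r) and r[5] is None and r[7] != "pool":
                unit_drop = intl_drop(r[6][0], 1.0)
                balance = (required - named) / unit_drop
                if balance < 0:
                    raise ValueError(
                        "named international items already exceed the required "
                        "localisation saving"
                    )
                out.append(r[:5] + (balance,) + r[6:])
            else:
                out.append(r)
        return out

    def pool_budget(modality: Modality) -> list[tuple[str, float]]:
        """Pool items of one arm as (row id, amount) pairs.

        The field-staff row has no explicit amount: it absorbs whatever the
        arm total leaves after the shared block, the respondent item and all
        itemised components, so arm totals are exact to the dollar.  It comes
        first in the returned list — it is the natural respondent-driven
        item for the fixed/variable split.
        """
        rows = resolved_rows(modality)
        arm_total = cfg["totals"][modality.value]
        resp_amount = _respondent_item(
            country, modality, cfg["n"][modality.value]
        ).money.amount
        itemised = sum(r[5] for r in rows if r[5] is not None)
        solved_field = arm_total - shared_total - resp_amount - itemised
        if solved_field < 0:
            raise ValueError("fixture composition exceeds the arm total")
        named = [(r[0], r[5]) for r in rows if r[7] == "pool" and r[5] is not None]
        field = [(r[0], solved_field) for r in rows if r[7] == "pool" and r[5] is None]
        return field + named

    def build_arm(modality: Modality, pool_amounts: Optional[dict] = None) -> list[CostItem]:
        """Materialise one arm; pool items split per ``pool_amounts``.

        Without ``pool_amounts`` every pool item is provisionally tagged
        ``per_month``; with it, each pool item is split into a
        ``per_respondent`` part of the given size and a ``per_month`` rest.
        """
        rows = resolved_rows(modality)
        budget = dict(pool_budget(modality))
        items = [_respondent_item(country, modality, cfg["n"][modality.value])]
        for row in rows:
            if row[7] != "pool":
                items.append(_build_item(country, modality, row, wages, params))
                continue
            amount = budget[row[0]]
            if pool_amounts is None:
                split = ((amount, "per_month", ""),)
            else:
                resp_part = pool_amounts.get(row[0], 0.0)
                split = (
                    (resp_part, "per_respondent", "-var"),
                    (amount - resp_part, "per_month", "-fix"),
                )
            for part, tag, suffix in split:
                if part <= 1e-9:
                    continue
                built = _build_item(
                    country, modality, row[:7] + (tag,), wages, params,
                    amount_override=part,
                )
                if suffix:
                    built = built.copy(id=built.id + suffix)
                items.append(built)
        return items

    shared_items = [
        _build_item(country, Modality.SHARED, row, wages, params)
        for row in cfg["shared"]
    ]

    # --- solve the fixed/variable split of each arm's pool ---------------
    items: list[CostItem] = list(shared_items)
    for modality in (Modality.INDDEX24, Modality.PAPI):
        provisional = build_arm(modality)  # pools tagged per_month
        valued = value_ledger(
            apply_localization(
                shared_items + provisional, ROLE_SUBSTITUTIONS, wages
            ),
            wages,
            macro,
            params,
        )
        ncfg = national[modality.value]
        _, summary = project_national(valued, ncfg, country, modality)
        target = cfg["national_totals"][modality.value]
        r_resp = ncfg.effective_interviews / ncfg.base_effective_interviews
        r_month = ncfg.total_field_months / ncfg.base_field_months
        x = (target - summary.total) / (r_resp - r_month)
        pool = pool_budget(modality)
        capacity = sum(a for _, a in pool)
        if not -1e-6 <= x <= capacity + 1e-6:
            raise RuntimeError(
                f"national calibration infeasible for {country.value}/{modality.value}: "
                f"need {x:.2f} of {capacity:.2f}"
            )
        remaining = max(x, 0.0)
        pool_amounts: dict[str, float] = {}
        for name, amount in pool:
            take = min(remaining, amount)
            pool_amounts[name] = take
            remaining -= take
        items.extend(build_arm(modality, pool_amounts=pool_amounts))

    return PaperFixture(
        country=country,
        items=items,
        wages=wages,
        macro=macro,
        n_respondents=dict(cfg["n"]),
        role_substitutions=dict(ROLE_SUBSTITUTIONS),
        national=national,
        params=params,
    )
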