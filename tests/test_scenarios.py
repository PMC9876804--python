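"""Counterfactual engines: borrowing, localisation, national projection."""

import numpy as np
import pandas as pd
import pytest

from recallcost.aggregate import summarize
from recallcost.ledger import (
    Activity,
    CostCentre,
    CostItem,
    Country,
    Location,
    Modality,
    Money,
    RoleWage,
    Variability,
    WageTable,
)
from recallcost.scenarios import (
    LocalizationError,
    NationalConfig,
    apply_fmdb_borrow,
    apply_localization,
    project_national,
    staffing_requirements,
)
from recallcost.valuation import ValuationParams, value_ledger


def _direct(i, amount, modality=Modality.INDDEX24, activity=Activity.SURVEY_EXECUTION,
            variability=Variability.FIXED, country=Country.VIETNAM):
    return CostItem(
        id=str(i),
        country=country,
        modality=modality,
        activity=activity,
        subactivity="s",
        centre=CostCentre.SUPPLIES,
        money=Money(amount, "USD", 2019),
        variability=variability,
    )


class TestFmdbBorrow:
    def test_zero_fraction_is_identity(self, vn_fixture):
        """Borrowing nothing leaves both arms' totals unchanged."""
        fx = vn_fixture
        out = apply_fmdb_borrow(fx.items, 0.0)
        valued0 = value_ledger(fx.items, fx.wages, fx.macro, fx.params)
        valued1 = value_ledger(out, fx.wages, fx.macro, fx.params)
        for m in ("inddex24", "papi"):
            t0 = summarize(valued0, "vietnam", m, 147).total
            t1 = summarize(valued1, "vietnam", m, 147).total
            assert t1 == pytest.approx(t0, rel=1e-12)

    def test_quarter_borrow_scales_reference_item(self):
        item = _direct(1, 1000.0, activity=Activity.DIETARY_REFERENCE_DATA_PREP)
        (out,) = apply_fmdb_borrow([item], 0.25)
        assert out.money.amount == pytest.approx(750.0)

    def test_papi_arm_untouched(self, vn_fixture):
        out = apply_fmdb_borrow(vn_fixture.items, 0.5)
        fx = vn_fixture
        valued = value_ledger(out, fx.wages, fx.macro, fx.params)
        sp = summarize(valued, "vietnam", "papi", 147)
        assert round(sp.total) == 120_483

    def test_full_borrow_zeroes_reference_prep_in_electronic_arm(self, vn_fixture):
        fx = vn_fixture
        out = apply_fmdb_borrow(fx.items, 1.0)
        valued = value_ledger(out, fx.wages, fx.macro, fx.params)
        si = summarize(valued, "vietnam", "inddex24", 147)
        assert si.by_activity["dietary_reference_data_prep"] == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_borrow_fraction(self, vn_fixture):
        fx = vn_fixture
        totals = []
        for f in (0.0, 0.25, 0.5, 0.75, 1.0):
            valued = value_ledger(apply_fmdb_borrow(fx.items, f), fx.wages, fx.macro, fx.params)
            totals.append(summarize(valued, "vietnam", "inddex24", 147).total)
        assert all(a > b for a, b in zip(totals, totals[1:]))

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            apply_fmdb_borrow([], 1.5)

    def test_vietnam_savings_near_printed_range(self, vn_fixture):
        """25%/75% borrowing saves about $136/$277 per respondent vs. paper arm."""
        fx = vn_fixture
        savings = {}
        for f in (0.25, 0.75):
            valued = value_ledger(apply_fmdb_borrow(fx.items, f), fx.wages, fx.macro, fx.params)
            si = summarize(valued, "vietnam", "inddex24", 147)
            sp = summarize(valued, "vietnam", "papi", 147)
            savings[f] = sp.per_respondent - si.per_respondent
        assert savings[0.25] == pytest.approx(136.0, abs=3.0)
        assert savings[0.75] == pytest.approx(277.0, abs=3.0)


class TestLocalization:
    def test_no_international_personnel_is_identity(self):
        items = [_direct(1, 10.0)]
        assert apply_localization(items, {}, WageTable([])) == items

    def test_forced_repricing(self, macro):
        wages = WageTable(
            [
                RoleWage("researcher", Location.INTERNATIONAL, Money(400.0, "USD", 2019)),
                RoleWage("researcher", Location.IN_COUNTRY, Money(80.0, "USD", 2019)),
            ]
        )
        item = CostItem(
            id="i",
            country=Country.VIETNAM,
            modality=Modality.INDDEX24,
            activity=Activity.ADMINISTRATION,
            subactivity="s",
            centre=CostCentre.PERSONNEL,
            money=Money(0.0, "USD", 2019),
            role="researcher",
            location=Location.INTERNATIONAL,
            person_minutes=480.0,
        )
        params = ValuationParams()
        before = value_ledger([item], wages, macro, params)["value_usd"].iloc[0]
        (swapped,) = apply_localization([item], {"researcher": "researcher"}, wages)
        after = value_ledger([swapped], wages, macro, params)["value_usd"].iloc[0]
        assert before == pytest.approx(400.0)
        assert after == pytest.approx(80.0)
        assert swapped.person_minutes == item.person_minutes

    def test_missing_substitution_names_role(self, vn_fixture):
        with pytest.raises(LocalizationError, match="lead_researcher"):
            apply_localization(vn_fixture.items, {"researcher": "researcher"}, vn_fixture.wages)

    def test_vietnam_printed_decrease(self, vn_fixture):
        fx = vn_fixture
        loc = value_ledger(
            apply_localization(fx.items, fx.role_substitutions, fx.wages),
            fx.wages, fx.macro, fx.params,
        )
        base = value_ledger(fx.items, fx.wages, fx.macro, fx.params)
        b = summarize(base, "vietnam", "inddex24", 147)
        l = summarize(loc, "vietnam", "inddex24", 147)
        assert l.per_respondent_reported == 498.0
        pct = (b.per_respondent - l.per_respondent) / b.per_respondent
        assert round(pct * 100) == 34

    def test_composition_with_borrowing_commutes(self, vn_fixture):
        fx = vn_fixture
        a = apply_fmdb_borrow(
            apply_localization(fx.items, fx.role_substitutions, fx.wages), 0.5
        )
        b = apply_localization(
            apply_fmdb_borrow(fx.items, 0.5), fx.role_substitutions, fx.wages
        )
        va = value_ledger(a, fx.wages, fx.macro, fx.params)
        vb = value_ledger(b, fx.wages, fx.macro, fx.params)
        sa = summarize(va, "vietnam", "inddex24", 147)
        sb = summarize(vb, "vietnam", "inddex24", 147)
        assert sa.total == pytest.approx(sb.total, rel=1e-12)


class TestStaffing:
    def _cfg(self, **kw):
        base = dict(n_respondents=6500, base_n_respondents=145)
        base.update(kw)
        return NationalConfig(**base)

    def test_supervisor_ratio_one_to_six(self):
        # 30 enumerator FTEs at a 1:6 ratio -> 5 field supervisors
        cfg = self._cfg(
            n_respondents=5280, replicate_fraction=0.0,
            interviews_per_enumerator_day=8.0, working_days_per_month=22.0,
        )
        st = staffing_requirements(cfg, Modality.INDDEX24)
        assert st.enumerators == 30
        assert st.field_supervisors == 5

    def test_replicate_fraction_inflates_interviews(self):
        cfg = self._cfg(n_respondents=6500, replicate_fraction=0.20)
        assert cfg.effective_interviews == pytest.approx(7800.0)

    def test_zero_replicates_identity(self):
        cfg = self._cfg(replicate_fraction=0.0)
        assert cfg.effective_interviews == 6500

    def test_clerks_only_for_paper_arm(self):
        cfg = self._cfg()
        papi = staffing_requirements(cfg, Modality.PAPI)
        capi = staffing_requirements(cfg, Modality.INDDEX24)
        assert papi.data_entry_clerks > 0
        assert capi.data_entry_clerks == 0
        assert capi.data_supervisors == cfg.hubs

    def test_zero_interviews_per_day_rejected(self):
        cfg = self._cfg(interviews_per_enumerator_day=0.0)
        with pytest.raises(ValueError):
            staffing_requirements(cfg, Modality.PAPI)


class TestProjectNational:
    def test_identity_scaling_when_config_matches_base(self, macro):
        """A national run at the base study's own scale reproduces the base total."""
        items = [
            _direct(1, 1000.0, variability=Variability.FIXED),
            _direct(2, 2000.0, variability=Variability.PER_RESPONDENT),
            _direct(3, 500.0, variability=Variability.PER_HUB),
            _direct(4, 800.0, variability=Variability.PER_MONTH),
        ]
        valued = value_ledger(items, None, macro, ValuationParams())
        cfg = NationalConfig(
            n_respondents=147, replicate_fraction=0.0, hubs=1, months_per_hub=2.0,
            base_n_respondents=147, base_hubs=1, base_field_months=2.0,
            capacity_building_included=True,
        )
        _, summary = project_national(valued, cfg, Country.VIETNAM, Modality.INDDEX24)
        assert summary.total == pytest.approx(4300.0, rel=1e-12)

    def test_missing_variability_tag_names_items(self, macro):
        items = [_direct(1, 10.0, variability=None)]
        valued = value_ledger(items, None, macro, ValuationParams())
        with pytest.raises(ValueError, match="variability"):
            project_national(
                valued,
                NationalConfig(n_respondents=100, base_n_respondents=10),
                Country.VIETNAM,
                Modality.INDDEX24,
            )

    @pytest.mark.parametrize(
        "country_fixture,expected",
        [
            ("vn", {"inddex24": (477_267, 109), "papi": (601_001, 137)}),
            ("bf", {"inddex24": (802_385, 123), "papi": (962_297, 148)}),
        ],
    )
    def test_national_fixture_totals(self, country_fixture, expected, vn_fixture, bf_fixture):
        fx = vn_fixture if country_fixture == "vn" else bf_fixture
        loc = value_ledger(
            apply_localization(fx.items, fx.role_substitutions, fx.wages),
            fx.wages, fx.macro, fx.params,
        )
        for m, (total, per_resp) in expected.items():
            _, s = project_national(loc, fx.national[m], fx.country, m)
            assert round(s.total) == total
            assert s.per_respondent_reported == per_resp

    def test_capacity_building_dropped_by_default(self, vn_fixture):
        fx = vn_fixture
        loc = value_ledger(
            apply_localization(fx.items, fx.role_substitutions, fx.wages),
            fx.wages, fx.macro, fx.params,
        )
        projected, _ = project_national(loc, fx.national["inddex24"], fx.country, "inddex24")
        cb = projected[projected["subactivity"] == "capacity_building"]
        assert (cb["value_usd"] == 0.0).all()

    def test_scale_economy_per_respondent_strictly_decreasing(self, macro):
        """With a positive fixed share, cost/respondent falls as n grows."""
        items = [
            _direct(1, 5000.0, variability=Variability.FIXED),
            _direct(2, 2000.0, variability=Variability.PER_RESPONDENT),
        ]
        valued = value_ledger(items, None, macro, ValuationParams())
        prev = np.inf
        for n in (200, 500, 1000, 5000, 20000):
            cfg = NationalConfig(
                n_respondents=n, replicate_fraction=0.2,
                base_n_respondents=147, base_field_months=1.0,
                capacity_building_included=True,
            )
            _, s = project_national(valued, cfg, Country.VIETNAM, Modality.INDDEX24)
            assert s.per_respondent < prev
            prev = s.per_respondent

    def test_break_even_scale_between_validation_and_national(self, vn_fixture):
        """The electronic arm overtakes paper somewhere between the two scales."""
        fx = vn_fixture
        loc = value_ledger(
            apply_localization(fx.items, fx.role_substitutions, fx.wages),
            fx.wages, fx.macro, fx.params,
        )
        diffs = []
        for n in (300, 600, 1200, 2400, 4376):
            per_resp = {}
            for m in ("inddex24", "papi"):
                cfg = fx.national[m]
                cfg = NationalConfig(
                    **{**cfg.__dict__, "n_respondents": n}
                )
                _, s = project_national(loc, cfg, fx.country, m)
                per_resp[m] = s.per_respondent
            diffs.append(per_resp["inddex24"] - per_resp["papi"])
        # paper arm cheaper at the smallest scale, electronic cheaper nationally
        assert diffs[0] > 0
        assert diffs[-1] < 0
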