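"""Roll-ups: totals, cost per respondent, arm differences, shares."""

import numpy as np
import pandas as pd
import pytest

from recallcost.aggregate import (
    arm_difference,
    cost_per_respondent,
    share_report,
    summarize,
    summary_table,
    time_nontime_by_activity,
)
from recallcost.ledger import Activity, CostCentre, Country, Modality
from recallcost.valuation import round_half_away


class TestCostPerRespondent:
    @pytest.mark.parametrize(
        "total,n,expected",
        [
            (120_483.0, 147, 820.0),
            (78_105.0, 145, 539.0),
            (111_004.0, 147, 755.0),
            (79_456.0, 146, 544.0),
            (0.0, 147, 0.0),
        ],
    )
    def test_printed_cost_efficiency(self, total, n, expected):
        assert cost_per_respondent(total, n) == expected

    def test_zero_respondents_rejected(self):
        with pytest.raises(ValueError):
            cost_per_respondent(100.0, 0)


class TestRounding:
    def test_half_rounds_away_from_zero(self):
        assert round_half_away(64.5) == 65.0
        assert round_half_away(-64.5) == -65.0
        assert round_half_away(0.805, 2) == 0.81


class TestSummarize:
    def test_fixture_reproduces_printed_totals(self, vn_valued, vn_fixture):
        s = summarize(vn_valued, "vietnam", "inddex24", vn_fixture.n_respondents["inddex24"])
        assert round(s.total) == 111_004
        assert s.per_respondent_reported == 755.0

    def test_empty_slice_warns_and_zeroes(self, vn_valued):
        empty = vn_valued[vn_valued["country"] == "nowhere"]
        with pytest.warns(UserWarning, match="empty"):
            s = summarize(empty, "vietnam", "papi", 10)
        assert s.total == 0.0
        assert s.per_respondent == 0.0

    def test_unit_arithmetic(self, vn_valued):
        one = vn_valued.iloc[:1].copy()
        one["value_usd"] = 147.0
        one["modality"] = "inddex24"
        s = summarize(one, one["country"].iloc[0], "inddex24", 147)
        assert s.per_respondent_reported == 1.0

    def test_conservation_across_disaggregations(self, vn_valued, bf_valued, vn_fixture, bf_fixture):
        for valued, fx in ((vn_valued, vn_fixture), (bf_valued, bf_fixture)):
            for m in ("inddex24", "papi"):
                s = summarize(valued, fx.country, m, fx.n_respondents[m])
                assert sum(s.by_activity.values()) == pytest.approx(s.total, rel=1e-12)
                assert sum(s.by_centre.values()) == pytest.approx(s.total, rel=1e-12)
                assert s.time_cost + s.nontime_cost == pytest.approx(s.total, rel=1e-12)

    def test_monotonicity_adding_positive_item(self, vn_valued, vn_fixture):
        s0 = summarize(vn_valued, "vietnam", "inddex24", 147)
        extra = vn_valued.iloc[:1].copy()
        extra["id"] = "extra"
        extra["modality"] = "inddex24"
        extra["value_usd"] = 500.0
        s1 = summarize(pd.concat([vn_valued, extra]), "vietnam", "inddex24", 147)
        assert s1.total > s0.total
        assert s1.per_respondent > s0.per_respondent

    def test_shared_split_allocation_halves_shared_block(self, vn_valued):
        dup = summarize(vn_valued, "vietnam", "inddex24", 147, shared_allocation="duplicate")
        split = summarize(vn_valued, "vietnam", "inddex24", 147, shared_allocation="split")
        shared_value = vn_valued.loc[vn_valued["modality"] == "shared", "value_usd"].sum()
        assert dup.total - split.total == pytest.approx(shared_value / 2.0, rel=1e-9)

    def test_respondent_perspective_contains_only_respondent_payers(self, vn_valued):
        s = summarize(vn_valued, "vietnam", "inddex24", 147, perspective="respondent")
        assert s.total == pytest.approx(
            vn_valued.loc[
                (vn_valued["payer"] == "respondent")
                & (vn_valued["modality"] == "inddex24"),
                "value_usd",
            ].sum()
        )
        # per respondent this is the participation cost, about $0.81
        assert round(s.per_respondent, 2) == 0.81

    def test_brute_force_oracle_on_random_ledgers(self):
        """summarize agrees with naive per-item summation to 1e-9."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            k = rng.integers(1, 50)
            df = pd.DataFrame(
                {
                    "id": [f"i{j}" for j in range(k)],
                    "country": "vietnam",
                    "modality": rng.choice(["inddex24", "papi", "shared"], size=k),
                    "activity": rng.choice([a.value for a in Activity], size=k),
                    "subactivity": "s",
                    "centre": rng.choice([c.value for c in CostCentre], size=k),
                    "payer": "project",
                    "role": None,
                    "location": None,
                    "is_capital": False,
                    "variability": None,
                    "value_usd": rng.uniform(0, 1e4, size=k),
                }
            )
            s = summarize(df, "vietnam", "inddex24", 100)
            brute = sum(
                v
                for m, v in zip(df["modality"], df["value_usd"])
                if m in ("inddex24", "shared")
            )
            assert s.total == pytest.approx(brute, rel=1e-9, abs=1e-9)


class TestArmDifference:
    def test_vietnam_printed_difference(self, vn_valued, vn_fixture):
        si = summarize(vn_valued, "vietnam", "inddex24", 147)
        sp = summarize(vn_valued, "vietnam", "papi", 147)
        d = arm_difference(si, sp)
        assert d.per_respondent_reported == -64.0

    def test_burkina_printed_difference(self, bf_valued, bf_fixture):
        si = summarize(bf_valued, "burkina_faso", "inddex24", 145)
        sp = summarize(bf_valued, "burkina_faso", "papi", 146)
        d = arm_difference(si, sp)
        assert d.per_respondent_reported == -6.0

    def test_identical_summaries_give_zero(self, vn_valued):
        s = summarize(vn_valued, "vietnam", "inddex24", 147)
        d = arm_difference(s, s)
        assert d.total == 0.0
        assert all(v == 0.0 for v in d.by_activity.values())
        assert d.per_respondent == 0.0

    def test_mismatched_country_rejected(self, vn_valued, bf_valued):
        a = summarize(vn_valued, "vietnam", "inddex24", 147)
        b = summarize(bf_valued, "burkina_faso", "papi", 146)
        with pytest.raises(ValueError, match="country"):
            arm_difference(a, b)


class TestShareReport:
    def test_single_activity_degenerate_share(self, vn_valued):
        only = vn_valued[vn_valued["activity"] == "administration"].copy()
        only["modality"] = "inddex24"
        s = summarize(only, "vietnam", "inddex24", 147)
        shares = share_report(s)
        assert shares["by_activity"]["administration"] == pytest.approx(1.0)

    def test_forced_arithmetic(self):
        df = pd.DataFrame(
            {
                "id": ["a", "b"],
                "country": "vietnam",
                "modality": "inddex24",
                "activity": "administration",
                "subactivity": "s",
                "centre": ["personnel", "other"],
                "payer": "project",
                "role": None,
                "location": None,
                "is_capital": False,
                "variability": None,
                "value_usd": [75.0, 25.0],
            }
        )
        s = summarize(df, "vietnam", "inddex24", 10)
        assert share_report(s)["by_centre"]["personnel"] == pytest.approx(0.75)

    def test_reference_data_share_matches_printed_37_percent(self, vn_valued):
        s = summarize(vn_valued, "vietnam", "inddex24", 147)
        share = share_report(s)["by_activity"]["dietary_reference_data_prep"]
        assert share == pytest.approx(0.37, abs=0.01)

    def test_personnel_share_within_printed_band(self, vn_valued, bf_valued, vn_fixture, bf_fixture):
        for valued, fx in ((vn_valued, vn_fixture), (bf_valued, bf_fixture)):
            for m in ("inddex24", "papi"):
                s = summarize(valued, fx.country, m, fx.n_respondents[m])
                assert 0.67 <= share_report(s)["by_centre"]["personnel"] <= 0.83


def test_summary_table_layout(vn_valued):
    si = summarize(vn_valued, "vietnam", "inddex24", 147)
    sp = summarize(vn_valued, "vietnam", "papi", 147)
    table = summary_table(si, sp)
    assert list(table.columns) == ["activity", "inddex24_usd", "papi_usd", "difference_usd"]
    total_row = table[table["activity"] == "Total"].iloc[0]
    assert total_row["inddex24_usd"] == 111_004
    assert total_row["papi_usd"] == 120_483
    pr = table[table["activity"] == "Cost per respondent"].iloc[0]
    assert (pr["inddex24_usd"], pr["papi_usd"], pr["difference_usd"]) == (755, 820, -64)


def test_time_nontime_tidy_export(vn_valued):
    tidy = time_nontime_by_activity(vn_valued, "vietnam", "inddex24")
    assert set(tidy["component"]) <= {"time", "nontime"}
    si = summarize(vn_valued, "vietnam", "inddex24", 147)
    assert tidy["value_usd"].sum() == pytest.approx(si.total, rel=1e-9)
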