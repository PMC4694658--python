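"""Contingency construction, frequency/share statistics and rank tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from wtflari import (
    build_contingency,
    event_share,
    kruskal_wallis_by_season_across_wts,
    kruskal_wallis_by_wt_across_seasons,
    wt_relative_frequency,
)
from wtflari.event_aggregation import apportion_percent, round_half_away


class TestRounding:
    def test_half_away_from_zero(self):
        assert round_half_away([0.5, 1.5, 2.4, -0.5]).tolist() == [1, 2, 2, -1]

    def test_apportionment_sums_to_100(self):
        out = apportion_percent([0.4883, 0.2212, 0.1552, 0.1353])
        assert out.sum() == 100

    @given(st.lists(st.integers(0, 1000), min_size=2, max_size=12).filter(
        lambda xs: sum(xs) > 0))
    @settings(max_examples=50, deadline=None)
    def test_apportionment_within_one_of_exact(self, counts):
        frac = np.asarray(counts, dtype=float) / sum(counts)
        out = apportion_percent(frac)
        assert out.sum() == 100
        assert np.abs(out - 100 * frac).max() < 1.0 + 1e-9


class TestBuildContingency:
    def test_single_day_two_events(self):
        wt = pd.DataFrame({"date": [pd.Timestamp("2001-01-15")], "wt": [3]})
        ev = pd.DataFrame({"date": [pd.Timestamp("2001-01-15")],
                           "region": ["Liguria"], "count": [2]})
        tables = build_contingency(wt, ev)
        assert tables.seasonal.loc[("winter", 3), "n_days"] == 1
        assert tables.seasonal.loc[("winter", 3), "n_events"] == 2
        assert tables.region_wt["annual"].loc["Liguria", 3] == 2

    def test_no_events_counts_days_only(self, tiny_daily):
        wt, _ = tiny_daily
        tables = build_contingency(wt, None)
        assert tables.seasonal["n_events"].sum() == 0
        assert tables.seasonal["n_days"].sum() == len(wt)

    def test_event_date_outside_series_is_an_error(self, tiny_daily):
        wt, ev = tiny_daily
        ev = pd.concat([ev, pd.DataFrame({
            "date": [pd.Timestamp("1999-06-01")], "region": ["Lazio"],
            "count": [1]})])
        with pytest.raises(ValueError, match="1999-06-01"):
            build_contingency(wt, ev)

    def test_conservation_of_totals(self, tiny_daily):
        wt, ev = tiny_daily
        tables = build_contingency(wt, ev)
        assert tables.seasonal["n_events"].sum() == ev["count"].sum()
        assert tables.seasonal["n_days"].sum() == len(wt)
        assert tables.region_wt["annual"].to_numpy().sum() == ev["count"].sum()

    @given(st.lists(st.tuples(st.integers(0, 59), st.integers(1, 8),
                              st.integers(1, 3)), max_size=25))
    @settings(max_examples=40, deadline=None)
    def test_conservation_property(self, triples):
        dates = pd.date_range("2002-01-01", periods=60, freq="D")
        wt = pd.DataFrame({"date": dates, "wt": (np.arange(60) % 8) + 1})
        ev = pd.DataFrame(
            [(dates[i], "Liguria", c) for i, _, c in triples],
            columns=["date", "region", "count"])
        tables = build_contingency(wt, ev if len(ev) else None)
        assert tables.seasonal["n_events"].sum() == sum(c for _, _, c in triples)
        assert tables.seasonal["n_days"].sum() == 60


class TestFrequenciesAndShares:
    def test_annual_wt_frequencies_match_reference(self, contingency):
        freq = wt_relative_frequency(contingency, "annual")
        assert freq["pct"].tolist() == [10, 22, 11, 12, 25, 0, 11, 9]
        assert freq["fraction"].sum() == pytest.approx(1.0)

    def test_uniform_counts_give_eighths(self):
        idx = pd.MultiIndex.from_product(
            [["winter", "spring", "summer", "autumn"], range(1, 9)],
            names=["season", "wt"])
        cont = pd.DataFrame({"n_days": 10, "n_events": 1}, index=idx)
        freq = wt_relative_frequency(cont, "annual")
        assert (freq["fraction"] == 0.125).all()

    def test_seasonal_event_shares(self, contingency):
        shares = event_share(contingency, "by-season")
        assert dict(zip(shares.index, shares["pct"])) == {
            "winter": 22, "spring": 14, "summer": 15, "autumn": 49}

    def test_within_season_shares(self, contingency):
        ws = event_share(contingency, "by-wt-within-season")
        assert ws.loc[("autumn", 8), "pct"] == 34
        assert ws.loc[("winter", 2), "pct"] == 23
        # shares within each season sum to 1 exactly (raw fractions)
        sums = ws.groupby(level="season", observed=True)["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_single_cell_gets_all_events(self):
        idx = pd.MultiIndex.from_product(
            [["winter", "spring", "summer", "autumn"], range(1, 9)],
            names=["season", "wt"])
        cont = pd.DataFrame({"n_days": 5, "n_events": 0}, index=idx)
        cont.loc[("summer", 4), "n_events"] = 7
        ws = event_share(cont, "by-wt-within-season")
        assert ws.loc[("summer", 4), "pct"] == 100
        assert ws["pct"].sum() == 100  # only summer appears

    def test_empty_scopes_are_errors(self, contingency):
        zero = contingency.copy()
        zero["n_events"] = 0
        with pytest.raises(ValueError):
            event_share(zero, "by-season")
        zero["n_days"] = 0
        with pytest.raises(ValueError):
            wt_relative_frequency(zero, "annual")

    def test_share_invariant_to_region_split(self, tiny_daily):
        wt, ev = tiny_daily
        merged = ev.groupby("date", as_index=False)["count"].sum()
        merged["region"] = "Umbria"
        a = event_share(build_contingency(wt, ev).seasonal, "by-season")
        b = event_share(build_contingency(wt, merged).seasonal, "by-season")
        pd.testing.assert_frame_equal(a, b)


def _daily_frame(counts_by_group, wt_of_group=None):
    """Build a wt/events pair where each group is a season (2001 dates)."""
    season_starts = {"winter": "2001-01-01", "spring": "2001-04-01",
                     "summer": "2001-07-01", "autumn": "2001-10-01"}
    wt_rows, ev_rows = [], []
    for (group, counts) in counts_by_group.items():
        dates = pd.date_range(season_starts[group], periods=len(counts), freq="D")
        w = 1 if wt_of_group is None else wt_of_group[group]
        for d, c in zip(dates, counts):
            wt_rows.append((d, w))
            if c > 0:
                ev_rows.append((d, "Lazio", c))
    wt = pd.DataFrame(wt_rows, columns=["date", "wt"])
    ev = pd.DataFrame(ev_rows, columns=["date", "region", "count"])
    return wt, ev


class TestKruskalWallis:
    def test_identical_counts_give_h0_p1(self):
        wt, ev = _daily_frame({s: [2, 2, 2] for s in
                               ("winter", "spring", "summer", "autumn")})
        res = kruskal_wallis_by_wt_across_seasons(wt, ev)
        assert res.loc[1, "H"] == 0.0 and res.loc[1, "p"] == 1.0

    def test_two_group_hand_computed_oracle(self):
        # groups {1,2,3} vs {4,5,6}: rank sums 6 and 15, no ties, so
        # H = 12/(6*7) * (36/3 + 225/3) - 3*7 = 27/7 = 3.857
        wt, ev = _daily_frame({"winter": [1, 2, 3], "summer": [4, 5, 6]})
        res = kruskal_wallis_by_wt_across_seasons(wt, ev)
        assert res.loc[1, "H"] == pytest.approx(27 / 7, abs=1e-9)
        assert res.loc[1, "df"] == 1
        assert res.loc[1, "p"] == pytest.approx(0.0495, abs=5e-4)

    def test_matches_scipy_on_shared_data(self):
        rng = np.random.default_rng(21)
        groups = {s: rng.poisson(2, size=40).tolist()
                  for s in ("winter", "spring", "summer", "autumn")}
        wt, ev = _daily_frame(groups)
        res = kruskal_wallis_by_wt_across_seasons(wt, ev)
        h, p = stats.kruskal(*groups.values())
        assert res.loc[1, "H"] == pytest.approx(h)
        assert res.loc[1, "p"] == pytest.approx(p)

    def test_wt_in_single_season_flagged_untestable(self):
        wt, ev = _daily_frame({"winter": [1, 2, 3]})
        res = kruskal_wallis_by_wt_across_seasons(wt, ev)
        assert not res.loc[1, "testable"]
        assert np.isnan(res.loc[1, "H"])

    def test_absent_wt_reduces_degrees_of_freedom(self):
        # winter days carry WTs 1..3 only: df = 2 for the winter test
        wt = pd.DataFrame({
            "date": pd.date_range("2001-01-01", periods=9, freq="D"),
            "wt": [1, 1, 1, 2, 2, 2, 3, 3, 3]})
        ev = pd.DataFrame({"date": [wt["date"][0]], "region": ["Lazio"],
                           "count": [4]})
        res = kruskal_wallis_by_season_across_wts(wt, ev)
        assert res.loc["winter", "df"] == 2
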