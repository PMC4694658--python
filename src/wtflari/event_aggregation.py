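"""Season x WT and region x WT contingency statistics and seasonal tests.

Given a daily weather-type series and daily damaging-event records this
module builds the season x WT contingency (``n_days`` N, ``n_events`` E) and
region x WT event counts, derives the frequency and share percentages, and
runs the Kruskal-Wallis rank test comparing per-day event counts across
seasons (per WT) or across WTs (per season).

Display rounding: individual percentages are rounded half-away-from-zero;
the four-season event-share composition is apportioned with the largest-
remainder (Hamilton) method so the displayed set sums to exactly 100, the
standard treatment for an exhaustive composition.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import (
    DEFAULT_SEASON_RULE,
    SEASONS,
    WT_IDS,
    as_event_frame,
    as_wt_frame,
    canonicalize_region,
)


def _season_column(dates: pd.Series, season_rule) -> pd.Series:
    rule = DEFAULT_SEASON_RULE if season_rule is None else dict(season_rule)
    return dates.dt.month.map(rule)

__all__ = [
    "ContingencyTables",
    "build_contingency",
    "wt_relative_frequency",
    "event_share",
    "kruskal_wallis_by_wt_across_seasons",
    "kruskal_wallis_by_season_across_wts",
    "round_half_away",
    "apportion_percent",
]


def round_half_away(x) -> np.ndarray:
    """Round half away from zero to the nearest integer (element-wise)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


def apportion_percent(fractions) -> np.ndarray:
    """Integer percentages summing to 100 via largest-remainder apportionment.

    ``fractions`` must be non-negative and sum to 1 (within tolerance).
    """
    f = np.asarray(fractions, dtype=float)
    if f.size == 0 or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    raw = 100.0 * f
    floors = np.floor(raw).astype(int)
    short = 100 - int(floors.sum())
    # stable: largest remainders first, index order breaking ties
    order = np.argsort(-(raw - floors), kind="stable")
    out = floors.copy()
    out[order[:short]] += 1
    return out


@dataclasses.dataclass
class ContingencyTables:
    """Contingency structures built from daily data.

    ``seasonal``: (season, wt)-indexed DataFrame with ``n_days``/``n_events``;
    ``region_wt``: region x wt event-count matrices per scope (``"annual"``
    plus each season); ``wt_days``: WT-day counts per scope.
    """

    seasonal: pd.DataFrame
    region_wt: dict[str, pd.DataFrame]
    wt_days: dict[str, pd.Series]


def _empty_region_wt(regions: Iterable[str]) -> pd.DataFrame:
    return pd.DataFrame(0, index=sorted(regions), columns=list(WT_IDS), dtype=int)


def build_contingency(wt_series, events=None,
                      season_rule: Mapping[int, str] | None = None,
                      regions: Iterable[str] | None = None) -> ContingencyTables:
    """Build season x WT and region x WT contingency tables from daily data.

    ``wt_series`` is the daily WT series (every day exactly one WT);
    ``events`` the damaging-event records, whose dates must all appear in
    the series (an error lists missing dates otherwise). Events on the same
    (date, region) are summed.
    """
    wt = as_wt_frame(wt_series)
    ev = as_event_frame(events if events is not None else [])
    if len(ev):
        ev["region"] = ev["region"].map(canonicalize_region)
        missing = set(ev["date"]) - set(wt["date"])
        if missing:
            missing_days = sorted(d.date().isoformat() for d in missing)
            raise ValueError(
                f"{len(missing_days)} event date(s) missing from the WT series: "
                f"{missing_days[:10]}")

    wt = wt.assign(season=_season_column(wt["date"], season_rule))
    seasonal = (wt.groupby(["season", "wt"], observed=True).size()
                .reindex(pd.MultiIndex.from_product([SEASONS, WT_IDS],
                                                    names=["season", "wt"]),
                         fill_value=0)
                .rename("n_days").to_frame())

    if regions is None:
        regions = sorted(ev["region"].unique()) if len(ev) else []
    region_wt = {scope: _empty_region_wt(regions) for scope in ("annual", *SEASONS)}

    if len(ev):
        ev = ev.merge(wt, on="date", how="left")
        e_seasonal = (ev.groupby(["season", "wt"], observed=True)["count"].sum()
                      .reindex(seasonal.index, fill_value=0))
        seasonal["n_events"] = e_seasonal.astype(int)
        by_region = ev.groupby(["region", "wt"], observed=True)["count"].sum().unstack(fill_value=0)
        region_wt["annual"] = region_wt["annual"].add(by_region, fill_value=0).astype(int)
        for season in SEASONS:
            sub = ev[ev["season"] == season]
            if len(sub):
                m = sub.groupby(["region", "wt"], observed=True)["count"].sum().unstack(fill_value=0)
                region_wt[season] = region_wt[season].add(m, fill_value=0).astype(int)
    else:
        seasonal["n_events"] = 0

    wt_days = {"annual": seasonal["n_days"].groupby(level="wt").sum()}
    for season in SEASONS:
        wt_days[season] = seasonal.loc[season, "n_days"]
    return ContingencyTables(seasonal=seasonal, region_wt=region_wt, wt_days=wt_days)


def _scope_table(cont: pd.DataFrame, scope: str) -> pd.DataFrame:
    if scope == "annual":
        return cont.groupby(level="wt").sum()
    if scope not in SEASONS:
        raise ValueError(f"scope must be 'annual' or one of {SEASONS}, got {scope!r}")
    return cont.loc[scope]


def wt_relative_frequency(cont: pd.DataFrame, scope: str = "annual") -> pd.DataFrame:
    """Relative WT-day frequency per WT in a scope (annual or one season).

    Returns a WT-indexed frame with the raw ``fraction`` (sums to 1) and the
    display ``pct`` rounded half-away-from-zero.
    """
    tab = _scope_table(cont, scope)
    total = int(tab["n_days"].sum())
    if total <= 0:
        raise ValueError(f"no WT days in scope {scope!r}")
    frac = tab["n_days"] / total
    return pd.DataFrame({"n_days": tab["n_days"],
                         "fraction": frac,
                         "pct": round_half_away(100 * frac.to_numpy())})


def event_share(cont: pd.DataFrame, mode: str = "by-season") -> pd.DataFrame:
    """Event-share percentages from a seasonal contingency table.

    ``mode="by-season"``: the share of all events falling in each season
    (display percentages apportioned to sum to exactly 100).
    ``mode="by-wt-within-season"``: per season, the share of the season's
    events attributable to each WT (rounded half-away-from-zero).
    Raw fractions are carried alongside in both modes.
    """
    total = int(cont["n_events"].sum())
    if total <= 0:
        raise ValueError("no events in the contingency table")
    if mode == "by-season":
        by_season = cont["n_events"].groupby(level="season", observed=True).sum().reindex(SEASONS)
        frac = by_season / total
        return pd.DataFrame({"n_events": by_season,
                             "fraction": frac,
                             "pct": apportion_percent(frac.to_numpy())})
    if mode == "by-wt-within-season":
        out = []
        for season in SEASONS:
            season_tab = cont.loc[season]
            season_total = int(season_tab["n_events"].sum())
            if season_total == 0:
                continue
            frac = season_tab["n_events"] / season_total
            out.append(pd.DataFrame({
                "season": season, "wt": season_tab.index,
                "n_events": season_tab["n_events"].to_numpy(),
                "fraction": frac.to_numpy(),
                "pct": round_half_away(100 * frac.to_numpy())}))
        return pd.concat(out, ignore_index=True).set_index(["season", "wt"])
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# nonparametric seasonal comparison

def _daily_counts(wt_series, events, season_rule) -> pd.DataFrame:
    """Per-day total event count (0 for event-free days) with season and WT."""
    wt = as_wt_frame(wt_series)
    ev = as_event_frame(events if events is not None else [])
    wt = wt.assign(season=_season_column(wt["date"], season_rule))
    if len(ev):
        per_day = ev.groupby("date")["count"].sum()
        wt["events"] = wt["date"].map(per_day).fillna(0).astype(int)
    else:
        wt["events"] = 0
    return wt


def _kruskal(groups: list[np.ndarray]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H, df and chi-squared p-value."""
    try:
        with np.errstate(invalid="ignore"):
            h, p = stats.kruskal(*groups)
    except ValueError:
        h = np.nan
    if np.isnan(h):
        # all observations identical across groups (the tie correction
        # degenerates): no evidence of any difference
        return 0.0, len(groups) - 1, 1.0
    return float(h), len(groups) - 1, float(p)


def kruskal_wallis_by_wt_across_seasons(wt_series, events,
                                        season_rule: Mapping[int, str] | None = None
                                        ) -> pd.DataFrame:
    """Compare daily event counts between seasons, separately per WT.

    The sampling unit is the day: for each WT, the per-day event counts of
    that WT's days are grouped by season and compared with the tie-corrected
    Kruskal-Wallis rank test (chi-squared approximation, groups-1 df).
    WTs whose days fall in fewer than two seasons are flagged untestable.
    """
    daily = _daily_counts(wt_series, events, season_rule)
    rows = []
    for w in WT_IDS:
        sub = daily[daily["wt"] == w]
        groups = [g["events"].to_numpy()
                  for _, g in sub.groupby("season", observed=True) if len(g)]
        if len(groups) < 2:
            rows.append({"wt": w, "H": np.nan, "df": np.nan, "p": np.nan,
                         "testable": False})
            continue
        h, df, p = _kruskal(groups)
        rows.append({"wt": w, "H": h, "df": df, "p": p, "testable": True})
    return pd.DataFrame(rows).set_index("wt")


def kruskal_wallis_by_season_across_wts(wt_series, events,
                                        season_rule: Mapping[int, str] | None = None
                                        ) -> pd.DataFrame:
    """Compare daily event counts between WTs, separately per season.

    WTs with no days in the season are omitted (degrees of freedom shrink
    accordingly); a season with fewer than two populated WTs is untestable.
    """
    daily = _daily_counts(wt_series, events, season_rule)
    rows = []
    for season in SEASONS:
        sub = daily[daily["season"] == season]
        groups = [g["events"].to_numpy()
                  for _, g in sub.groupby("wt", observed=True) if len(g)]
        if len(groups) < 2:
            rows.append({"season": season, "H": np.nan, "df": np.nan,
                         "p": np.nan, "testable": False})
            continue
        h, df, p = _kruskal(groups)
        rows.append({"season": season, "H": h, "df": df, "p": p, "testable": True})
    return pd.DataFrame(rows).set_index("season")
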