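"""Domain types, packaged reference tables, and input validation.

The package ships four small reference tables covering Italy, 1948-2003:

``wt_catalog``
    the eight European weather types (WTs) and the circulation each brings
    over the Italian peninsula;
``exposure``
    per-region exposure/vulnerability measurements — population density
    (inhabitants/km^2), river surface (km) and non-plain surface (km^2);
``seasonal_contingency``
    the season x WT table of WT-day counts ``n_days`` (N) and damaging
    flood/landslide event counts ``n_events`` (E);
``region_wt_share``
    the region x WT matrix of event percentages.

Region names are canonicalized to the Italian spellings of the exposure
table; an alias table maps the English variants (``Lombardy``/``Lombardia``,
``Apulia``/``Puglia``, ``Tuscany``/``Toscany``/``Toscana``, ...).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SEASONS",
    "WT_IDS",
    "DEFAULT_SEASON_RULE",
    "CANONICAL_REGIONS",
    "season_of",
    "canonicalize_region",
    "UnknownRegionError",
    "WeatherTypeDef",
    "RegionExposureRecord",
    "DailyWTRecord",
    "EventRecord",
    "RiskConfig",
    "ValidationReport",
    "load_fixture",
    "validate_event_records",
    "as_wt_frame",
    "as_event_frame",
]

#: Canonical season order used everywhere (calendar winter first).
SEASONS: tuple[str, ...] = ("winter", "spring", "summer", "autumn")

#: Valid weather-type identifiers.
WT_IDS: tuple[int, ...] = tuple(range(1, 9))

#: Meteorological season convention: DJF / MAM / JJA / SON.
DEFAULT_SEASON_RULE: dict[int, str] = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}

#: The 19 Italian regions of the exposure table (canonical spellings).
CANONICAL_REGIONS: tuple[str, ...] = (
    "Abruzzo",
    "Basilicata",
    "Calabria",
    "Campania",
    "Emilia Romagna",
    "Friuli Venezia Giulia",
    "Lazio",
    "Liguria",
    "Lombardia",
    "Marche",
    "Molise",
    "Piemonte",
    "Puglia",
    "Sardegna",
    "Sicilia",
    "Toscana",
    "Trentino Alto Adige",
    "Umbria",
    "Veneto",
)

# Alias -> canonical; keys are lower-case with hyphens collapsed to spaces.
_REGION_ALIASES: dict[str, str] = {
    "lombardy": "Lombardia",
    "piedmont": "Piemonte",
    "sardinia": "Sardegna",
    "sicily": "Sicilia",
    "tuscany": "Toscana",
    "toscany": "Toscana",
    "apulia": "Puglia",
    "emilia romagna": "Emilia Romagna",
    "friuli venezia giulia": "Friuli Venezia Giulia",
    "trentino alto adige": "Trentino Alto Adige",
    "aosta valley": "Valle d'Aosta",  # not part of the 19-region table
}
_CANONICAL_LOOKUP = {r.lower(): r for r in CANONICAL_REGIONS}


class UnknownRegionError(KeyError):
    """Raised when a region name cannot be mapped to a canonical region."""


def season_of(when: dt.date | pd.Timestamp | int,
              rule: Mapping[int, str] | None = None) -> str:
    """Return the season of a date (or month number) under ``rule``.

    ``rule`` maps month (1-12) to a season name; defaults to the
    meteorological convention (Dec-Feb winter, Mar-May spring, ...).
    """
    rule = DEFAULT_SEASON_RULE if rule is None else rule
    month = when if isinstance(when, int) else when.month
    try:
        return rule[month]
    except KeyError:
        raise ValueError(f"season rule does not cover month {month}") from None


def canonicalize_region(name: str) -> str:
    """Map a region name (any known spelling, case-insensitive) to canonical.

    Raises :class:`UnknownRegionError` for names outside the catalog.
    """
    key = " ".join(str(name).strip().replace("-", " ").split()).lower()
    if key in _CANONICAL_LOOKUP:
        return _CANONICAL_LOOKUP[key]
    if key in _REGION_ALIASES:
        canon = _REGION_ALIASES[key]
        if canon.lower() in _CANONICAL_LOOKUP:
            return canon
    raise UnknownRegionError(f"unknown region name: {name!r}")


# ---------------------------------------------------------------------------
# record types

@dataclasses.dataclass(frozen=True)
class WeatherTypeDef:
    """One weather type: integer id in 1..8 plus a circulation description."""

    id: int
    description: str

    def __post_init__(self) -> None:
        if self.id not in WT_IDS:
            raise ValueError(f"weather type id must be in 1..8, got {self.id}")
        if not self.description:
            raise ValueError("weather type description must be non-empty")


@dataclasses.dataclass(frozen=True)
class RegionExposureRecord:
    """Exposure/vulnerability measurements for one region (all > 0)."""

    region: str
    population_density: float
    river_surface: float
    non_plain_surface: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "region", canonicalize_region(self.region))
        for field in ("population_density", "river_surface", "non_plain_surface"):
            if not getattr(self, field) > 0:
                raise ValueError(f"{field} must be strictly positive")


@dataclasses.dataclass(frozen=True)
class DailyWTRecord:
    """One day of the daily weather-type series."""

    date: dt.date
    wt: int

    def __post_init__(self) -> None:
        if self.wt not in WT_IDS:
            raise ValueError(f"wt must be in 1..8, got {self.wt}")


@dataclasses.dataclass(frozen=True)
class EventRecord:
    """Damaging flood/landslide event count for one (date, region)."""

    date: dt.date
    region: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


@dataclasses.dataclass
class RiskConfig:
    """Tunable parameters of the WT-FLARI computation.

    ``w_event``/``w_ev`` weight the event and exposure-vulnerability layers
    in the final index (0.75/0.25); ``layer_weights`` weight population
    density, river surface and non-plain surface inside the EV layer (1/3
    each); ``quantile_levels`` give the annual-index quantiles separating
    low / moderate / high / very-high risk.
    """

    w_event: float = 0.75
    w_ev: float = 0.25
    layer_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    quantile_levels: tuple[float, float, float] = (0.90, 0.95, 0.99)
    season_rule: Mapping[int, str] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SEASON_RULE))
    normalization: str = "minmax"
    event_norm_scope: str = "pooled"  # or "per_wt"

    def __post_init__(self) -> None:
        if abs(self.w_event + self.w_ev - 1.0) > 1e-9:
            raise ValueError("w_event + w_ev must equal 1")
        if not (0.0 <= self.w_event <= 1.0):
            raise ValueError("w_event must lie in [0, 1]")
        if abs(sum(self.layer_weights) - 1.0) > 1e-9:
            raise ValueError("layer_weights must sum to 1")
        q = tuple(self.quantile_levels)
        if len(q) != 3 or not all(0.0 < a < 1.0 for a in q) or not (q[0] < q[1] < q[2]):
            raise ValueError("quantile_levels must be strictly increasing in (0, 1)")
        months = set(self.season_rule)
        if months != set(range(1, 13)):
            raise ValueError("season_rule must map every month 1..12")
        if self.normalization != "minmax":
            raise ValueError(f"unknown normalization method {self.normalization!r}")
        if self.event_norm_scope not in ("pooled", "per_wt"):
            raise ValueError("event_norm_scope must be 'pooled' or 'per_wt'")

    def to_dict(self) -> dict:
        return {
            "w_event": self.w_event,
            "w_ev": self.w_ev,
            "layer_weights": list(self.layer_weights),
            "quantile_levels": list(self.quantile_levels),
            "season_rule": {int(k): v for k, v in self.season_rule.items()},
            "normalization": self.normalization,
            "event_norm_scope": self.event_norm_scope,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RiskConfig":
        d = dict(d)
        if "layer_weights" in d:
            d["layer_weights"] = tuple(d["layer_weights"])
        if "quantile_levels" in d:
            d["quantile_levels"] = tuple(d["quantile_levels"])
        if "season_rule" in d:
            d["season_rule"] = {int(k): v for k, v in d["season_rule"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# packaged fixtures

_FIXTURE_FILES = {
    "wt_catalog": "wt_catalog.csv",
    "exposure": "exposure.csv",
    "seasonal_contingency": "seasonal_contingency.csv",
    "region_wt_share": "region_wt_share.csv",
}


def _read_packaged_csv(filename: str) -> pd.DataFrame:
    with resources.files("wtflari.data").joinpath(filename).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, comment="#")


def load_fixture(table_id: str) -> pd.DataFrame:
    """Load one of the packaged reference tables as a validated DataFrame.

    Returns, by ``table_id``:

    - ``"wt_catalog"``: columns ``wt`` (1..8), ``description``;
    - ``"exposure"``: region-indexed, columns ``population_density``,
      ``river_surface``, ``non_plain_surface``;
    - ``"seasonal_contingency"``: (season, wt)-MultiIndexed, columns
      ``n_days``, ``n_events`` (32 rows);
    - ``"region_wt_share"``: region-indexed, integer columns 1..8.
    """
    if table_id not in _FIXTURE_FILES:
        raise KeyError(
            f"unknown table_id {table_id!r}; valid ids: {sorted(_FIXTURE_FILES)}")
    df = _read_packaged_csv(_FIXTURE_FILES[table_id])

    if table_id == "wt_catalog":
        defs = [WeatherTypeDef(int(r.wt), str(r.description)) for r in df.itertuples()]
        if sorted(d.id for d in defs) != list(WT_IDS):
            raise ValueError("wt_catalog must contain exactly WTs 1..8")
        return df.astype({"wt": int}).set_index("wt").sort_index().reset_index()

    if table_id == "exposure":
        df["region"] = df["region"].map(canonicalize_region)
        if df["region"].duplicated().any():
            raise ValueError("duplicate regions in exposure table")
        if set(df["region"]) != set(CANONICAL_REGIONS):
            raise ValueError("exposure table must cover exactly the 19 regions")
        if not (df[["population_density", "river_surface", "non_plain_surface"]] > 0).all().all():
            raise ValueError("exposure measures must be strictly positive")
        return df.set_index("region").sort_index().astype(float)

    if table_id == "seasonal_contingency":
        out = df.astype({"wt": int, "n_days": int, "n_events": int})
        if set(out["season"]) != set(SEASONS) or len(out) != 32:
            raise ValueError("seasonal contingency must have 4 seasons x 8 WTs")
        if (out[["n_days", "n_events"]] < 0).any().any():
            raise ValueError("contingency counts must be non-negative")
        out["season"] = pd.Categorical(out["season"], categories=SEASONS, ordered=True)
        return out.set_index(["season", "wt"]).sort_index()[["n_days", "n_events"]]

    # region_wt_share
    df["region"] = df["region"].map(canonicalize_region)
    share = df.set_index("region").sort_index()
    share.columns = [int(c.lower().removeprefix("wt")) for c in share.columns]
    share = share.astype(float)
    if set(share.index) != set(CANONICAL_REGIONS) or list(share.columns) != list(WT_IDS):
        raise ValueError("share matrix must be 19 regions x 8 WTs")
    if not ((share >= 0) & share.notna()).all().all():
        raise ValueError("share values must be finite and non-negative")
    return share


# ---------------------------------------------------------------------------
# user-input coercion and validation

def as_wt_frame(wt_series) -> pd.DataFrame:
    """Coerce a daily WT series (records or DataFrame) to a (date, wt) frame."""
    if isinstance(wt_series, pd.DataFrame):
        df = wt_series[["date", "wt"]].copy()
    else:
        df = pd.DataFrame(
            [(r.date, r.wt) for r in wt_series], columns=["date", "wt"])
    df["date"] = pd.to_datetime(df["date"])
    df["wt"] = df["wt"].astype(int)
    if df["date"].duplicated().any():
        dups = df.loc[df["date"].duplicated(), "date"].dt.date.unique()
        raise ValueError(f"duplicate dates in WT series: {list(dups)[:5]}")
    if not df["wt"].isin(WT_IDS).all():
        bad = sorted(set(df.loc[~df["wt"].isin(WT_IDS), "wt"]))
        raise ValueError(f"WT labels outside 1..8: {bad}")
    return df.sort_values("date").reset_index(drop=True)


def as_event_frame(events) -> pd.DataFrame:
    """Coerce event records to a (date, region, count) frame (no validation
    of region names; see :func:`validate_event_records`)."""
    if isinstance(events, pd.DataFrame):
        df = events.copy()
        if "count" not in df.columns:
            df["count"] = 1
        df = df[["date", "region", "count"]]
    else:
        df = pd.DataFrame(
            [(r.date, r.region, r.count) for r in events],
            columns=["date", "region", "count"])
    if len(df):
        df["date"] = pd.to_datetime(df["date"])
        df["count"] = df["count"].astype(int)
    return df.reset_index(drop=True)


@dataclasses.dataclass
class ValidationReport:
    """Outcome of event-record validation (report-based, never raising)."""

    unknown_regions: list[tuple[int, str]] = dataclasses.field(default_factory=list)
    nonpositive_counts: list[int] = dataclasses.field(default_factory=list)
    merge_advisories: list[tuple[str, str, int]] = dataclasses.field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.unknown_regions or self.nonpositive_counts)

    def summary(self) -> str:
        if self.ok and not self.merge_advisories:
            return "event records OK"
        parts = []
        if self.unknown_regions:
            parts.append(f"{len(self.unknown_regions)} unknown region(s)")
        if self.nonpositive_counts:
            parts.append(f"{len(self.nonpositive_counts)} non-positive count(s)")
        if self.merge_advisories:
            parts.append(f"{len(self.merge_advisories)} duplicate (date, region) group(s) to merge")
        return "; ".join(parts)


def validate_event_records(events, exposure: pd.DataFrame | None = None) -> ValidationReport:
    """Check event records against the region catalog.

    Reports unknown regions, non-positive counts and duplicate
    (date, region) rows that would be merged (same-day events per region
    are summed by the aggregation step).
    """
    if exposure is None:
        exposure = load_fixture("exposure")
    known = {str(r).lower() for r in exposure.index}
    df = as_event_frame(events)
    report = ValidationReport()
    canon = []
    for i, row in df.iterrows():
        try:
            c = canonicalize_region(row["region"])
        except UnknownRegionError:
            report.unknown_regions.append((int(i), str(row["region"])))
            canon.append(None)
            continue
        if c.lower() not in known:
            report.unknown_regions.append((int(i), str(row["region"])))
            canon.append(None)
        else:
            canon.append(c)
        if row["count"] < 1:
            report.nonpositive_counts.append(int(i))
    if len(df):
        df = df.assign(_canon=canon).dropna(subset=["_canon"])
        grouped = df.groupby([df["date"].dt.date, "_canon"]).size()
        for (date, region), n in grouped[grouped > 1].items():
            report.merge_advisories.append((str(date), str(region), int(n)))
    return report
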