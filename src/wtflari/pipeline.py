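"""End-to-end orchestration of the WT-FLARI workflow.

Two input modes are supported:

- *tables mode*: the analysis is driven by aggregate tables — the
  region x WT event-share matrix, the seasonal contingency table and the
  exposure table (the packaged reference tables by default). The seasonal
  event layer distributes each region x WT annual weight over seasons in
  proportion to the season's share of that WT's events.
- *daily mode*: a daily WT series plus daily event records; contingency
  tables, per-WT event rates (events per WT-day) and the nonparametric
  seasonal tests are computed from scratch.

Either way the pipeline produces the contingency statistics, the EV and
event layers, annual + seasonal risk matrices, annual quantile thresholds,
categories for every scope, and a run manifest. Outputs are deterministic
given inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_data import (
    SEASONS,
    WT_IDS,
    RiskConfig,
    as_event_frame,
    as_wt_frame,
    canonicalize_region,
    load_fixture,
    validate_event_records,
)
from .event_aggregation import (
    build_contingency,
    event_share,
    kruskal_wallis_by_season_across_wts,
    kruskal_wallis_by_wt_across_seasons,
    wt_relative_frequency,
)
from .risk_index import (
    Layer,
    RiskThresholds,
    build_ev_layer,
    build_event_layer,
    categorize,
    compute_flari,
    derive_thresholds,
    event_rate_weights,
)

__all__ = ["PipelineInputs", "PipelineBundle", "run_pipeline",
           "write_bundle", "read_bundle"]

SCOPES: tuple[str, ...] = ("annual", *SEASONS)


@dataclasses.dataclass
class PipelineInputs:
    """Validated inputs for one pipeline run."""

    mode: str  # "tables" or "daily"
    exposure: pd.DataFrame
    region_wt_share: pd.DataFrame | None = None
    seasonal_contingency: pd.DataFrame | None = None
    wt_series: pd.DataFrame | None = None
    events: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("tables", "daily"):
            raise ValueError("mode must be 'tables' or 'daily'")
        if self.mode == "tables":
            if self.region_wt_share is None or self.seasonal_contingency is None:
                raise ValueError(
                    "tables mode needs region_wt_share and seasonal_contingency")
        else:
            if self.wt_series is None or self.events is None:
                raise ValueError("daily mode needs wt_series and events")

    @classmethod
    def from_fixtures(cls) -> "PipelineInputs":
        """The packaged reference tables (the study's own inputs)."""
        return cls(mode="tables",
                   exposure=load_fixture("exposure"),
                   region_wt_share=load_fixture("region_wt_share"),
                   seasonal_contingency=load_fixture("seasonal_contingency"))

    @classmethod
    def from_daily(cls, wt_series, events,
                   exposure: pd.DataFrame | None = None) -> "PipelineInputs":
        exposure = load_fixture("exposure") if exposure is None else exposure
        wt = as_wt_frame(wt_series)
        ev = as_event_frame(events)
        report = validate_event_records(ev, exposure)
        if not report.ok:
            raise ValueError(f"invalid event records: {report.summary()}")
        if len(ev):
            ev["region"] = ev["region"].map(canonicalize_region)
        return cls(mode="daily", exposure=exposure, wt_series=wt, events=ev)


@dataclasses.dataclass
class PipelineBundle:
    """Everything one pipeline run produces."""

    mode: str
    config: RiskConfig
    contingency: pd.DataFrame
    wt_frequency: pd.DataFrame            # (scope, wt) -> n_days, fraction, pct
    shares_by_season: pd.DataFrame
    shares_within_season: pd.DataFrame
    ev_layer: Layer | None
    event_layers: dict[str, Layer]
    ri: dict[str, pd.DataFrame]
    categories: dict[str, pd.DataFrame]
    thresholds: RiskThresholds
    kw_by_wt: pd.DataFrame | None = None
    kw_by_season: pd.DataFrame | None = None
    manifest: dict = dataclasses.field(default_factory=dict)


def _tables_mode_weights(share: pd.DataFrame, cont: pd.DataFrame
                         ) -> dict[str, pd.DataFrame]:
    """Raw event weights per scope from aggregate tables.

    Annual weights are the share matrix verbatim. A season's weight is the
    annual weight scaled by the season's fraction of that WT's events
    (0 where the WT produced no events at all).
    """
    weights = {"annual": share.copy()}
    e = cont["n_events"].unstack("wt")
    e_total = e.sum(axis=0)
    for season in SEASONS:
        frac = (e.loc[season] / e_total.where(e_total > 0)).fillna(0.0)
        weights[season] = share.mul(frac, axis=1)
    return weights


def _frequency_table(cont: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for scope in SCOPES:
        f = wt_relative_frequency(cont, scope)
        f = f.assign(scope=scope, wt=f.index)
        rows.append(f)
    return pd.concat(rows, ignore_index=True).set_index(["scope", "wt"])


def run_pipeline(inputs: PipelineInputs, config: RiskConfig | None = None,
                 seed: int | None = None) -> PipelineBundle:
    """Run the full workflow and return the output bundle."""
    config = RiskConfig() if config is None else config

    kw_by_wt = kw_by_season = None
    if inputs.mode == "tables":
        cont = inputs.seasonal_contingency
        raw_weights = _tables_mode_weights(inputs.region_wt_share, cont)
    else:
        tables = build_contingency(inputs.wt_series, inputs.events,
                                   season_rule=config.season_rule,
                                   regions=list(inputs.exposure.index))
        cont = tables.seasonal
        raw_weights = {
            scope: event_rate_weights(tables.region_wt[scope], tables.wt_days[scope])
            for scope in SCOPES}
        kw_by_wt = kruskal_wallis_by_wt_across_seasons(
            inputs.wt_series, inputs.events, config.season_rule)
        kw_by_season = kruskal_wallis_by_season_across_wts(
            inputs.wt_series, inputs.events, config.season_rule)

    ev_layer = build_ev_layer(inputs.exposure, config.layer_weights)
    annual_layer = build_event_layer(raw_weights["annual"], scope="annual",
                                     norm_scope=config.event_norm_scope)
    event_layers = {"annual": annual_layer}
    for season in SEASONS:
        event_layers[season] = build_event_layer(
            raw_weights[season], scope=season, annual_norm=annual_layer)

    ri = {scope: compute_flari(event_layers[scope], ev_layer,
                               config.w_event, config.w_ev)
          for scope in SCOPES}
    thresholds = derive_thresholds(ri["annual"], config.quantile_levels)
    categories = {scope: categorize(ri[scope], thresholds) for scope in SCOPES}

    bundle = PipelineBundle(
        mode=inputs.mode, config=config, contingency=cont,
        wt_frequency=_frequency_table(cont),
        shares_by_season=event_share(cont, "by-season"),
        shares_within_season=event_share(cont, "by-wt-within-season"),
        ev_layer=ev_layer, event_layers=event_layers,
        ri=ri, categories=categories, thresholds=thresholds,
        kw_by_wt=kw_by_wt, kw_by_season=kw_by_season)
    bundle.manifest = _build_manifest(inputs, config, seed)
    return bundle


# ---------------------------------------------------------------------------
# manifest and bundle IO

def _digest(df: pd.DataFrame | None) -> str | None:
    if df is None:
        return None
    payload = df.to_csv(float_format="%.12g").encode("utf-8")
    return hashlib.sha256(payload).hexdigest()


def _build_manifest(inputs: PipelineInputs, config: RiskConfig,
                    seed: int | None) -> dict:
    return {
        "package": "wtflari",
        "version": __version__,
        "mode": inputs.mode,
        "seed": seed,
        "config": config.to_dict(),
        "input_digests": {
            "exposure": _digest(inputs.exposure),
            "region_wt_share": _digest(inputs.region_wt_share),
            "seasonal_contingency": _digest(inputs.seasonal_contingency),
            "wt_series": _digest(inputs.wt_series),
            "events": _digest(inputs.events),
        },
        "created": dt.datetime.now(dt.timezone.utc).isoformat(timespec="seconds"),
    }


_FLOAT_FMT = "%.10g"


def write_bundle(bundle: PipelineBundle, out_dir) -> list[Path]:
    """Write the bundle as UTF-8 CSV/JSON files; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _csv(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = out / name
        df.to_csv(path, float_format=_FLOAT_FMT, index=index)
        written.append(path)

    _csv(bundle.contingency, "contingency.csv")
    _csv(bundle.wt_frequency, "wt_frequency.csv")
    _csv(bundle.shares_by_season, "shares_by_season.csv")
    _csv(bundle.shares_within_season, "shares_within_season.csv")
    if bundle.kw_by_wt is not None:
        kw = pd.concat([
            bundle.kw_by_wt.assign(unit="wt", group=bundle.kw_by_wt.index.astype(str)),
            bundle.kw_by_season.assign(unit="season",
                                       group=bundle.kw_by_season.index.astype(str)),
        ]).set_index(["unit", "group"])[["H", "df", "p", "testable"]]
        _csv(kw, "kw_tests.csv")
    if bundle.ev_layer is not None:
        _csv(pd.DataFrame({"ev_raw": bundle.ev_layer.raw,
                           "ev": bundle.ev_layer.normalized}),
             "ev_layer.csv")

    rows = []
    for scope in SCOPES:
        ri = bundle.ri[scope]
        cat = bundle.categories[scope]
        long = ri.stack()
        rows.append(pd.DataFrame({
            "scope": scope,
            "region": long.index.get_level_values(0),
            "wt": long.index.get_level_values(1),
            "ri": long.to_numpy(),
            "category": cat.stack().to_numpy()}))
    _csv(pd.concat(rows, ignore_index=True), "ri_matrix.csv", index=False)

    thr_path = out / "thresholds.json"
    thr_path.write_text(json.dumps({
        **bundle.thresholds.to_dict(),
        "w_event": bundle.config.w_event,
        "w_ev": bundle.config.w_ev,
        "layer_weights": list(bundle.config.layer_weights),
        "event_norm_scope": bundle.config.event_norm_scope,
    }, indent=1) + "\n", encoding="utf-8")
    written.append(thr_path)

    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(bundle.manifest, indent=1) + "\n",
                        encoding="utf-8")
    written.append(man_path)
    return written


def read_bundle(out_dir) -> PipelineBundle:
    """Reconstruct a bundle from a written output directory.

    Layers are not reconstructed (only their products are stored); the
    result carries everything the report renderer consumes.
    """
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text(encoding="utf-8"))
    thr = json.loads((out / "thresholds.json").read_text(encoding="utf-8"))
    config = RiskConfig.from_dict(manifest["config"])

    cont = pd.read_csv(out / "contingency.csv")
    cont["season"] = pd.Categorical(cont["season"], categories=SEASONS, ordered=True)
    cont = cont.set_index(["season", "wt"]).sort_index()

    wt_freq = pd.read_csv(out / "wt_frequency.csv").set_index(["scope", "wt"])
    by_season = pd.read_csv(out / "shares_by_season.csv", index_col=0)
    within = pd.read_csv(out / "shares_within_season.csv").set_index(["season", "wt"])

    ri_long = pd.read_csv(out / "ri_matrix.csv")
    ri, categories = {}, {}
    for scope in SCOPES:
        sub = ri_long[ri_long["scope"] == scope]
        ri[scope] = sub.pivot(index="region", columns="wt", values="ri")
        categories[scope] = sub.pivot(index="region", columns="wt", values="category")

    kw_by_wt = kw_by_season = None
    if (out / "kw_tests.csv").exists():
        kw = pd.read_csv(out / "kw_tests.csv")
        kw_by_wt = (kw[kw["unit"] == "wt"].astype({"group": int})
                    .set_index("group")[["H", "df", "p", "testable"]])
        kw_by_wt.index.name = "wt"
        kw_by_season = kw[kw["unit"] == "season"].set_index("group")[
            ["H", "df", "p", "testable"]]
        kw_by_season.index.name = "season"

    ev_layer = None
    if (out / "ev_layer.csv").exists():
        ev = pd.read_csv(out / "ev_layer.csv", index_col=0)
        ev_layer = Layer(raw=ev["ev_raw"], normalized=ev["ev"],
                         label="exposure_vulnerability",
                         lo=float(ev["ev_raw"].min()), hi=float(ev["ev_raw"].max()))

    return PipelineBundle(
        mode=manifest["mode"], config=config, contingency=cont,
        wt_frequency=wt_freq, shares_by_season=by_season,
        shares_within_season=within, ev_layer=ev_layer, event_layers={},
        ri=ri, categories=categories,
        thresholds=RiskThresholds(q90=thr["q90"], q95=thr["q95"], q99=thr["q99"],
                                  levels=tuple(thr["levels"]), rule=thr["rule"]),
        kw_by_wt=kw_by_wt, kw_by_season=kw_by_season, manifest=manifest)
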