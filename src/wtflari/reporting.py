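"""Human-readable reports and the optional GeoJSON category join."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core_data import SEASONS, WT_IDS, canonicalize_region
from .pipeline import SCOPES, PipelineBundle

__all__ = ["render_report", "attach_categories_to_geojson"]

_SEVERITY = ("very_high", "high", "moderate")  # reported, most severe first


def _contingency_md(cont: pd.DataFrame) -> list[str]:
    lines = ["| season | " + " | ".join(f"WT{w} N / E" for w in WT_IDS) + " |",
             "|" + "---|" * 9]
    for season in SEASONS:
        cells = [f"{int(cont.loc[(season, w), 'n_days'])} / "
                 f"{int(cont.loc[(season, w), 'n_events'])}" for w in WT_IDS]
        lines.append(f"| {season} | " + " | ".join(cells) + " |")
    return lines


def render_report(bundle: PipelineBundle) -> str:
    """Render a markdown report from a bundle (pure function of the bundle).

    Lists, per WT and scope, the regions at each above-low risk category in
    descending index order, alongside the contingency and share statistics.
    """
    L: list[str] = []
    L.append("# WT-FLARI risk report")
    L.append("")
    L.append(f"Input mode: {bundle.mode}. Index weights: "
             f"{bundle.config.w_event:.2f} event layer + "
             f"{bundle.config.w_ev:.2f} exposure/vulnerability layer. "
             f"Annual thresholds (quantiles {list(bundle.thresholds.levels)}, "
             f"{bundle.thresholds.rule} rule): "
             f"q90={bundle.thresholds.q90:.4f}, q95={bundle.thresholds.q95:.4f}, "
             f"q99={bundle.thresholds.q99:.4f}.")
    L.append("")

    L.append("## Season x weather-type contingency (N days / E events)")
    L.append("")
    L.extend(_contingency_md(bundle.contingency))
    L.append("")

    annual_freq = bundle.wt_frequency.loc["annual"]
    freq_txt = ", ".join(f"WT{int(w)} {int(row.pct)}%"
                         for w, row in annual_freq.iterrows())
    L.append(f"Annual weather-type frequencies: {freq_txt}.")
    total_events = int(bundle.shares_by_season["n_events"].sum())
    share_txt = ", ".join(f"{int(row.pct)}% in {s}"
                          for s, row in bundle.shares_by_season.iterrows())
    L.append(f"Of the {total_events} damaging events: {share_txt}.")
    L.append("")

    if bundle.kw_by_season is not None:
        L.append("## Kruskal-Wallis tests (daily event counts)")
        L.append("")
        for season, row in bundle.kw_by_season.iterrows():
            if row["testable"]:
                L.append(f"- {season}: WTs discriminate event frequency with "
                         f"H={row['H']:.2f} (df={int(row['df'])}, p={row['p']:.3g})")
            else:
                L.append(f"- {season}: not testable (fewer than two WTs present)")
        L.append("")

    for scope in SCOPES:
        L.append(f"## Risk categories — {scope}")
        L.append("")
        ri = bundle.ri[scope]
        cats = bundle.categories[scope]
        for w in WT_IDS:
            entries = []
            for severity in _SEVERITY:
                regions = cats.index[cats[w] == severity]
                ranked = ri.loc[regions, w].sort_values(ascending=False)
                entries.extend(
                    f"{region} ({severity}, RI={value:.4f})"
                    for region, value in ranked.items())
            if entries:
                L.append(f"- WT{w}: " + "; ".join(entries))
            else:
                L.append(f"- WT{w}: no regions above the low-risk threshold")
        L.append("")
    return "\n".join(L) + "\n"


def attach_categories_to_geojson(geojson: dict, categories: pd.DataFrame,
                                 region_property: str = "name") -> dict:
    """Join per-WT risk categories onto region boundary features.

    ``geojson`` must be a FeatureCollection whose features carry a region
    name under ``properties[region_property]`` (any known spelling).
    Features gain ``wt<k>_category`` properties; unknown names raise.
    """
    out = json.loads(json.dumps(geojson))  # deep copy
    for feature in out.get("features", []):
        name = feature.get("properties", {}).get(region_property)
        if name is None:
            raise ValueError(f"feature lacks the {region_property!r} property")
        region = canonicalize_region(name)
        if region not in categories.index:
            raise ValueError(f"region {region!r} not present in the category table")
        for w in categories.columns:
            feature["properties"][f"wt{int(w)}_category"] = str(categories.loc[region, w])
    return out
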