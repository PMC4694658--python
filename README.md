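# wtflari

Weather-type-conditioned flood and landslide risk analysis for the Italian
regions.

Damaging floods and landslides in Italy cluster under a small number of
recurrent large-scale circulation patterns ("weather types", WTs). This
package provides a tested, reusable implementation of the full analysis
chain connecting those patterns to regional damage risk:

1. **Weather-type classification** (`wtflari.wt_classifier`): T-mode
   principal-component classification of daily 500 hPa geopotential-height
   fields on a 30–70°N, 30°W–30°E grid (2.5° spacing) into *k* = 8
   circulation classes. Days are the PCA variables and gridpoints the
   observations; the *k*/2 leading components (varimax-rotated) define
   prototype circulation patterns, and each day is assigned to the
   component it loads most strongly on, split by sign:
   component *c* gives class 2*c*−1 for positive loadings and 2*c* for
   negative ones.
2. **Event aggregation** (`wtflari.event_aggregation`): season × WT
   contingency tables of WT-day counts *N* and damaging-event counts *E*,
   all derived frequency and share percentages, and tie-corrected
   Kruskal–Wallis rank tests comparing per-day event counts across seasons
   (per WT) or across WTs (per season).
3. **The WT-FLARI risk index** (`wtflari.risk_index`): following the
   hazard–exposure–vulnerability "risk triangle", each region's exposure /
   vulnerability (EV) layer combines min-max-normalized population density,
   river surface and non-plain surface (weights 1/3 each, renormalized to
   [0, 1]); the event layer min-max-normalizes per-(region, WT) event
   weights; and

   RI(r, w) = 0.75 · event(r, w) + 0.25 · EV(r) ∈ [0, 1].

   Risk categories come from empirical quantiles of the pooled annual
   index: *very high* above the 99th percentile, *high* above the 95th,
   *moderate* above the 90th, *low* otherwise; seasonal indices are
   normalized with the annual anchors and categorized against the same
   annual thresholds.
4. **Synthetic data** (`wtflari.synthetic_data`): seasonal Markov WT
   series, per-(region, WT) Poisson event records with exact bookkeeping,
   and gridded field stacks built from signed prototype patterns plus
   noise — everything needed to exercise and calibrate the pipeline
   without external downloads.

The package ships the study's aggregate reference tables (the eight-WT
catalog, the 19-region exposure table, the 1948–2003 season × WT
contingency, and the region × WT event-share matrix) as plain CSV
fixtures, so the tabular analysis is reproducible out of the box; the
classifier runs on user-supplied gridded fields (CSV matrix + grid spec,
or classic NetCDF) or on synthetic stacks.

## Worked example

```python
>>> import wtflari as w
>>> cont = w.load_fixture("seasonal_contingency")
>>> w.wt_relative_frequency(cont, "annual")[["n_days", "pct"]]
    n_days  pct
wt
1     2066   10
2     4403   22
3     2322   11
4     2512   12
5     5067   25
6       18    0
7     2174   11
8     1865    9
>>> w.event_share(cont, "by-season")["pct"]
season
winter    22
spring    14
summer    15
autumn    49
```

WT5 (Azores high over the Mediterranean) is the most frequent pattern
(25% of the 20 427 classified days), while the rare WT6 occurred on only
18 days in 56 years. Almost half of the 3 002 damaging events (49%) fell
in autumn. The composite risk index on the packaged tables:

```python
>>> ev = w.build_ev_layer(w.load_fixture("exposure"))
>>> event = w.build_event_layer(w.load_fixture("region_wt_share"), scope="annual")
>>> ri = w.compute_flari(event, ev)
>>> ri.stack().nlargest(4)
region
Calabria   6    0.901878
Abruzzo    6    0.827466
Lombardia  8    0.591717
Piemonte   8    0.571120
>>> w.derive_thresholds(ri)
RiskThresholds(q90=0.3454, q95=0.4233, q99=0.7072, levels=(0.9, 0.95, 0.99), rule='linear')
```

With the event-share table taken verbatim, the two WT6 cells at the
matrix maximum (Abruzzo and Calabria, 5.56) dominate the annual index and
are the only *very high* cells; the strongest WT8 cells are Lombardia and
Piemonte (see `docs/methods.md` for a discussion of the event-weight
normalization options and their consequences).

A command-line interface wraps the same functionality:

```sh
wtflari simulate --seed 42 --years 4 --out-dir sim/       # synthetic inputs
wtflari classify --fields sim/fields.csv --grid sim/grid.json --out labels.csv
wtflari aggregate --wt-series sim/wt_series.csv --events sim/events.csv --out-dir agg/
wtflari risk --mode daily --wt-series sim/wt_series.csv --events sim/events.csv --out-dir out/
wtflari report --bundle-dir out/ --out report.md
```

`wtflari risk` (tables mode, the default) reproduces the packaged-table
analysis and writes `contingency.csv`, `ri_matrix.csv` (scope, region,
WT, index, category), `thresholds.json`, a markdown report and a run
manifest; `--geo boundaries.geojson` additionally joins the annual
categories onto user-supplied region polygons.

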