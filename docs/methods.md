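# Methods

This note records the models implemented by `wtflari`, the defaults and
the reasoning behind the choices that were genuinely open.

## Weather-type classification (T-mode PCA)

Daily 500 hPa geopotential-height fields on a regular lat–lon grid
(default 30–70°N, 30°W–30°E at 2.5°, i.e. 17 × 25 = 425 gridpoints) are
classified into an even number *k* of circulation classes (default 8).

**Preprocessing.** Each gridpoint column is standardized over days to
mean 0 and unit standard deviation, using the population (n-denominator)
standard deviation. This makes the classification invariant to the
overall scale and offset of the input fields; zero-variance gridpoints
are set to 0. Whether the source fields should enter as raw heights,
anomalies or standardized anomalies is not uniquely determined by the
classification literature; standardized anomalies were chosen because
they are deterministic and scale-free. `fit_pct(..., standardize=False)`
disables this.

**Extraction.** The *k*/2 leading right singular vectors of the
standardized day × gridpoint matrix define the component patterns
(T-mode: days are the variables, gridpoints the observations). The
retained components are then varimax-rotated on the day loadings. The
rotation matters: when the atmosphere visits a handful of recurrent
prototypes with comparable frequency, the leading singular values are
nearly degenerate and the unrotated singular vectors are an essentially
arbitrary orthogonal mixture within the signal subspace — the classifier
would be well-defined but its classes would not correspond to individual
circulation prototypes. Orthogonal varimax restores one pattern per
prototype (the "simple structure" that T-mode classification schemes
aim for), keeps the patterns exactly orthonormal, and is deterministic
(the iteration starts from the identity). `fit_pct(..., rotate=False)`
keeps the unrotated variant.

**Assignment.** Components are ordered by explained variance
(non-increasing). Each component's sign is fixed so the day loading most
strongly on it sits at its positive pole (first such day on ties). A day
is assigned to the component with the largest absolute score; positive
scores take class 2*c*−1, negative 2*c*. Ties in |score| break toward
the lowest component index; an exact zero score takes the positive sign
and logs a warning. Rank-deficient stacks (e.g. all days identical, or
fewer non-degenerate directions than *k*/2) raise a degenerate-input
error rather than returning meaningless components.

**Identity of the classes.** Which class carries which synoptic identity
depends on the training sample. Labels from independently fitted models
are comparable only up to a permutation of the (odd, even) class pairs
and a sign swap within each pair; `best_label_agreement` evaluates
agreement maximized over exactly those relabelings.

## Event aggregation and display rounding

The daily database joins a WT series (one WT per day) with damaging-event
records (date, region, count ≥ 1); same-day events in the same region are
summed, since the unit of the analysis is the number of events per day.
Seasons follow the meteorological convention (DJF winter, MAM spring,
JJA summer, SON autumn), configurable through `RiskConfig.season_rule`.
"Annual" aggregates all days regardless of season.

Raw fractions are carried everywhere; integer percentages are a display
layer on top. Two rounding rules are used, deliberately:

- individual percentages (per-WT frequencies, within-season event
  shares) are rounded half-away-from-zero;
- the four-season event-share composition is apportioned with the
  largest-remainder (Hamilton) method, the standard treatment when a
  displayed set of percentages is itself the statistic and must sum to
  exactly 100.

With the packaged 1948–2003 contingency table this reproduces the
published integer percentages, with one residual disagreement (the
spring WT5 within-season share computes to 17 where the source prints
18) that is documented in the test suite as a source-side rounding
artifact.

**Kruskal–Wallis wrappers.** The sampling unit is the day: per-day total
event counts (0 for event-free days) are grouped by season within a WT,
or by WT within a season, and compared with the tie-corrected
Kruskal–Wallis test (χ² approximation, groups − 1 degrees of freedom,
via `scipy.stats.kruskal`). Groups without days are omitted; fewer than
two populated groups flags the cell not-testable; all-identical
observations (a degenerate tie correction) are reported as H = 0,
p = 1. Whether multiple same-day events should count once or be summed
is not determined by the aggregate tables; summed per-day counts are
used.

## The WT-FLARI index

**EV layer.** Population density (inhab/km²), river surface (km) and
non-plain surface (km²) are each min-max-normalized over the 19 regions,
combined with weights 1/3 each, and the weighted sum is min-max
rescaled a second time (so the least-exposed region anchors 0 and the
most-exposed 1). The second rescaling is one of two readings of
"renormalized into a single layer"; it was chosen over division by the
maximum because it preserves the [0, 1] anchoring convention used
everywhere else. Note the layer is built from the absolute measures in
the packaged exposure table; per-area densities (river km per km² of
territory, non-plain fraction) would rank small mountainous regions such
as Liguria higher, but regional areas are not part of the packaged data.
This is a known limitation discussed below.

**Event layer.** A non-negative raw weight per (region, WT) cell is
min-max-normalized. Defaults:

- *tables mode*: the packaged region × WT event-share matrix is used
  verbatim. Its normalization basis is not stated in the source (columns
  do not sum to 100), but min-max rescaling makes any global scale
  factor irrelevant.
- *daily mode*: the weight is events per (region, WT) divided by the
  number of days of that WT in the scope — a per-WT-day rate, so rare
  WTs with few days but concentrated damage can score high. A WT with
  zero days gets weight 0 with a warning.

Normalization pools all 19 × 8 cells by default
(`RiskConfig.event_norm_scope="pooled"`); per-WT-column min-max is
available (`"per_wt"`). Pooled was kept as the default because
categorization pools the annual cells too, and per-column rescaling
would force a maximum of 1 into every WT column, including WTs that are
nationally negligible.

**Combination and categories.**
RI(r, w) = w_event · event(r, w) + w_ev · EV(r), defaults 0.75/0.25.
Thresholds are the empirical 90/95/99% quantiles (linear interpolation
between order statistics — numpy's default rule, recorded in the output
metadata) of the pooled annual RI cells; at least 10 cells are required.
Categories: very high above q99, high above q95, moderate above q90,
low otherwise, with boundary values attaching to the lower category
(the source's interval notation leaves boundaries undefined; strict
inequality to enter a higher category is deterministic and
conservative).

**Seasonal indices.** Thresholds are derived from the annual index only
and reused seasonally. Seasonal event layers are normalized with the
*annual* min-max anchors, clipped to [0, 1] (with a warning when
clipping occurs — in daily mode a season's per-day rate can legitimately
exceed the annual rate), so seasonal and annual categories are directly
comparable. In tables mode the seasonal raw weight distributes each
region × WT annual weight over seasons in proportion to the season's
share of that WT's events from the contingency table:
weight(r, w, s) = share(r, w) · E(s, w) / Σₛ E(s, w). This is the
package's concrete construction for a seasonal layer when only annual
region-level shares are available.

## Synthetic-data generators

The generators emulate the statistical structure the analysis assumes,
not the physics behind it:

- **WT series**: day *t* repeats day *t*−1's WT with persistence
  probability ρ (default 0), otherwise draws from the season's marginal.
  Default marginals are the day-count proportions of the packaged
  contingency table, so synthetic series match the 1948–2003 seasonal WT
  climatology out of the box.
- **Events**: independent Poisson counts per day and region with mean
  λ(region, WT-of-day). No spatial correlation, no antecedent-moisture
  memory, no multi-day event persistence — passing tests therefore
  demonstrate correct bookkeeping and calibration under independence,
  not realism of real damage series.
- **Fields**: day = sign · amplitude · P_c + white noise, prototypes
  uniform, signs uniform on {±1}. The prototypes are deterministic
  plane-wave harmonics over the flattened grid (cos/sin pairs of
  increasing frequency, unit norm, exactly orthogonal); the cos/sin
  pairing keeps the pointwise variance envelope nearly constant, so
  per-gridpoint standardization barely distorts the planted patterns.
  Defaults: amplitude 100 gpm, noise sd 10 gpm (10% of amplitude),
  400 days.

A single integer seed drives independent sub-streams (series, events,
fields) via `numpy.random.SeedSequence(seed, spawn_key=(stream,))`; all
generators are bit-reproducible for a fixed seed and spec.

## Problem sizes used in the test suite

The calibration experiments use 400 null replicates and 200 power
replicates of the rank tests at 500 days per group (test size band
0.02–0.09 at α = 0.05; power at a tenfold rate contrast), 400-day field
stacks for classifier recovery, a 56-year series for the marginal check
and a ~10 000-day single-WT series for Poisson rate recovery — large
enough for the stated tolerances, small enough that the full suite runs
in well under a minute of simulation time.

## Known limitations

- The synoptic identity of the eight classes (which label is "the Azores
  ridge") is not reproducible without the original 1948–2003 reanalysis
  fields; only label structure up to permutation is testable.
- The EV layer built from absolute exposure measures does not reproduce
  the published qualitative claim that Liguria has the highest EV value;
  that claim evidently relies on per-area incidence, which the packaged
  tables cannot express. Likewise, with the event-share table taken
  verbatim, its two dominant WT6 cells (5.56, Abruzzo and Calabria) —
  not the strongest WT8 cells — carry the largest annual index values
  under pooled min-max. The relevant tests state the published rankings
  and are left failing rather than silently reinterpreted; the package
  reports what the packaged tables actually imply.
- Tables-mode seasonal layers are a reconstruction (annual shares ×
  seasonal event fractions), not the study's own unavailable seasonal
  region × WT table.
- The index ignores antecedent conditions (multi-day rainfall memory);
  a time-lagged weighting is out of scope.
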