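"""Stochastic generators emulating the statistical structure of the analysis.

Three generators cover the pipeline's inputs:

- a daily weather-type series: each day's WT repeats the previous day's
  with persistence probability ``rho``, otherwise it is drawn from the
  season's marginal distribution (default marginals are those implied by
  the packaged seasonal contingency table, so synthetic series look like
  the 1948-2003 Italian record out of the box);
- damaging-event records: for each day and region an independent Poisson
  count with mean ``lambda(region, wt_of_day)``; zero counts are omitted
  from the records but tracked in the bookkeeping totals;
- gridded daily fields: signed prototype circulation patterns plus white
  noise (``day = sign * amplitude * P_c + noise``), with the ground-truth
  class label ``2c-1``/``2c`` stored per day.

All generators are bit-reproducible for a fixed seed; a single integer
seed drives independent sub-streams (weather series, events, fields) via
``numpy.random.SeedSequence(seed, spawn_key)`` derivation.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .core_data import (
    CANONICAL_REGIONS,
    DEFAULT_SEASON_RULE,
    SEASONS,
    WT_IDS,
    load_fixture,
)
from .wt_classifier import FieldStack, default_grid

__all__ = [
    "WTGeneratorSpec",
    "EventGeneratorSpec",
    "FieldGeneratorSpec",
    "default_seasonal_marginals",
    "simulate_wt_series",
    "simulate_events",
    "simulate_fields",
    "make_prototype_patterns",
    "rng_for",
]

# Fixed sub-stream identifiers for seed derivation.
_STREAMS = {"wt_series": 0, "events": 1, "fields": 2}


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for a named sub-stream of a single seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def default_seasonal_marginals() -> pd.DataFrame:
    """Season x WT probability table implied by the packaged day counts."""
    cont = load_fixture("seasonal_contingency")
    n = cont["n_days"].unstack("wt")
    return n.div(n.sum(axis=1), axis=0)


@dataclasses.dataclass
class WTGeneratorSpec:
    """Daily WT series generator parameters.

    ``seasonal_probs``: season x WT table, rows summing to 1;
    ``persistence``: probability of repeating yesterday's WT;
    ``n_years``: calendar years simulated starting at ``start_year``.
    """

    seasonal_probs: pd.DataFrame | None = None
    persistence: float = 0.0
    n_years: int = 8
    seed: int = 0
    start_year: int = 1948
    season_rule: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        if self.seasonal_probs is None:
            self.seasonal_probs = default_seasonal_marginals()
        probs = self.seasonal_probs
        if set(probs.index) != set(SEASONS) or list(probs.columns) != list(WT_IDS):
            raise ValueError("seasonal_probs must be a 4-season x 8-WT table")
        if (probs.to_numpy() < 0).any():
            raise ValueError("seasonal probabilities must be non-negative")
        if not np.allclose(probs.sum(axis=1).to_numpy(), 1.0, atol=1e-9):
            raise ValueError("each season's probability row must sum to 1")
        if not (0.0 <= self.persistence < 1.0):
            raise ValueError("persistence must lie in [0, 1)")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")


def simulate_wt_series(spec: WTGeneratorSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a daily WT series; returns (series frame, target marginals).

    Day t repeats day t-1's WT with probability ``persistence``, otherwise
    draws from its season's marginal. The returned marginals are the
    generator's target probabilities (also the stationary per-day marginals,
    since persistence resamples from the same distribution).
    """
    rng = rng_for(spec.seed, "wt_series")
    dates = pd.date_range(f"{spec.start_year}-01-01",
                          f"{spec.start_year + spec.n_years - 1}-12-31", freq="D")
    rule = DEFAULT_SEASON_RULE if spec.season_rule is None else dict(spec.season_rule)
    seasons = dates.month.map(rule).to_numpy()
    probs = {s: spec.seasonal_probs.loc[s].to_numpy() for s in SEASONS}
    wts = np.asarray(WT_IDS)

    n = len(dates)
    fresh = np.empty(n, dtype=int)  # season-marginal draw for every day
    for s in SEASONS:
        mask = seasons == s
        fresh[mask] = rng.choice(wts, size=int(mask.sum()), p=probs[s])
    if spec.persistence > 0:
        repeat = rng.random(n) < spec.persistence
        series = fresh.copy()
        for t in range(1, n):
            if repeat[t]:
                series[t] = series[t - 1]
    else:
        series = fresh
    frame = pd.DataFrame({"date": dates, "wt": series})
    return frame, spec.seasonal_probs.copy()


@dataclasses.dataclass
class EventGeneratorSpec:
    """Event generator parameters: expected events/day per (region, WT)."""

    rates: pd.DataFrame  # region x WT, lambda >= 0
    seed: int = 0

    def __post_init__(self) -> None:
        r = self.rates
        if list(r.columns) != list(WT_IDS):
            raise ValueError("rate table must have WT columns 1..8")
        values = r.to_numpy(dtype=float)
        if not np.isfinite(values).all() or (values < 0).any():
            raise ValueError("rates must be finite and non-negative")

    @classmethod
    def uniform(cls, rate: float, regions=CANONICAL_REGIONS, seed: int = 0
                ) -> "EventGeneratorSpec":
        rates = pd.DataFrame(rate, index=list(regions), columns=list(WT_IDS))
        return cls(rates=rates, seed=seed)


def simulate_events(wt_series: pd.DataFrame, spec: EventGeneratorSpec
                    ) -> tuple[pd.DataFrame, dict]:
    """Simulate Poisson event records on a daily WT series.

    Returns ``(events, bookkeeping)`` where ``events`` holds the non-zero
    (date, region, count) records and ``bookkeeping`` carries exact totals:
    ``region_wt_events`` (region x WT), ``wt_days`` (days per WT) and
    ``total_events``. Every (region, WT) pair must be covered by the rate
    table.
    """
    rng = rng_for(spec.seed, "events")
    wt = wt_series.copy()
    wt["date"] = pd.to_datetime(wt["date"])
    missing_wt = set(wt["wt"].unique()) - set(spec.rates.columns)
    if missing_wt:
        raise ValueError(f"rate table missing WT entries: {sorted(missing_wt)}")

    regions = list(spec.rates.index)
    counts = np.zeros((len(wt), len(regions)), dtype=int)
    # one vectorized Poisson block per WT, in fixed WT order for determinism
    for w in WT_IDS:
        day_idx = np.flatnonzero(wt["wt"].to_numpy() == w)
        if day_idx.size == 0:
            continue
        lam = spec.rates[w].to_numpy(dtype=float)
        counts[day_idx] = rng.poisson(lam=lam, size=(day_idx.size, len(regions)))

    day_rows, region_cols = np.nonzero(counts)
    events = pd.DataFrame({
        "date": wt["date"].to_numpy()[day_rows],
        "region": np.asarray(regions, dtype=object)[region_cols],
        "count": counts[day_rows, region_cols],
    })
    region_wt = pd.DataFrame(0, index=regions, columns=list(WT_IDS), dtype=int)
    for w in WT_IDS:
        mask = wt["wt"].to_numpy() == w
        region_wt[w] = counts[mask].sum(axis=0)
    bookkeeping = {
        "region_wt_events": region_wt,
        "wt_days": wt["wt"].value_counts().reindex(WT_IDS, fill_value=0),
        "total_events": int(counts.sum()),
    }
    return events, bookkeeping


# ---------------------------------------------------------------------------
# gridded fields

def make_prototype_patterns(n: int, lats: np.ndarray | None = None,
                            lons: np.ndarray | None = None) -> np.ndarray:
    """Deterministic smooth orthonormal prototype patterns on the grid.

    Plane-wave harmonics over the flattened grid: pattern ``2m`` is
    ``cos(2*pi*(m+1)*t/G)`` and pattern ``2m+1`` the matching sine, each
    normalized to unit length. Cos/sin pairs make the pointwise sum of
    squared loadings nearly constant across the grid, so per-gridpoint
    standardization barely distorts the patterns. Returns an (n_grid, n)
    matrix with orthonormal columns (Gram matrix = identity to 1e-8).
    """
    if lats is None or lons is None:
        lats, lons = default_grid()
    n_grid = int(np.size(lats) * np.size(lons))
    if n < 1 or n > n_grid:
        raise ValueError(f"need 1 <= n <= {n_grid} patterns, got {n}")
    t = np.arange(n_grid)
    cols = []
    for m in range(n):
        freq = m // 2 + 1
        phase = 2 * np.pi * freq * t / n_grid
        col = np.cos(phase) if m % 2 == 0 else np.sin(phase)
        cols.append(col / np.linalg.norm(col))
    patterns = np.column_stack(cols)
    gram = patterns.T @ patterns
    if not np.allclose(gram, np.eye(n), atol=1e-8):
        raise AssertionError("prototype patterns failed orthonormality check")
    return patterns


@dataclasses.dataclass
class FieldGeneratorSpec:
    """Gridded-field generator parameters.

    ``prototypes``: (n_grid, k/2) orthogonal unit-norm patterns;
    ``amplitude``: signal amplitude; ``noise_sd``: sd of the white noise
    added at every gridpoint; ``n_days`` simulated days.
    """

    prototypes: np.ndarray
    amplitude: float = 100.0
    noise_sd: float = 10.0
    n_days: int = 400
    seed: int = 0
    lats: np.ndarray | None = None
    lons: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lats is None or self.lons is None:
            self.lats, self.lons = default_grid()
        self.prototypes = np.asarray(self.prototypes, dtype=float)
        if self.prototypes.ndim != 2:
            raise ValueError("prototypes must be an (n_grid, n_patterns) matrix")
        if self.prototypes.shape[0] != np.size(self.lats) * np.size(self.lons):
            raise ValueError("prototype rows must match the gridpoint count")
        gram = self.prototypes.T @ self.prototypes
        if not np.allclose(gram - np.diag(np.diag(gram)),
                           np.zeros_like(gram), atol=1e-8):
            raise ValueError("prototype patterns must be mutually orthogonal")
        if self.noise_sd < 0 or self.n_days < 1:
            raise ValueError("noise_sd must be >= 0 and n_days >= 1")


def simulate_fields(spec: FieldGeneratorSpec) -> tuple[FieldStack, np.ndarray]:
    """Simulate a daily field stack with known class labels.

    Day ``i`` is ``s_i * amplitude * P_{c_i} + noise`` with the prototype
    index ``c_i`` uniform and the sign ``s_i`` uniform on {+1, -1}; the true
    label is ``2*c_i - 1`` for positive sign, ``2*c_i`` for negative
    (1-based ``c_i``), matching the classifier's class construction.
    """
    rng = rng_for(spec.seed, "fields")
    n_proto = spec.prototypes.shape[1]
    comp = rng.integers(0, n_proto, size=spec.n_days)
    sign = rng.choice([1.0, -1.0], size=spec.n_days)
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_days, spec.prototypes.shape[0]))
    values = sign[:, None] * spec.amplitude * spec.prototypes[:, comp].T + noise
    labels = 2 * (comp + 1) - 1 + (sign < 0).astype(int)
    dates = pd.date_range("2000-01-01", periods=spec.n_days, freq="D")
    stack = FieldStack(values=values, lats=spec.lats, lons=spec.lons, dates=dates)
    return stack, labels.astype(int)
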