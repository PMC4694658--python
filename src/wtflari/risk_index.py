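"""The WT-FLARI composite risk index.

Following the hazard-exposure-vulnerability (risk triangle) design, the
index combines two min-max normalized layers per Italian region:

- the *exposure/vulnerability (EV) layer*: population density, river
  surface and non-plain surface are each min-max rescaled to [0, 1] over
  regions, averaged with equal weights (1/3 each) and the weighted sum is
  min-max rescaled again, so the least exposed region scores 0 and the
  most exposed 1;
- the *event layer*: a per-(region, WT) non-negative event weight, min-max
  rescaled over all region x WT cells (pooled, the default) or within each
  WT column.

The index is ``RI(r, w) = 0.75 * event(r, w) + 0.25 * EV(r)`` and lies in
[0, 1]. Risk categories come from empirical quantiles (linear
interpolation) of the pooled *annual* index values: very high above the
99th percentile, high above the 95th, moderate above the 90th, low
otherwise; boundaries attach to the lower category. Seasonal index values
are normalized with the annual min-max constants (clipped to [0, 1]) and
categorized against the same annual thresholds, so seasonal and annual
categories are directly comparable.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import RiskConfig, WT_IDS

__all__ = [
    "Layer",
    "RiskThresholds",
    "CATEGORIES",
    "minmax_normalize",
    "build_ev_layer",
    "build_event_layer",
    "compute_flari",
    "derive_thresholds",
    "categorize",
    "event_rate_weights",
]

#: Category labels, most severe first.
CATEGORIES: tuple[str, ...] = ("very_high", "high", "moderate", "low")


@dataclasses.dataclass
class Layer:
    """A normalized layer: raw values, [0,1] values, and the min-max anchors."""

    raw: pd.Series | pd.DataFrame
    normalized: pd.Series | pd.DataFrame
    label: str
    lo: float | pd.Series
    hi: float | pd.Series


def _minmax(values: np.ndarray, label: str) -> tuple[np.ndarray, float, float]:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        warnings.warn(f"degenerate {label}: all values equal; layer set to 0",
                      RuntimeWarning, stacklevel=3)
        return np.zeros_like(values, dtype=float), lo, hi
    return (values - lo) / (hi - lo), lo, hi


def minmax_normalize(raw: pd.Series | pd.DataFrame, label: str = "layer") -> Layer:
    """Min-max rescale a keyed set of values to [0, 1].

    Requires at least two keys and finite values; if all values are equal
    the layer degenerates to all zeros (with a warning).
    """
    values = raw.to_numpy(dtype=float)
    if values.size < 2:
        raise ValueError("min-max normalization needs at least 2 values")
    if not np.isfinite(values).all():
        raise ValueError("values must all be finite")
    normed, lo, hi = _minmax(values, label)
    if isinstance(raw, pd.DataFrame):
        normalized = pd.DataFrame(normed, index=raw.index, columns=raw.columns)
    else:
        normalized = pd.Series(normed, index=raw.index)
    return Layer(raw=raw.copy(), normalized=normalized, label=label, lo=lo, hi=hi)


def build_ev_layer(exposure: pd.DataFrame,
                   layer_weights: Sequence[float] = (1 / 3, 1 / 3, 1 / 3)) -> Layer:
    """Combine the three exposure/vulnerability measures into one [0,1] layer.

    Each measure (population density, river surface, non-plain surface) is
    min-max normalized over regions, the three are combined with
    ``layer_weights`` (default equal thirds), and the weighted sum is
    min-max rescaled once more.
    """
    cols = ("population_density", "river_surface", "non_plain_surface")
    if abs(sum(layer_weights) - 1.0) > 1e-9:
        raise ValueError("layer_weights must sum to 1")
    parts = [minmax_normalize(exposure[c], label=c).normalized for c in cols]
    weighted = sum(w * p for w, p in zip(layer_weights, parts))
    out = minmax_normalize(weighted, label="exposure_vulnerability")
    out.raw = weighted  # pre-renormalization composite, for inspection
    return out


def build_event_layer(weights: pd.DataFrame, scope: str = "annual",
                      annual_norm: "tuple | Layer | None" = None,
                      norm_scope: str = "pooled") -> Layer:
    """Normalize region x WT event weights into the [0,1] event layer.

    Annual scope: min-max over the cells (pooled over the whole matrix by
    default, or per WT column with ``norm_scope="per_wt"``); the anchors are
    recorded on the returned layer. Seasonal scope: the annual anchors must
    be supplied (``annual_norm``, a ``(lo, hi)`` pair or the annual Layer)
    and are reused, with values clipped to [0, 1], so seasonal layers are
    comparable with the annual thresholds.
    """
    values = weights.to_numpy(dtype=float)
    if not np.isfinite(values).all() or (values < 0).any():
        raise ValueError("event weights must be finite and non-negative")
    if scope == "annual":
        if norm_scope == "pooled":
            normed, lo, hi = _minmax(values.ravel(), "event layer")
            normed = normed.reshape(values.shape)
            lo_out, hi_out = lo, hi
        elif norm_scope == "per_wt":
            cols, los, his = [], [], []
            for j in range(values.shape[1]):
                nj, lo, hi = _minmax(values[:, j], f"event layer (WT column {j})")
                cols.append(nj)
                los.append(lo)
                his.append(hi)
            normed = np.column_stack(cols)
            lo_out = pd.Series(los, index=weights.columns)
            hi_out = pd.Series(his, index=weights.columns)
        else:
            raise ValueError("norm_scope must be 'pooled' or 'per_wt'")
    else:
        if annual_norm is None:
            raise ValueError("seasonal event layer requires the annual min-max anchors")
        if isinstance(annual_norm, Layer):
            lo_out, hi_out = annual_norm.lo, annual_norm.hi
        else:
            lo_out, hi_out = annual_norm
        lo_arr = np.asarray(lo_out, dtype=float)
        hi_arr = np.asarray(hi_out, dtype=float)
        span = np.where(hi_arr > lo_arr, hi_arr - lo_arr, 1.0)
        normed = (values - lo_arr) / span
        if (normed > 1).any():
            warnings.warn(
                f"{scope} event weights exceed the annual maximum; clipped to 1",
                RuntimeWarning, stacklevel=2)
        normed = np.clip(normed, 0.0, 1.0)
    normalized = pd.DataFrame(normed, index=weights.index, columns=weights.columns)
    return Layer(raw=weights.copy(), normalized=normalized,
                 label=f"event layer ({scope})", lo=lo_out, hi=hi_out)


def event_rate_weights(region_wt_events: pd.DataFrame, wt_days: pd.Series) -> pd.DataFrame:
    """Raw event weights for daily data: events per (region, WT) divided by
    the number of days of that WT in the scope.

    Rare WTs with few days but concentrated damage thereby score high. WT
    columns with zero days yield 0 (with a warning).
    """
    days = wt_days.reindex(region_wt_events.columns).astype(float)
    if (days == 0).any():
        zero = [int(w) for w in days.index[days == 0]]
        if region_wt_events.loc[:, days == 0].to_numpy().any():
            warnings.warn(f"WT(s) {zero} have events but zero days; weight set to 0",
                          RuntimeWarning, stacklevel=2)
    rates = region_wt_events.div(days.where(days > 0), axis=1)
    return rates.fillna(0.0)


def compute_flari(event_layer: Layer, ev_layer: Layer,
                  w_event: float = 0.75, w_ev: float | None = None) -> pd.DataFrame:
    """Weighted combination of the event and EV layers.

    ``RI(r, w) = w_event * event(r, w) + w_ev * EV(r)``, a region x WT
    matrix in [0, 1]. The region sets of the two layers must coincide.
    """
    if w_ev is None:
        w_ev = 1.0 - w_event
    if abs(w_event + w_ev - 1.0) > 1e-9:
        raise ValueError("w_event + w_ev must equal 1")
    ev = ev_layer.normalized
    event = event_layer.normalized
    missing = set(event.index) - set(ev.index)
    extra = set(ev.index) - set(event.index)
    if missing or extra:
        raise ValueError(
            f"region sets differ between layers; only in event layer: "
            f"{sorted(missing)}; only in EV layer: {sorted(extra)}")
    ev = ev.reindex(event.index)
    return event.mul(w_event).add(ev * w_ev, axis=0)


@dataclasses.dataclass
class RiskThresholds:
    """Annual-index quantile thresholds separating the risk categories."""

    q90: float
    q95: float
    q99: float
    levels: tuple[float, float, float] = (0.90, 0.95, 0.99)
    rule: str = "linear"

    def __post_init__(self) -> None:
        if not (self.q90 <= self.q95 <= self.q99):
            raise ValueError("thresholds must be non-decreasing")

    def to_dict(self) -> dict:
        return {"q90": self.q90, "q95": self.q95, "q99": self.q99,
                "levels": list(self.levels), "rule": self.rule}


def derive_thresholds(annual_ri: pd.DataFrame,
                      quantile_levels: Sequence[float] = (0.90, 0.95, 0.99)
                      ) -> RiskThresholds:
    """Empirical quantiles of the pooled annual RI cells.

    Uses linear interpolation between order statistics; requires at least
    10 cells.
    """
    values = annual_ri.to_numpy(dtype=float).ravel()
    if values.size < 10:
        raise ValueError(f"need >= 10 annual RI cells, got {values.size}")
    q = [float(np.quantile(values, lv, method="linear")) for lv in quantile_levels]
    return RiskThresholds(q90=q[0], q95=q[1], q99=q[2],
                          levels=tuple(quantile_levels), rule="linear")


def categorize(ri: pd.DataFrame, thresholds: RiskThresholds) -> pd.DataFrame:
    """Assign a risk category to every RI cell.

    very_high for RI > q99, high for q95 < RI <= q99, moderate for
    q90 < RI <= q95, low otherwise; boundary values fall to the lower
    category (strict > to enter a higher one).
    """
    values = ri.to_numpy(dtype=float)
    cats = np.full(values.shape, "low", dtype=object)
    cats[values > thresholds.q90] = "moderate"
    cats[values > thresholds.q95] = "high"
    cats[values > thresholds.q99] = "very_high"
    return pd.DataFrame(cats, index=ri.index, columns=ri.columns)
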