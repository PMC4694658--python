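"""T-mode principal-component (PCT) weather-type classification.

Daily 500 hPa geopotential-height fields on a lat-lon grid are classified
into ``k`` circulation classes. In T-mode PCA the days are the variables and
the gridpoints the observations: the leading ``k/2`` singular vectors of the
standardized day x gridpoint matrix define prototype circulation patterns,
and each day is assigned to the component its field loads most strongly on,
split by the sign of the loading (component ``c``, 1-based, gives class
``2c-1`` for positive loadings and ``2c`` for negative ones). With ``k = 8``
this yields the eight classes commonly used to describe the main circulation
types over the Italian peninsula.

Preprocessing standardizes each gridpoint over days (population standard
deviation), so classification is invariant to the overall scale of the
input fields. After extraction the retained components are varimax-rotated
on the day loadings: recurrent circulation prototypes of comparable
frequency produce nearly degenerate leading singular values, within which
unrotated components are an arbitrary orthogonal mixture; the rotation
restores one identifiable pattern per prototype (the standard practice for
T-mode classifications) while keeping the patterns orthonormal. Which class
ends up carrying which synoptic identity still depends on the training
sample; labels are therefore comparable only up to a permutation across
independently fitted models.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FieldStack",
    "PCTModel",
    "DegenerateFieldsError",
    "default_grid",
    "standardize_fields",
    "fit_pct",
    "assign_classes",
    "classify_new",
    "best_label_agreement",
    "read_fields_csv",
    "write_fields_csv",
    "read_fields_netcdf",
    "write_labels_csv",
    "read_labels_csv",
]

_SVD_RTOL = 1e-10


class DegenerateFieldsError(ValueError):
    """Raised when the field stack has too little variance to support k classes."""


def default_grid() -> tuple[np.ndarray, np.ndarray]:
    """The default classification grid: 30-70N, 30W-30E at 2.5 degrees."""
    return np.arange(30.0, 70.0 + 1e-9, 2.5), np.arange(-30.0, 30.0 + 1e-9, 2.5)


@dataclasses.dataclass
class FieldStack:
    """A day x gridpoint matrix of 500 hPa geopotential heights (gpm).

    ``values`` has one row per day; columns enumerate gridpoints in
    row-major (lat, lon) order. ``dates`` is optional day metadata.
    """

    values: np.ndarray
    lats: np.ndarray
    lons: np.ndarray
    dates: pd.DatetimeIndex | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D day x gridpoint matrix")
        if self.values.shape[1] != self.lats.size * self.lons.size:
            raise ValueError(
                f"gridpoint count {self.values.shape[1]} != "
                f"lat_count x lon_count = {self.lats.size * self.lons.size}")
        if not np.isfinite(self.values).all():
            raise ValueError("field values must all be finite")
        if self.dates is not None:
            self.dates = pd.DatetimeIndex(self.dates)
            if len(self.dates) != self.values.shape[0]:
                raise ValueError("number of dates must equal number of rows")

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    @property
    def n_grid(self) -> int:
        return self.values.shape[1]

    def same_grid(self, other: "FieldStack | PCTModel") -> bool:
        return (self.lats.size == other.lats.size
                and self.lons.size == other.lons.size
                and np.allclose(self.lats, other.lats)
                and np.allclose(self.lons, other.lons))


@dataclasses.dataclass
class PCTModel:
    """Fitted T-mode PCA classification model.

    ``patterns`` holds the ``k/2`` orthonormal component patterns as columns
    (gridpoint space); ``mean_``/``scale_`` are the training standardization
    constants; ``explained`` the non-increasing share of variance carried by
    each retained component.
    """

    k: int
    patterns: np.ndarray          # (n_grid, k/2)
    mean_: np.ndarray             # (n_grid,)
    scale_: np.ndarray            # (n_grid,) population sd; 0 where degenerate
    explained: np.ndarray         # (k/2,)
    lats: np.ndarray
    lons: np.ndarray

    @property
    def n_components(self) -> int:
        return self.k // 2

    def standardize(self, values: np.ndarray) -> np.ndarray:
        """Apply the training standardization to raw field rows."""
        values = np.asarray(values, dtype=float)
        scale = np.where(self.scale_ > 0, self.scale_, 1.0)
        out = (values - self.mean_) / scale
        out[..., self.scale_ == 0] = 0.0
        return out

    def scores(self, values: np.ndarray, standardized: bool = False) -> np.ndarray:
        """Component scores (projections on the patterns) for field rows."""
        z = np.asarray(values, dtype=float) if standardized else self.standardize(values)
        return z @ self.patterns


def standardize_fields(stack: FieldStack) -> FieldStack:
    """Standardize each gridpoint column to mean 0, unit sd (anomalies).

    Uses the population standard deviation (n denominator). Zero-variance
    columns come back as all zeros. Requires at least two days.
    """
    if stack.n_days < 2:
        raise ValueError("standardization requires at least 2 days")
    mean = stack.values.mean(axis=0)
    sd = stack.values.std(axis=0)  # ddof=0: population sd
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (stack.values - mean) / sd, 0.0)
    return FieldStack(values=z, lats=stack.lats, lons=stack.lons, dates=stack.dates)


def _varimax_rotation(loadings: np.ndarray, tol: float = 1e-10,
                      max_iter: int = 500) -> np.ndarray:
    """Orthogonal varimax rotation matrix for a loading matrix.

    Classic SVD-driven iteration maximizing the variance of squared
    loadings per component; deterministic (starts from the identity).
    """
    n, m = loadings.shape
    if m < 2:
        return np.eye(m)
    rotation = np.eye(m)
    objective = 0.0
    for _ in range(max_iter):
        rotated = loadings @ rotation
        target = rotated ** 3 - rotated * (rotated ** 2).sum(axis=0) / n
        u, s, vt = np.linalg.svd(loadings.T @ target)
        rotation = u @ vt
        new_objective = float(s.sum())
        if new_objective <= objective * (1 + tol):
            break
        objective = new_objective
    return rotation


def fit_pct(stack: FieldStack, k: int = 8, standardize: bool = True,
            rotate: bool = True) -> PCTModel:
    """Fit the T-mode PCA model with ``k`` classes (``k/2`` components).

    The components are the leading right singular vectors of the
    standardized day x gridpoint matrix, varimax-rotated on the day
    loadings (disable with ``rotate=False``) and ordered by explained
    variance; each pattern's sign is fixed so the day loading most strongly
    on it sits at its positive pole. Raises
    :class:`DegenerateFieldsError` when the stack does
    not carry ``k/2`` non-degenerate directions (e.g. all days identical).
    """
    if k % 2 != 0 or k < 2:
        raise ValueError(f"k must be even and >= 2, got {k}")
    if stack.n_days < k:
        raise ValueError(f"need at least k={k} days, got {stack.n_days}")
    if k > 2 * stack.n_days:
        raise ValueError("k may not exceed twice the number of days")

    mean = stack.values.mean(axis=0)
    sd = stack.values.std(axis=0)
    if standardize:
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (stack.values - mean) / sd, 0.0)
        model_mean, model_scale = mean, sd
    else:
        z = stack.values
        model_mean = np.zeros(stack.n_grid)
        model_scale = np.ones(stack.n_grid)

    n_comp = k // 2
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    if s.size < n_comp or s[0] <= 0 or s[n_comp - 1] <= _SVD_RTOL * s[0]:
        raise DegenerateFieldsError(
            f"field stack is rank-deficient: cannot extract {n_comp} components")
    patterns = vt[:n_comp].T.copy()
    day_scores = z @ patterns
    if rotate:
        rotation = _varimax_rotation(day_scores)
        patterns = patterns @ rotation
        day_scores = day_scores @ rotation
    explained = (day_scores ** 2).sum(axis=0) / float(np.sum(s ** 2))
    order = np.argsort(-explained, kind="stable")
    patterns, explained = patterns[:, order], explained[order]
    day_scores = day_scores[:, order]
    # deterministic sign: orient each component toward its most strongly
    # loading day (first such day on ties), so the day pattern that defines
    # the component is its positive pole
    for c in range(n_comp):
        i = int(np.argmax(np.abs(day_scores[:, c])))
        if day_scores[i, c] < 0:
            patterns[:, c] *= -1.0
    return PCTModel(k=k, patterns=patterns, mean_=model_mean, scale_=model_scale,
                    explained=explained, lats=stack.lats.copy(), lons=stack.lons.copy())


def _labels_from_scores(scores: np.ndarray) -> np.ndarray:
    scores = np.atleast_2d(scores)
    comp = np.argmax(np.abs(scores), axis=1)  # first max wins: lowest index
    sign = scores[np.arange(len(scores)), comp]
    if np.any(sign == 0):
        warnings.warn("zero component score(s): tie broken to the positive class",
                      RuntimeWarning, stacklevel=3)
    labels = 2 * comp + 1 + (sign < 0).astype(int)  # +: 2c-1, -: 2c (1-based c)
    return labels.astype(int)


def assign_classes(model: PCTModel, stack: FieldStack) -> np.ndarray:
    """Assign each day of ``stack`` to a class 1..k.

    Each day goes to the component with the largest absolute score;
    positive scores take the odd class ``2c-1``, negative the even ``2c``.
    Ties in |score| break toward the lowest component index, and exact zero
    scores take the positive sign (with a warning).
    """
    if not stack.same_grid(model):
        raise ValueError("field stack grid does not match the fitted model grid")
    return _labels_from_scores(model.scores(stack.values))


def classify_new(model: PCTModel, field: np.ndarray) -> int:
    """Classify a single day's field (model grid, raw heights) to 1..k."""
    field = np.asarray(field, dtype=float).ravel()
    if field.size != model.patterns.shape[0]:
        raise ValueError(
            f"field has {field.size} gridpoints; model expects {model.patterns.shape[0]}")
    if not np.isfinite(field).all():
        raise ValueError("field values must all be finite")
    return int(_labels_from_scores(model.scores(field[None, :]))[0])


def best_label_agreement(truth: np.ndarray, predicted: np.ndarray, k: int) -> float:
    """Label agreement maximized over component permutations and sign swaps.

    Class identities are only defined up to the ordering of the fitted
    components and the sign convention within each component, so agreement
    between two labelings is evaluated over all relabelings that permute the
    ``k/2`` (odd, even) class pairs and optionally swap the two classes
    within a pair.
    """
    from itertools import permutations

    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape:
        raise ValueError("label arrays must have the same shape")
    n_comp = k // 2
    t_comp, t_sign = (truth - 1) // 2, (truth - 1) % 2
    p_comp, p_sign = (predicted - 1) // 2, (predicted - 1) % 2
    best = 0.0
    for perm in permutations(range(n_comp)):
        perm = np.asarray(perm)
        comp_match = perm[t_comp] == p_comp
        if not comp_match.any():
            continue
        # per-component optimal sign swap given this permutation
        agree = 0
        for c in range(n_comp):
            m = comp_match & (t_comp == c)
            same = int(np.sum(t_sign[m] == p_sign[m]))
            agree += max(same, int(m.sum()) - same)
        best = max(best, agree / truth.size)
    return best


# ---------------------------------------------------------------------------
# IO helpers

def write_fields_csv(stack: FieldStack, fields_path, grid_path) -> None:
    """Write a stack as a flat CSV matrix plus a JSON grid spec."""
    df = pd.DataFrame(stack.values)
    df.columns = [f"g{j}" for j in range(stack.n_grid)]
    if stack.dates is not None:
        df.insert(0, "date", stack.dates.strftime("%Y-%m-%d"))
    df.to_csv(fields_path, index=False, float_format="%.10g")
    Path(grid_path).write_text(json.dumps(
        {"lats": list(map(float, stack.lats)), "lons": list(map(float, stack.lons))},
        indent=1) + "\n", encoding="utf-8")


def read_fields_csv(fields_path, grid_path) -> FieldStack:
    """Read a stack written by :func:`write_fields_csv`."""
    grid = json.loads(Path(grid_path).read_text(encoding="utf-8"))
    df = pd.read_csv(fields_path)
    dates = None
    if "date" in df.columns:
        dates = pd.DatetimeIndex(pd.to_datetime(df.pop("date")))
    return FieldStack(values=df.to_numpy(dtype=float),
                      lats=np.asarray(grid["lats"]), lons=np.asarray(grid["lons"]),
                      dates=dates)


def read_fields_netcdf(path, var: str = "z500") -> FieldStack:
    """Read a (time, lat, lon) NetCDF file into a FieldStack.

    Classic NetCDF (v3) files are supported through xarray's scipy backend.
    """
    import xarray as xr

    ds = xr.open_dataset(path)
    da = ds[var]
    da = da.transpose("time", "lat", "lon")
    stack = FieldStack(
        values=da.values.reshape(da.sizes["time"], -1),
        lats=ds["lat"].values, lons=ds["lon"].values,
        dates=pd.DatetimeIndex(ds["time"].values))
    ds.close()
    return stack


def write_labels_csv(dates: pd.DatetimeIndex, labels: np.ndarray, path) -> None:
    pd.DataFrame({"date": pd.DatetimeIndex(dates).strftime("%Y-%m-%d"),
                  "wt": np.asarray(labels, dtype=int)}).to_csv(path, index=False)


def read_labels_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    df["wt"] = df["wt"].astype(int)
    return df
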