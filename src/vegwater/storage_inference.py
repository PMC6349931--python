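"""Inference of vegetation-accessible water storage.

Greenness (NDVI) and water storage are reduced to monthly anomalies by
subtracting each calendar month's climatological mean.  Storage is
integrated over five nested depth classes — surface water only, the top
soil layer, top+shallow, top+shallow+deep, and the whole column including
groundwater.  The class whose anomalies best rank-correlate with future
greenness anomalies (lagged Spearman rho over the subsequent 1..12 months)
is the apparent vegetation-accessible storage; its 98th percentile over the
record is the storage capacity in mm, and the number of consecutive months
from lag 1 with rho above a threshold (default 0.6) is the skilful forecast
lead time.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

#: nested integration depth classes, shallow to deep.
DEPTH_CLASSES = ("SURFACE", "TOP", "TOP_SHALLOW", "TOP_SHALLOW_DEEP", "ALL")

_CLASS_STORES = {
    "SURFACE": ("surface_water",),
    "TOP": ("s_top",),
    "TOP_SHALLOW": ("s_top", "s_shallow"),
    "TOP_SHALLOW_DEEP": ("s_top", "s_shallow", "s_deep"),
    "ALL": ("s_top", "s_shallow", "s_deep", "groundwater"),
}


def integrate_storage(states: pd.DataFrame, depth_class: str) -> pd.Series:
    """Sum the stores belonging to a depth class (daily series, mm)."""
    if depth_class not in _CLASS_STORES:
        raise ValueError(f"unknown depth class {depth_class!r}")
    return states[list(_CLASS_STORES[depth_class])].sum(axis=1)


def monthly_mean(daily: pd.Series) -> pd.Series:
    """Calendar-month means of a daily series, PeriodIndex('M')."""
    s = daily.copy()
    s.index = pd.DatetimeIndex(s.index).to_period("M")
    return s.groupby(level=0).mean()


def monthly_anomalies(series: pd.Series, exclude_months=None):
    """Split a monthly series into seasonal climatology and anomalies.

    climatology[m] is the mean over non-excluded occurrences of calendar
    month m; anomaly = value - climatology[month].  By construction the mean
    anomaly of each calendar month over non-excluded data is zero.

    Returns (climatology: ndarray of 12 values indexed month-1, anomalies:
    Series aligned with the input).
    """
    if len(series) < 24:
        raise ValueError("need at least 24 monthly values")
    idx = series.index
    if not isinstance(idx, pd.PeriodIndex):
        idx = pd.DatetimeIndex(idx).to_period("M")
        series = pd.Series(series.to_numpy(), index=idx)
    excl = set(exclude_months) if exclude_months is not None else set()
    excl = {pd.Period(e, freq="M") for e in excl}
    train = series[~series.index.isin(excl)]
    clim = np.full(12, np.nan)
    for m in range(1, 13):
        vals = train[train.index.month == m].dropna()
        if len(vals) == 0:
            raise ValueError(f"calendar month {m} entirely excluded or missing")
        clim[m - 1] = vals.mean()
    anom = series - clim[series.index.month - 1]
    return clim, anom


def lagged_spearman(x: pd.Series, y: pd.Series, lag: int,
                    min_overlap: int = 12) -> float:
    """Spearman rho of (x_t, y_{t+lag}); ties averaged, NaN pairs dropped.

    Returns NaN if either series has zero rank variance over the overlap.
    Raises if the overlap after shifting is shorter than ``min_overlap``.
    """
    x = pd.Series(x)
    y = pd.Series(y)
    if isinstance(x.index, (pd.PeriodIndex, pd.DatetimeIndex)):
        xs = x.copy()
        ys = y.copy()
        if isinstance(xs.index, pd.DatetimeIndex):
            xs.index = xs.index.to_period("M")
        if isinstance(ys.index, pd.DatetimeIndex):
            ys.index = ys.index.to_period("M")
        ys.index = ys.index - lag  # align y_{t+lag} with x_t
        joined = pd.concat([xs, ys], axis=1, join="inner").dropna()
        xv, yv = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    else:
        xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
        if lag > 0:
            xa, ya = xa[:-lag or None], ya[lag:]
        keep = np.isfinite(xa) & np.isfinite(ya)
        xv, yv = xa[keep], ya[keep]
    if len(xv) < min_overlap:
        raise ValueError(f"overlap {len(xv)} too short (need >= {min_overlap})")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return float("nan")
    rho = stats.spearmanr(xv, yv).statistic
    return float(rho)


@dataclasses.dataclass
class GreennessSeries:
    """Monthly NDVI with its seasonal climatology and anomalies."""

    values: pd.Series
    climatology: np.ndarray
    anomalies: pd.Series

    @classmethod
    def from_values(cls, values: pd.Series, exclude_months=None):
        clim, anom = monthly_anomalies(values, exclude_months)
        v = values.copy()
        if not isinstance(v.index, pd.PeriodIndex):
            v.index = pd.DatetimeIndex(v.index).to_period("M")
        return cls(values=v, climatology=clim, anomalies=anom)


@dataclasses.dataclass
class IntegratedStorageSeries:
    """Monthly storage (absolute, mm) and anomalies per depth class."""

    monthly: pd.DataFrame     # columns = DEPTH_CLASSES
    anomalies: pd.DataFrame

    @classmethod
    def from_states(cls, states: pd.DataFrame):
        monthly = pd.DataFrame(
            {z: monthly_mean(integrate_storage(states, z))
             for z in DEPTH_CLASSES})
        anors = {}
        for z in DEPTH_CLASSES:
            _, anors[z] = monthly_anomalies(monthly[z])
        return cls(monthly=monthly, anomalies=pd.DataFrame(anors))


@dataclasses.dataclass
class AccessibleStorageResult:
    """Per-pixel accessible-storage inference outcome."""

    depth_class: str | None          # None when not responsive to water
    responsive: bool
    profile: pd.DataFrame            # rho, index=depth class, columns=lag 1..12
    capacity_mm: float
    lead_time: int


def select_accessible_depth(storage: IntegratedStorageSeries,
                            greenness: GreennessSeries,
                            max_lag: int = 12,
                            min_rho: float = 0.3):
    """Pick the depth class whose storage anomalies best predict greenness.

    Score per class = max over lags 1..max_lag of Spearman rho between the
    class's storage anomaly at month t and the greenness anomaly at month
    t+lag.  Ties break toward the shallower class.  A pixel whose best rho
    is below ``min_rho`` (or undefined) is flagged as not responsive to
    water availability.

    Returns (depth_class or None, profile DataFrame).
    """
    lags = range(1, max_lag + 1)
    prof = pd.DataFrame(index=list(DEPTH_CLASSES), columns=list(lags),
                        dtype=float)
    for z in DEPTH_CLASSES:
        for lag in lags:
            prof.loc[z, lag] = lagged_spearman(storage.anomalies[z],
                                               greenness.anomalies, lag)
    scores = prof.max(axis=1)
    if scores.isna().all() or scores.max(skipna=True) < min_rho:
        return None, prof
    best = float(scores.max(skipna=True))
    # first (shallowest) class attaining the best score
    z_star = next(z for z in DEPTH_CLASSES if scores[z] == best)
    return z_star, prof


def storage_capacity(series, percentile: float = 98.0,
                     min_values: int = 50) -> float:
    """Percentile of the accessible-storage series (mm), linear interpolation."""
    a = np.asarray(series, dtype=float)
    a = a[np.isfinite(a)]
    if a.size < min_values:
        raise ValueError(f"need >= {min_values} values, got {a.size}")
    return float(np.percentile(a, percentile, method="linear"))


def skilful_lead_time(profile, threshold: float = 0.6) -> int:
    """Consecutive months from lag 1 with rho strictly above threshold.

    0 means skill only for the current month.  NaNs end the run.
    """
    a = np.asarray(profile, dtype=float)
    n = 0
    for rho in a:
        if np.isfinite(rho) and rho > threshold:
            n += 1
        else:
            break
    return n


def infer_pixel(states: pd.DataFrame, greenness_values: pd.Series,
                max_lag: int = 12, min_rho: float = 0.3,
                threshold: float = 0.6,
                percentile: float = 98.0) -> AccessibleStorageResult:
    """Full accessible-storage inference for one pixel."""
    storage = IntegratedStorageSeries.from_states(states)
    greenness = GreennessSeries.from_values(greenness_values)
    z_star, prof = select_accessible_depth(storage, greenness, max_lag, min_rho)
    if z_star is None:
        return AccessibleStorageResult(None, False, prof,
                                       float("nan"), 0)
    cap = storage_capacity(storage.monthly[z_star]
                           if len(storage.monthly) >= 50
                           else integrate_storage(states, z_star),
                           percentile)
    lead = skilful_lead_time(prof.loc[z_star].to_numpy(), threshold)
    return AccessibleStorageResult(z_star, True, prof, cap, lead)
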