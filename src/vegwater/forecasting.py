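"""Statistical greenness forecasting and hindcast skill evaluation.

The deterministic forecast of the greenness anomaly t months ahead is a
linear combination of the current greenness anomaly (unit coefficient) and
the current anomaly of accessible storage S_z:

    dV_t = dV_t0 + b1 * S_z,t0 + b2

with b1 (NDVI per mm) and b2 (NDVI) fitted by least squares per pixel and
lead.  Baselines: persistence (dV_t = dV_t0), climatology (monthly-mean
NDVI from training data), and the same linear model driven by alternative
predictors (antecedent precipitation index, open-loop model storage,
near-surface or column-total observations).

Skill is evaluated by a 3-segment hindcast: the record is split into three
contiguous segments; each segment is forecast with coefficients and
climatologies fitted on the other two only, and the pooled held-out
absolute-greenness forecasts are scored with Spearman rank correlation
against the observations.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import signal, stats


@dataclasses.dataclass
class ForecastModel:
    """Fitted coefficients of the anomaly forecast at one lead."""

    lead: int
    beta1: float        # NDVI per mm
    beta2: float        # NDVI
    n_train: int
    degenerate: bool = False    # constant predictor: persistence + intercept

    def __post_init__(self):
        if not (np.isfinite(self.beta1) and np.isfinite(self.beta2)):
            raise ValueError("non-finite forecast coefficients")
        if not 1 <= self.lead <= 12:
            raise ValueError("lead must lie in 1..12")


def fit_forecast_model(dv: pd.Series, s: pd.Series, lead: int,
                       min_train: int = 12) -> ForecastModel:
    """Least-squares fit of (dV_{t+lead} - dV_t) on S_t with intercept.

    The persistence term enters with a fixed unit coefficient, so only the
    storage slope b1 and intercept b2 are estimated.  A constant storage
    predictor degenerates to persistence-plus-intercept (with a warning).
    """
    dv = pd.Series(dv)
    s = pd.Series(s)
    target = dv.copy()
    target.index = target.index - lead     # dV_{t+lead} aligned on t
    frame = pd.concat({"dv0": dv, "s0": s, "dvt": target}, axis=1,
                      join="inner").dropna()
    if len(frame) < min_train:
        raise ValueError(f"need >= {min_train} training triplets, "
                         f"got {len(frame)}")
    y = (frame["dvt"] - frame["dv0"]).to_numpy()
    x = frame["s0"].to_numpy()
    if np.ptp(x) == 0:
        warnings.warn("constant storage predictor: falling back to "
                      "persistence plus intercept")
        return ForecastModel(lead, 0.0, float(y.mean()), len(frame),
                             degenerate=True)
    A = np.column_stack([x, np.ones_like(x)])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return ForecastModel(lead, float(beta[0]), float(beta[1]), len(frame))


def forecast_anomaly(model: ForecastModel, dv0, s0):
    """dV at lead months ahead from the current anomalies."""
    return dv0 + model.beta1 * np.asarray(s0) + model.beta2


def forecast_greenness(model: ForecastModel, dv0, s0, climatology,
                       target_month: int):
    """Absolute NDVI forecast: anomaly forecast + climatology, clipped."""
    clim = np.asarray(climatology, dtype=float)[target_month - 1]
    return float(np.clip(forecast_anomaly(model, dv0, s0) + clim, 0.0, 1.0))


def persistence_forecast(dv0):
    """Persistence: the next months keep the current anomaly."""
    return dv0


def climatology_forecast(history: pd.Series, target_month: int,
                         exclude=None) -> float:
    """Mean of available observations of the target calendar month."""
    h = pd.Series(history)
    if not isinstance(h.index, pd.PeriodIndex):
        h.index = pd.DatetimeIndex(h.index).to_period("M")
    if exclude is not None:
        excl = {pd.Period(e, freq="M") for e in exclude}
        h = h[~h.index.isin(excl)]
    vals = h[h.index.month == target_month].dropna()
    if len(vals) == 0:
        raise ValueError(f"no history for calendar month {target_month}")
    return float(vals.mean())


def api_index(precip, decay: float = 0.9) -> np.ndarray:
    """Antecedent precipitation index: API_t = decay * API_{t-1} + P_t."""
    if not 0.0 < decay < 1.0:
        raise ValueError("decay must lie in (0, 1)")
    p = np.asarray(precip, dtype=float)
    if (p < 0).any():
        raise ValueError("precipitation must be >= 0")
    # linear recursion y_t = P_t + k y_{t-1}  (API_0 = 0)
    return signal.lfilter([1.0], [1.0, -decay], p)


def monthly_api(precip: pd.Series, decay: float = 0.9) -> pd.Series:
    """Daily API sampled at each month's last day, PeriodIndex('M')."""
    api = pd.Series(api_index(precip.to_numpy(), decay), index=precip.index)
    per = pd.DatetimeIndex(api.index).to_period("M")
    out = api.groupby(per).last()
    return out


def forecast_skill(forecast, observed) -> float:
    """Spearman rho between pooled forecasts and observations."""
    f = np.asarray(forecast, dtype=float)
    o = np.asarray(observed, dtype=float)
    keep = np.isfinite(f) & np.isfinite(o)
    f, o = f[keep], o[keep]
    if len(f) < 3 or np.ptp(f) == 0 or np.ptp(o) == 0:
        return float("nan")
    return float(stats.spearmanr(f, o).statistic)


def _segments(n: int, n_segments: int):
    """Contiguous index segments; trailing months go to the last segment."""
    base = n // n_segments
    if base < 12:
        raise ValueError("each hindcast segment needs >= 12 months")
    bounds = [i * base for i in range(n_segments)] + [n]
    return [np.arange(bounds[i], bounds[i + 1]) for i in range(n_segments)]


def _train_climatology(values: pd.Series, train_mask: np.ndarray) -> np.ndarray:
    clim = np.full(12, np.nan)
    months = values.index.month
    v = values.to_numpy()
    for m in range(1, 13):
        sel = train_mask & (months == m) & np.isfinite(v)
        if not sel.any():
            raise ValueError(f"calendar month {m} absent from training data")
        clim[m - 1] = v[sel].mean()
    return clim


@dataclasses.dataclass
class SkillResult:
    """Hindcast skill per method and lead, plus pooled predictions."""

    skill: pd.DataFrame          # columns: method, lead, rho, n
    details: dict | None = None  # per (lead, segment): fitted models, clim
    predictions: dict | None = None  # (method, lead) -> (forecasts, observed)


def hindcast_evaluate(greenness: pd.Series, predictors: dict,
                      leads=(1, 2, 3), n_segments: int = 3,
                      return_details: bool = False,
                      return_predictions: bool = False) -> SkillResult:
    """Three-segment hindcast of monthly greenness.

    ``predictors`` maps method name -> monthly predictor series (raw level;
    anomalised per fold against the training climatology).  Persistence and
    climatology baselines are always evaluated.  For each fold the model is
    fitted on pairs whose start and target months both lie in the training
    segments, and evaluated on targets inside the held-out segment.
    """
    g = pd.Series(greenness)
    if not isinstance(g.index, pd.PeriodIndex):
        g.index = pd.DatetimeIndex(g.index).to_period("M")
    n = len(g)
    segs = _segments(n, n_segments)
    methods = ["persistence", "climatology"] + list(predictors)
    pooled = {(m, lead): ([], []) for m in methods for lead in leads}
    details = {}

    for si, seg in enumerate(segs):
        train_mask = np.ones(n, dtype=bool)
        train_mask[seg] = False
        g_clim = _train_climatology(g, train_mask)
        dv = g.to_numpy() - g_clim[g.index.month - 1]
        pred_anoms = {}
        for name, series in predictors.items():
            s = pd.Series(series)
            if not isinstance(s.index, pd.PeriodIndex):
                s.index = pd.DatetimeIndex(s.index).to_period("M")
            s = s.reindex(g.index)
            p_clim = _train_climatology(s, train_mask)
            pred_anoms[name] = s.to_numpy() - p_clim[s.index.month - 1]

        for lead in leads:
            t0 = np.arange(n - lead)
            tt = t0 + lead
            eval_sel = ~train_mask[tt]
            obs_eval = g.to_numpy()[tt[eval_sel]]
            target_month = g.index.month[tt[eval_sel]]
            clim_eval = g_clim[target_month - 1]
            dv0_eval = dv[t0[eval_sel]]

            fc = {"persistence": np.clip(dv0_eval + clim_eval, 0.0, 1.0),
                  "climatology": np.clip(clim_eval, 0.0, 1.0)}
            for name in predictors:
                s_anom = pred_anoms[name]
                dv_fit = pd.Series(dv, index=g.index)
                s_fit = pd.Series(s_anom, index=g.index)
                # restrict fitting to training pairs
                dv_train = dv_fit.copy()
                dv_train[~train_mask] = np.nan
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = fit_forecast_model(dv_train, s_fit, lead)
                anoms = forecast_anomaly(model, dv0_eval,
                                         s_anom[t0[eval_sel]])
                fc[name] = np.clip(anoms + clim_eval, 0.0, 1.0)
                details[(lead, si, name)] = model
            details[(lead, si, "climatology")] = g_clim
            for m in methods:
                pooled[(m, lead)][0].extend(fc[m])
                pooled[(m, lead)][1].extend(obs_eval)

    rows = []
    for (m, lead), (f, o) in pooled.items():
        rows.append({"method": m, "lead": lead,
                     "rho": forecast_skill(f, o), "n": len(f)})
    skill = pd.DataFrame(rows).sort_values(["lead", "method"]).reset_index(drop=True)
    preds_out = ({k: (np.asarray(v[0]), np.asarray(v[1]))
                  for k, v in pooled.items()} if return_predictions else None)
    return SkillResult(skill=skill,
                       details=details if return_details else None,
                       predictions=preds_out)


def best_ndvi_baseline(skill: pd.DataFrame) -> pd.DataFrame:
    """Per lead, the better of the two NDVI-only baselines."""
    base = skill[skill["method"].isin(["persistence", "climatology"])]
    out = base.groupby("lead")["rho"].max().reset_index()
    out["method"] = "best_ndvi_baseline"
    return out
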