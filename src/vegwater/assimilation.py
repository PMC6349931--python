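"""Ensemble Kalman Smoother assimilation of contrasting water observations.

Three observation kinds constrain the column model: the 8-day surface-water
fraction through simple nudging with a high gain; daily near-surface soil
water and the single monthly column-total observation through a perturbed-
observation Ensemble Kalman Smoother with a fixed 1-month window.

Within each calendar-month window the state vector stacks the daily values
of the three soil layers and groundwater for every day of the month
(4 x days), so the month's observations update *all* days of the month via
the ensemble sample cross-covariance — the smoother character that lets a
single monthly column observation, whose operator is the temporal mean of
the daily column totals, be partitioned over depth and time.  Model
uncertainty comes from an ensemble (default 100 members) generated by
perturbing precipitation, air temperature and radiation.

Surface water is excluded from the update vector (it is handled by
nudging) but is included in the predicted column total.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .climate import pet_penman_monteith
from .synthetic import ObservationSet, surface_fraction_inverse
from .water_balance import STORES, ColumnParams, ColumnState, step_arrays

logger = logging.getLogger(__name__)

_UPD_STORES = ("s_top", "s_shallow", "s_deep", "groundwater")


@dataclasses.dataclass(frozen=True)
class PerturbationParams:
    """Forcing-perturbation magnitudes for ensemble generation.

    precip_lognorm_sd: sigma of the mean-one lognormal factor on daily
    precipitation; tair_sd: additive Gaussian sd (degC); rad_frac_sd: sd of
    the mean-one truncated-Gaussian factor on radiation.
    """

    precip_lognorm_sd: float = 0.3
    tair_sd: float = 1.0
    rad_frac_sd: float = 0.1


@dataclasses.dataclass(frozen=True)
class AssimilationOptions:
    n_members: int = 100
    nudge_gain: float = 0.9
    sw_fraction_scale: float = 20.0
    perturbation: PerturbationParams = PerturbationParams()
    rel_humidity: float = 0.6
    inflation: float = 1.0      # multiplicative anomaly inflation before update
    update: bool = True         # False -> open-loop ensemble


@dataclasses.dataclass
class EnsembleWindow:
    """One calendar-month window of member trajectories.

    states has shape (n_days, n_members, 5) ordered as STORES.
    """

    month: pd.Period
    dates: pd.DatetimeIndex
    states: np.ndarray

    def __post_init__(self):
        if self.states.shape[1] < 2:
            raise ValueError("need at least 2 ensemble members")
        if self.states.shape[0] != len(self.dates):
            raise ValueError("member length must match window dates")


@dataclasses.dataclass
class ObservationVector:
    """Stacked in-window observations with diagonal error covariance."""

    values: np.ndarray
    variances: np.ndarray
    day_index: np.ndarray       # day-of-window of each near-surface record
    has_column: bool            # last element is the monthly column obs

    def __post_init__(self):
        if (self.variances <= 0).any():
            raise ValueError("observation error variances must be > 0")


def perturb_forcings(forcings: pd.DataFrame, n_members: int,
                     perturbation: PerturbationParams, seed) -> dict:
    """Member forcing fields as arrays of shape (n_days, n_members).

    Precipitation is multiplied by mean-one lognormal factors, temperature
    shifted by Gaussian noise, radiation multiplied by mean-one Gaussian
    factors floored at zero.
    """
    if n_members < 2:
        raise ValueError("need at least 2 ensemble members")
    rng = np.random.default_rng(seed)
    n = len(forcings)
    s = perturbation.precip_lognorm_sd
    if s > 0:
        pf = rng.lognormal(-0.5 * s ** 2, s, size=(n, n_members))
    else:
        pf = np.ones((n, n_members))
    dt = rng.normal(0.0, perturbation.tair_sd, size=(n, n_members)) \
        if perturbation.tair_sd > 0 else np.zeros((n, n_members))
    rf = np.maximum(rng.normal(1.0, perturbation.rad_frac_sd,
                               size=(n, n_members)), 0.0) \
        if perturbation.rad_frac_sd > 0 else np.ones((n, n_members))
    return {
        "precip": forcings["precip"].to_numpy()[:, None] * pf,
        "tair": forcings["tair"].to_numpy()[:, None] + dt,
        "rad": forcings["rad"].to_numpy()[:, None] * rf,
        "wind": np.repeat(forcings["wind"].to_numpy()[:, None], n_members, 1),
        "pressure": np.repeat(forcings["pressure"].to_numpy()[:, None],
                              n_members, 1),
        "snow": np.repeat(forcings["snow"].to_numpy()[:, None], n_members, 1),
    }


def observation_operator(member_states, day_index, include_column=True):
    """Predicted observations for one member (or a whole ensemble).

    member_states: array (n_days, ..., 5); near-surface prediction for an
    observed day is that day's s_top; the column prediction is the
    calendar-month mean of the daily column totals (surface water included).
    """
    st = np.asarray(member_states, dtype=float)
    day_index = np.asarray(day_index, dtype=int)
    if len(day_index) and (day_index.min() < 0 or day_index.max() >= st.shape[0]):
        raise ValueError("observation dated outside the window")
    parts = [st[day_index, ..., 1]]  # s_top
    if include_column:
        parts.append(st[..., :5].sum(axis=-1).mean(axis=0, keepdims=True))
    return np.concatenate(parts, axis=0)


def enkf_update(states: np.ndarray, pred_obs: np.ndarray,
                obs: np.ndarray, obs_var: np.ndarray,
                rng: np.random.Generator,
                inflation: float = 1.0) -> np.ndarray:
    """Stochastic (perturbed-observation) ensemble Kalman update.

    states: (n_state, N); pred_obs: (n_obs, N); obs, obs_var: (n_obs,).
    Returns the updated state matrix x + K (y + eps - H x) with the Kalman
    gain K built from ensemble sample covariances.
    """
    X = np.asarray(states, dtype=float)
    Y = np.asarray(pred_obs, dtype=float)
    n = X.shape[1]
    if n < 2:
        raise ValueError("need at least 2 ensemble members")
    obs = np.asarray(obs, dtype=float)
    obs_var = np.asarray(obs_var, dtype=float)
    A = (X - X.mean(axis=1, keepdims=True)) * inflation
    D = (Y - Y.mean(axis=1, keepdims=True)) * inflation
    cxy = A @ D.T / (n - 1)
    cyy = D @ D.T / (n - 1) + np.diag(obs_var)
    cond = np.linalg.cond(cyy)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "singular innovation covariance; increase the ensemble size or "
            "use covariance inflation")
    eps = rng.normal(0.0, 1.0, size=(len(obs), n)) * np.sqrt(obs_var)[:, None]
    innov = obs[:, None] + eps - Y
    return X + cxy @ np.linalg.solve(cyy, innov)


def enks_update(window: EnsembleWindow, observations: ObservationVector,
                seed, params: ColumnParams | None = None,
                inflation: float = 1.0):
    """EnKS update of a monthly window (all days, 4 sub-surface stores).

    Returns (updated window, increments) where increments is an array
    (n_days, 4) of ensemble-mean posterior-minus-prior changes (clipping to
    [0, capacity] included).
    """
    params = params or ColumnParams()
    if len(observations.values) < 1:
        raise ValueError("need at least one observation")
    nd, nm, _ = window.states.shape
    X = window.states[:, :, 1:5].transpose(0, 2, 1).reshape(nd * 4, nm)
    Y = observation_operator(window.states, observations.day_index,
                             include_column=observations.has_column)
    rng = np.random.default_rng(seed)
    Xa = enkf_update(X, Y, observations.values, observations.variances,
                     rng, inflation)
    Xa = Xa.reshape(nd, 4, nm)
    caps = np.array([params.cap_top, params.cap_shallow, params.cap_deep,
                     np.inf])
    clipped = np.clip(Xa, 0.0, caps[None, :, None])
    clip_mass = float(np.abs(clipped - Xa).mean(axis=2).sum())
    if clip_mass > 0:
        logger.debug("EnKS clipping moved %.3g mm (window %s)",
                     clip_mass, window.month)
    prior_mean = window.states[:, :, 1:5].mean(axis=1)
    new_states = window.states.copy()
    new_states[:, :, 1:5] = clipped.transpose(0, 2, 1)
    increments = new_states[:, :, 1:5].mean(axis=1) - prior_mean
    return EnsembleWindow(window.month, window.dates, new_states), increments


def nudge_surface_water(state: ColumnState, observed_fraction: float,
                        gain: float, scale: float = 20.0) -> ColumnState:
    """Relax ponded surface water toward an observed areal water fraction."""
    if not 0.0 <= observed_fraction <= 1.0:
        raise ValueError("observed fraction must lie in [0, 1]")
    if not 0.0 <= gain <= 1.0:
        raise ValueError("gain must lie in [0, 1]")
    target = float(surface_fraction_inverse(observed_fraction, scale))
    new = dataclasses.replace(state)
    new.surface_water = (1.0 - gain) * state.surface_water + gain * target
    return new


@dataclasses.dataclass
class AssimilationResult:
    """Posterior-mean analysis with uncertainty and bookkeeping.

    analysis/spread: daily DataFrames over STORES;
    fluxes: daily ensemble-mean flux ledger;
    increments: daily applied mass changes (long format: date, store,
    increment_mm, source in {enks, nudge}) such that
    delta(total) = (water_in - aet - sw_loss - discharge) + sum(increments)
    holds each day to float precision.
    """

    analysis: pd.DataFrame
    spread: pd.DataFrame
    fluxes: pd.DataFrame
    increments: pd.DataFrame


def assimilation_closure(result: AssimilationResult) -> float:
    """Max daily closure error of analysis = physics + ledgered increments."""
    totals = result.analysis[list(STORES)].sum(axis=1).to_numpy()
    f = result.fluxes
    net = (f["water_in"] - f["aet"] - f["sw_loss"] - f["discharge"]).to_numpy()
    inc = np.zeros(len(f))
    if len(result.increments):
        per_day = result.increments.groupby("date")["increment_mm"].sum()
        pos = f.index.get_indexer(pd.DatetimeIndex(per_day.index))
        inc[pos] = per_day.to_numpy()
    err = np.abs(np.diff(totals) - net - inc)
    return float(err.max()) if len(err) else 0.0


def assimilate_series(forcings: pd.DataFrame, observations: ObservationSet,
                      params: ColumnParams | None = None,
                      options: AssimilationOptions | None = None,
                      seed=0,
                      initial: ColumnState | None = None) -> AssimilationResult:
    """Run the month-by-month assimilation over a daily forcing record.

    Each calendar month: propagate all members with individually perturbed
    forcings (PET recomputed per member from the perturbed temperature and
    radiation), nudge surface water at 8-day observation times, then apply
    the EnKS update with that month's near-surface and column observations.
    The end-of-month posterior member states initialise the next window.
    With ``options.update=False`` or an empty observation set this is the
    open-loop ensemble run.
    """
    params = params or ColumnParams()
    options = options or AssimilationOptions()
    observations.validate()
    initial = initial or ColumnState(s_top=5.0, s_shallow=50.0,
                                     s_deep=200.0, groundwater=100.0)
    dates = pd.DatetimeIndex(forcings.index)
    months = dates.to_period("M")

    near = observations.near_surface
    near_dates = pd.DatetimeIndex(near["date"]) if len(near) else pd.DatetimeIndex([])
    if len(near_dates) and ((near_dates < dates[0]).any()
                            or (near_dates > dates[-1]).any()):
        raise ValueError("near-surface observation outside the forcing span")
    col = observations.column_total
    sw = observations.surface_fraction
    sw_by_date = ({pd.Timestamp(d): (v, s) for d, v, s in
                   zip(sw["date"], sw["value"], sw["error_sd"])}
                  if len(sw) else {})

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    month_list = months.unique()
    month_seeds = ss.spawn(len(month_list))

    N = options.n_members
    S = np.repeat(initial.as_array()[None, :], N, axis=0)   # (N, 5)
    ana_rows, sd_rows, flux_rows, inc_records = [], [], [], []
    out_index = []

    for mi, month in enumerate(month_list):
        sel = months == month
        mdates = dates[sel]
        mf = forcings.loc[sel]
        child = month_seeds[mi].spawn(3)
        pert = perturb_forcings(mf, N, options.perturbation, child[0])
        pet = pet_penman_monteith(pert["tair"], pert["rad"], pert["wind"],
                                  pert["pressure"],
                                  rel_humidity=options.rel_humidity)
        nd = len(mdates)
        daily = np.empty((nd, N, 5))
        prior_means = np.empty((nd, 5))
        for j in range(nd):
            S, fl = step_arrays(S, pert["precip"][j], pert["snow"][j],
                                pet[j], params)
            flux_rows.append([fl[c].mean() for c in
                              ("water_in", "aet", "sw_loss", "discharge")])
            d = mdates[j]
            if d in sw_by_date and options.update:
                frac, _ = sw_by_date[d]
                target = float(surface_fraction_inverse(
                    frac, options.sw_fraction_scale))
                g = options.nudge_gain
                before = S[:, 0].mean()
                S[:, 0] = (1.0 - g) * S[:, 0] + g * target
                inc_records.append((d, "surface_water",
                                    S[:, 0].mean() - before, "nudge"))
            daily[j] = S
            out_index.append(d)

        window = EnsembleWindow(month, mdates, daily)
        # gather this month's EnKS observations
        obs_vals, obs_var, day_idx = [], [], []
        if len(near):
            inm = near_dates.to_period("M") == month
            for d, v, s_ in zip(near_dates[inm], near["value"][inm],
                                near["error_sd"][inm]):
                day_idx.append(int((d - mdates[0]).days))
                obs_vals.append(v)
                obs_var.append(s_ ** 2)
        has_col = False
        if len(col):
            hit = col[col["month"] == month]
            if len(hit):
                has_col = True
                obs_vals.append(float(hit["value"].iloc[0]))
                obs_var.append(float(hit["error_sd"].iloc[0]) ** 2)

        if options.update and len(obs_vals):
            ov = ObservationVector(np.asarray(obs_vals, dtype=float),
                                   np.asarray(obs_var, dtype=float),
                                   np.asarray(day_idx, dtype=int), has_col)
            window, incs = enks_update(window, ov, child[1], params,
                                       options.inflation)
            daily = window.states
            # ledger per-day applied delta: difference of the cumulative
            # increment between consecutive days of the window
            prev = np.zeros(4)
            for j in range(nd):
                delta = incs[j] - prev
                prev = incs[j]
                for k, store in enumerate(_UPD_STORES):
                    if delta[k] != 0.0:
                        inc_records.append((mdates[j], store, delta[k], "enks"))
            S = daily[-1].copy()
        else:
            if options.update and not len(obs_vals):
                logger.info("no EnKS observations in %s: open-loop month", month)
            S = daily[-1].copy()

        ana_rows.append(daily.mean(axis=1))
        sd_rows.append(daily.std(axis=1, ddof=1))

    analysis = pd.DataFrame(np.concatenate(ana_rows), columns=list(STORES),
                            index=pd.DatetimeIndex(out_index))
    spread = pd.DataFrame(np.concatenate(sd_rows), columns=list(STORES),
                          index=analysis.index)
    fluxes = pd.DataFrame(flux_rows,
                          columns=["water_in", "aet", "sw_loss", "discharge"],
                          index=analysis.index)
    increments = pd.DataFrame(inc_records,
                              columns=["date", "store", "increment_mm",
                                       "source"])
    # prepend the initial state so analysis has n+1 rows like run_simulation
    init_row = pd.DataFrame([initial.as_array()], columns=list(STORES),
                            index=pd.DatetimeIndex(
                                [dates[0] - pd.Timedelta(days=1)]))
    analysis = pd.concat([init_row, analysis])
    return AssimilationResult(analysis=analysis, spread=spread,
                              fluxes=fluxes, increments=increments)
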