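"""Layered bucket model of the land water column for one pixel.

Five stores, all in mm equivalent water thickness: ponded surface water,
three unsaturated soil layers — top (0-5 cm), shallow root zone (5-100 cm),
deep root zone (1-10 m) — and unconfined groundwater.  The model is a
deliberately simple surrogate for a full ecohydrological land-surface
scheme: it keeps the properties the downstream analysis relies on (distinct
storage time constants per layer, exact mass balance, vertical contrast
between fast near-surface and slow deep stores) and drops everything else
(energy balance, canopy dynamics, snowpack).

Daily explicit time stepping with a fixed flux order: infiltration -> ET ->
drainage -> capillary rise -> groundwater discharge.  The order matters at
the second decimal and is part of the model definition.

All step arithmetic is carried out on numpy arrays so that an ensemble of
columns can be advanced in one call; the scalar dataclass API wraps the
array core.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

STORES = ("surface_water", "s_top", "s_shallow", "s_deep", "groundwater")
SOIL_STORES = ("s_top", "s_shallow", "s_deep")

#: flux ledger columns produced by every step (mm/day).
#: water_in enters the column; aet, sw_loss and discharge leave it.
FLUX_COLUMNS = ("water_in", "aet", "sw_loss", "discharge",
                "drain_to_gw", "capillary_rise")


@dataclasses.dataclass(frozen=True)
class ColumnParams:
    """Parameters of the layered column.

    Capacities are mm; rate coefficients are day^-1 fractions of the donor
    store; ET half-saturations are mm; root-access fractions are
    dimensionless in [0, 1], one triple per vegetation class over
    (top, shallow, deep).
    """

    cap_top: float = 25.0
    cap_shallow: float = 250.0
    cap_deep: float = 800.0
    drain_top: float = 0.2
    drain_shallow: float = 0.02
    drain_deep: float = 0.004
    capillary_rise: float = 0.001
    gw_discharge: float = 0.002
    et_half_sat: tuple = (10.0, 80.0, 300.0)
    access_shallow_veg: tuple = (0.6, 0.4, 0.0)
    access_deep_veg: tuple = (0.2, 0.4, 0.4)
    cover_shallow: float = 0.5
    cover_deep: float = 0.5
    sw_runoff_frac: float = 0.05
    sw_decay: float = 0.2

    def __post_init__(self):
        rates = {"drain_top": self.drain_top, "drain_shallow": self.drain_shallow,
                 "drain_deep": self.drain_deep, "capillary_rise": self.capillary_rise,
                 "gw_discharge": self.gw_discharge, "sw_decay": self.sw_decay}
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name, v in [("cap_top", self.cap_top), ("cap_shallow", self.cap_shallow),
                        ("cap_deep", self.cap_deep)]:
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name, triple in [("access_shallow_veg", self.access_shallow_veg),
                             ("access_deep_veg", self.access_deep_veg)]:
            if any(not 0.0 <= f <= 1.0 for f in triple):
                raise ValueError(f"{name} fractions must be in [0, 1]")
        if not 0.0 <= self.sw_runoff_frac <= 1.0:
            raise ValueError("sw_runoff_frac must be in [0, 1]")

    @property
    def soil_caps(self) -> np.ndarray:
        return np.array([self.cap_top, self.cap_shallow, self.cap_deep])

    @property
    def access(self) -> np.ndarray:
        """Cover-weighted effective root access per soil layer."""
        a = (self.cover_shallow * np.asarray(self.access_shallow_veg)
             + self.cover_deep * np.asarray(self.access_deep_veg))
        return a


@dataclasses.dataclass
class ColumnState:
    """Water stored in each compartment of the column (mm)."""

    surface_water: float = 0.0
    s_top: float = 0.0
    s_shallow: float = 0.0
    s_deep: float = 0.0
    groundwater: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.surface_water, self.s_top, self.s_shallow,
                         self.s_deep, self.groundwater])

    @classmethod
    def from_array(cls, a) -> "ColumnState":
        return cls(*(float(x) for x in np.asarray(a)))

    def validate(self, params: ColumnParams | None = None) -> None:
        for name in STORES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite state field: {name}={v}")
            if v < 0:
                raise ValueError(f"negative state field: {name}={v}")
        if params is not None:
            for name, cap in zip(SOIL_STORES, params.soil_caps):
                if getattr(self, name) > cap * (1 + 1e-12):
                    raise ValueError(f"{name} exceeds capacity {cap}")


@dataclasses.dataclass(frozen=True)
class ForcingDay:
    """One day of meteorological forcing.

    precipitation and snowfall_rate in mm/day, air_temperature in degC,
    net_radiation in MJ m-2 day-1, wind_speed in m/s, surface_pressure
    in kPa.
    """

    precipitation: float
    air_temperature: float
    net_radiation: float
    wind_speed: float
    surface_pressure: float
    snowfall_rate: float = 0.0

    def validate(self) -> None:
        for name in ("precipitation", "air_temperature", "net_radiation",
                     "wind_speed", "surface_pressure", "snowfall_rate"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite forcing field: {name}={v}")
        if self.precipitation < 0:
            raise ValueError("precipitation must be >= 0")
        if self.net_radiation < 0:
            raise ValueError("net_radiation must be >= 0")


FORCING_COLUMNS = ("precip", "tair", "rad", "wind", "pressure", "snow")


def forcings_frame(days: Sequence[ForcingDay], index=None) -> pd.DataFrame:
    """Stack ForcingDay records into the canonical forcing DataFrame."""
    df = pd.DataFrame(
        {"precip": [d.precipitation for d in days],
         "tair": [d.air_temperature for d in days],
         "rad": [d.net_radiation for d in days],
         "wind": [d.wind_speed for d in days],
         "pressure": [d.surface_pressure for d in days],
         "snow": [d.snowfall_rate for d in days]})
    if index is not None:
        df.index = pd.Index(index)
    return df


def step_arrays(states: np.ndarray, precip, snow, pet, params: ColumnParams):
    """Advance column states one day.

    Parameters
    ----------
    states : array (..., 5)
        Batched states ordered as STORES.
    precip, snow, pet : scalars or arrays broadcastable to ``states[..., 0]``
        mm/day.
    params : ColumnParams

    Returns
    -------
    (next_states, fluxes)
        fluxes is a dict of arrays keyed by FLUX_COLUMNS.  The per-step
        balance ``delta(total) == water_in - aet - sw_loss - discharge``
        holds to float round-off by construction.
    """
    states = np.asarray(states, dtype=float)
    sw, top, sh, dp, gw = (states[..., i].copy() for i in range(5))
    precip = np.asarray(precip, dtype=float)
    pet = np.asarray(pet, dtype=float)
    caps = params.soil_caps

    # infiltration: snow is treated as rain (dryland focus, no snowpack)
    water_in = precip + np.asarray(snow, dtype=float)
    sw = sw + params.sw_runoff_frac * water_in
    infil = (1.0 - params.sw_runoff_frac) * water_in
    take = np.minimum(infil, caps[0] - top)
    top = top + take
    infil = infil - take
    take = np.minimum(infil, caps[1] - sh)
    sh = sh + take
    infil = infil - take
    take = np.minimum(infil, caps[2] - dp)
    dp = dp + take
    gw = gw + (infil - take)  # saturation excess recharges groundwater

    # transpiration + soil evaporation, saturating per layer, capped by
    # both demand (pet) and supply
    acc = params.access
    half = np.asarray(params.et_half_sat)
    layers = [top, sh, dp]
    demand = [pet * acc[i] * layers[i] / (layers[i] + half[i]) for i in range(3)]
    demand = [np.minimum(d, s) for d, s in zip(demand, layers)]
    total_demand = demand[0] + demand[1] + demand[2]
    scale = np.where(total_demand > pet,
                     np.divide(pet, total_demand,
                               out=np.ones_like(total_demand + pet * 0.0),
                               where=total_demand > 0),
                     1.0)
    aet_layers = [d * scale for d in demand]
    top = top - aet_layers[0]
    sh = sh - aet_layers[1]
    dp = dp - aet_layers[2]
    aet = aet_layers[0] + aet_layers[1] + aet_layers[2]

    # drainage cascade, top-down, linear in the (updated) donor store
    d1 = params.drain_top * top
    top = top - d1
    take = np.minimum(d1, caps[1] - sh)
    sh = sh + take
    spill = d1 - take  # shallow layer full: passes straight down
    d2 = params.drain_shallow * sh + spill
    sh = sh - params.drain_shallow * sh
    take = np.minimum(d2, caps[2] - dp)
    dp = dp + take
    spill = d2 - take
    d3 = params.drain_deep * dp + spill
    dp = dp - params.drain_deep * dp
    gw = gw + d3

    # open-water loss (evaporation + lateral outflow lumped)
    sw_loss = params.sw_decay * sw
    sw = sw - sw_loss

    # capillary rise, capped by the deep-layer deficit
    cr = np.minimum(params.capillary_rise * gw, caps[2] - dp)
    cr = np.maximum(cr, 0.0)
    gw = gw - cr
    dp = dp + cr

    # groundwater discharge to streams
    q = params.gw_discharge * gw
    gw = gw - q

    nxt = np.stack([sw, top, sh, dp, gw], axis=-1)
    fluxes = {"water_in": water_in + np.zeros_like(sw),
              "aet": aet, "sw_loss": sw_loss, "discharge": q,
              "drain_to_gw": d3, "capillary_rise": cr}
    return nxt, fluxes


def step_day(state: ColumnState, forcing: ForcingDay, pet: float,
             params: ColumnParams) -> ColumnState:
    """One daily step of the column model (scalar API)."""
    state.validate(params)
    forcing.validate()
    if not np.isfinite(pet):
        raise ValueError(f"non-finite pet={pet}")
    if pet < 0:
        raise ValueError("pet must be >= 0")
    nxt, _ = step_arrays(state.as_array(), forcing.precipitation,
                         forcing.snowfall_rate, pet, params)
    return ColumnState.from_array(nxt)


def run_simulation(initial: ColumnState, forcings, pet_series,
                   params: ColumnParams):
    """Run the column model over a forcing sequence.

    ``forcings`` may be a canonical forcing DataFrame or a sequence of
    ForcingDay.  Returns ``(states, fluxes)`` where ``states`` is a
    DataFrame of length n+1 (row 0 is the initial state) and ``fluxes`` a
    DataFrame of length n with FLUX_COLUMNS.
    """
    if not isinstance(forcings, pd.DataFrame):
        forcings = forcings_frame(list(forcings))
    pet_series = np.asarray(pet_series, dtype=float)
    if len(forcings) != len(pet_series):
        raise ValueError(
            f"forcings ({len(forcings)}) and pet_series ({len(pet_series)}) "
            "must have the same length")
    if len(forcings) < 1:
        raise ValueError("need at least one forcing day")
    for col in ("precip", "tair", "rad", "snow"):
        bad = ~np.isfinite(forcings[col].to_numpy())
        if bad.any():
            raise ValueError(f"non-finite forcing field: {col} at row "
                             f"{int(np.argmax(bad))}")
    if (forcings["precip"].to_numpy() < 0).any():
        raise ValueError("precipitation must be >= 0")
    if not np.isfinite(pet_series).all() or (pet_series < 0).any():
        raise ValueError("pet_series must be finite and >= 0")
    initial.validate(params)

    n = len(forcings)
    states = np.empty((n + 1, 5))
    states[0] = initial.as_array()
    flux_rows = np.empty((n, len(FLUX_COLUMNS)))
    precip = forcings["precip"].to_numpy()
    snow = forcings["snow"].to_numpy()
    s = states[0]
    for t in range(n):
        s, fl = step_arrays(s, precip[t], snow[t], pet_series[t], params)
        states[t + 1] = s
        flux_rows[t] = [fl[c] for c in FLUX_COLUMNS]
    idx = forcings.index
    states_df = pd.DataFrame(states, columns=list(STORES))
    fluxes_df = pd.DataFrame(flux_rows, columns=list(FLUX_COLUMNS))
    if isinstance(idx, pd.DatetimeIndex):
        # row 0 is the state one day before the first forcing day
        states_df.index = pd.DatetimeIndex([idx[0] - pd.Timedelta(days=1)]).append(idx)
        fluxes_df.index = idx
    return states_df, fluxes_df


def total_water_storage(state) -> float:
    """Column total (mm): surface water + three soil layers + groundwater."""
    if isinstance(state, ColumnState):
        state.validate()
        return float(state.as_array().sum())
    a = np.asarray(state, dtype=float)
    return a[..., :5].sum(axis=-1)


def check_mass_balance(states, fluxes) -> float:
    """Max absolute closure error (mm) of a trajectory against its ledger.

    ``states`` has one more row than ``fluxes``; per step the balance is
    delta(total) = water_in - aet - sw_loss - discharge.
    """
    if isinstance(states, pd.DataFrame):
        totals = states[list(STORES)].to_numpy().sum(axis=1)
    else:
        totals = np.asarray(states, dtype=float).sum(axis=-1)
    if len(totals) != len(fluxes) + 1:
        raise ValueError("trajectory length must equal ledger length + 1")
    f = fluxes
    net = (np.asarray(f["water_in"]) - np.asarray(f["aet"])
           - np.asarray(f["sw_loss"]) - np.asarray(f["discharge"]))
    err = np.abs(np.diff(totals) - net)
    return float(err.max()) if len(err) else 0.0
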