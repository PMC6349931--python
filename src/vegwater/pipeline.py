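"""End-to-end orchestration: simulate -> assimilate -> infer -> forecast ->
evaluate, with reproducible configuration and file-based stage handoff.

Every stage writes CSV outputs plus a manifest (config hash, seed, package
version) into the run directory; a stage reads only what earlier stages
wrote (or regenerates deterministic inputs from the seed), so a run is
idempotent and byte-identical for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assimilation import (AssimilationOptions, AssimilationResult,
                           PerturbationParams, assimilate_series)
from .climate import classify_pixel
from .forecasting import hindcast_evaluate, monthly_api
from .io_utils import read_table, write_table
from .storage_inference import (GreennessSeries, IntegratedStorageSeries,
                                infer_pixel, monthly_anomalies, monthly_mean,
                                integrate_storage)
from .synthetic import (ObservationSet, SyntheticConfig, generate_truth,
                        model_forcings, pet_series, simulate_observations)
from .water_balance import STORES, ColumnParams

logger = logging.getLogger(__name__)

STAGES = ("simulate", "assimilate", "infer", "forecast", "evaluate")
_STAGE_NEEDS = {"simulate": None, "assimilate": "simulate",
                "infer": "assimilate", "forecast": "infer",
                "evaluate": "forecast"}


@dataclasses.dataclass(frozen=True)
class InferenceOptions:
    threshold: float = 0.6
    percentile: float = 98.0
    min_rho: float = 0.3
    max_lag: int = 12


@dataclasses.dataclass(frozen=True)
class ForecastOptions:
    leads: tuple = (1, 2, 3, 4, 5, 6)
    n_segments: int = 3
    api_decay: float = 0.9
    skill_threshold: float = 0.6


@dataclasses.dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    synthetic: SyntheticConfig = SyntheticConfig()
    params: ColumnParams = ColumnParams()
    assimilation: AssimilationOptions = AssimilationOptions()
    inference: InferenceOptions = InferenceOptions()
    forecast: ForecastOptions = ForecastOptions()

    def replace_seed(self, seed: int) -> "RunConfig":
        syn = dataclasses.replace(self.synthetic, seed=seed)
        return dataclasses.replace(self, seed=seed, synthetic=syn)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        def build(klass, key):
            sub = raw.get(key, {})
            fields = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - fields
            if unknown:
                raise ValueError(f"unknown {key} options: {sorted(unknown)}")
            for name in ("leads", "et_half_sat", "access_shallow_veg",
                         "access_deep_veg", "nearsurface_sd_range",
                         "column_sd_range", "hidden_depth_classes"):
                if name in sub and sub[name] is not None:
                    sub[name] = tuple(sub[name])
            return klass(**sub)
        assim_raw = dict(raw.get("assimilation", {}))
        pert = assim_raw.pop("perturbation", None)
        assim = AssimilationOptions(**assim_raw) if pert is None else \
            AssimilationOptions(perturbation=PerturbationParams(**pert),
                                **assim_raw)
        return cls(seed=raw.get("seed", 0),
                   synthetic=build(SyntheticConfig, "synthetic"),
                   params=build(ColumnParams, "params"),
                   assimilation=assim,
                   inference=build(InferenceOptions, "inference"),
                   forecast=build(ForecastOptions, "forecast"))


def _states_to_long(states: pd.DataFrame, pixel: int) -> pd.DataFrame:
    df = states.reset_index(names="date").melt(
        id_vars="date", var_name="variable", value_name="value_mm")
    df["pixel_id"] = pixel
    return df[["date", "pixel_id", "variable", "value_mm"]]


def _long_to_states(df: pd.DataFrame, pixel: int) -> pd.DataFrame:
    sub = df[df["pixel_id"] == pixel]
    wide = sub.pivot(index="date", columns="variable", values="value_mm")
    wide.index = pd.DatetimeIndex(wide.index)
    return wide[list(STORES)].sort_index()


def _write_manifest(outdir: Path, stage: str, config: RunConfig) -> None:
    manifest = {"stage": stage, "seed": config.seed,
                "config_hash": config.config_hash(),
                "vegwater_version": __version__,
                "config": config.to_dict()}
    (outdir / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=list))


def _require(outdir: Path, stage: str) -> None:
    need = _STAGE_NEEDS[stage]
    if need and not (outdir / f"manifest_{need}.json").exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs outputs of stage '{need}': "
            f"run '{need}' first")


def stage_simulate(config: RunConfig, outdir: Path) -> None:
    syn = config.synthetic
    truth_rows, green_rows = [], []
    near_rows, col_rows, frac_rows, mask_rows = [], [], [], []
    for px in range(syn.n_pixels):
        truth = generate_truth(syn, px, config.params)
        truth_rows.append(_states_to_long(truth.states, px))
        g = truth.greenness
        green_rows.append(pd.DataFrame(
            {"month": g.index.astype(str), "pixel_id": px,
             "value": g.to_numpy()}))
        obs = simulate_observations(truth.states, syn, px)
        for frame, rows in ((obs.near_surface, near_rows),
                            (obs.column_total, col_rows),
                            (obs.surface_fraction, frac_rows)):
            f = frame.copy()
            f["pixel_id"] = px
            rows.append(f)
        pet_m = monthly_mean(pd.Series(truth.pet, index=truth.forcings.index))
        p_m = monthly_mean(truth.forcings["precip"])
        pet_clim = np.array([pet_m[pet_m.index.month == m].mean()
                             for m in range(1, 13)])
        p_clim = np.array([p_m[p_m.index.month == m].mean()
                           for m in range(1, 13)])
        ci = classify_pixel(pet_clim, p_clim, g.to_numpy())
        mask_rows.append({"pixel_id": px, "dryness": ci.dryness,
                          "max_ndvi": ci.max_ndvi,
                          "in_domain": ci.in_domain})
    write_table(pd.concat(truth_rows), outdir / "truth_states.csv",
                "states_long")
    write_table(pd.concat(green_rows), outdir / "greenness.csv", "greenness")
    for name, rows, schema in (
            ("obs_near_surface", near_rows, "obs_near_surface"),
            ("obs_column_total", col_rows, "obs_column_total"),
            ("obs_surface_fraction", frac_rows, "obs_surface_fraction")):
        df = pd.concat(rows)
        df = df.rename(columns={"month": "month"})
        write_table(df, outdir / f"{name}.csv", schema)
    write_table(pd.DataFrame(mask_rows), outdir / "climate_mask.csv", "mask")
    _write_manifest(outdir, "simulate", config)


def _load_observations(outdir: Path, pixel: int) -> ObservationSet:
    near = read_table(outdir / "obs_near_surface.csv", "obs_near_surface")
    col = read_table(outdir / "obs_column_total.csv", "obs_column_total")
    frac = read_table(outdir / "obs_surface_fraction.csv",
                      "obs_surface_fraction")
    near = near[near["pixel_id"] == pixel][["date", "value", "error_sd"]]
    col = col[col["pixel_id"] == pixel][["month", "value", "error_sd"]].copy()
    col["month"] = pd.DatetimeIndex(col["month"]).to_period("M")
    frac = frac[frac["pixel_id"] == pixel][["date", "value", "error_sd"]]
    return ObservationSet(near.reset_index(drop=True),
                          col.reset_index(drop=True),
                          frac.reset_index(drop=True))


def run_pixel_assimilation(config: RunConfig, pixel: int,
                           observations: ObservationSet):
    """DA analysis and open-loop runs for one pixel (degraded forcings)."""
    syn = config.synthetic
    truth_forcings = None
    from .synthetic import generate_forcings
    truth_forcings = generate_forcings(syn, pixel)
    forc = model_forcings(truth_forcings, syn, pixel)
    seed_da, seed_ol = np.random.SeedSequence(
        [syn.seed, pixel, 23]).spawn(2)
    da = assimilate_series(forc, observations, config.params,
                           config.assimilation, seed=seed_da)
    ol_opts = dataclasses.replace(config.assimilation, update=False)
    ol = assimilate_series(forc, ObservationSet.empty(), config.params,
                           ol_opts, seed=seed_ol)
    return da, ol


def stage_assimilate(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "assimilate")
    ana_rows, ol_rows, inc_rows = [], [], []
    for px in range(config.synthetic.n_pixels):
        obs = _load_observations(outdir, px)
        da, ol = run_pixel_assimilation(config, px, obs)
        ana_rows.append(_states_to_long(da.analysis, px))
        ol_rows.append(_states_to_long(ol.analysis, px))
        inc = da.increments.copy()
        inc["pixel_id"] = px
        inc_rows.append(inc)
    write_table(pd.concat(ana_rows), outdir / "analysis_states.csv",
                "states_long")
    write_table(pd.concat(ol_rows), outdir / "openloop_states.csv",
                "states_long")
    write_table(pd.concat(inc_rows), outdir / "increments.csv", "increments")
    _write_manifest(outdir, "assimilate", config)


def stage_infer(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "infer")
    ana = read_table(outdir / "analysis_states.csv", "states_long")
    green = read_table(outdir / "greenness.csv", "greenness")
    rows = []
    opts = config.inference
    for px in range(config.synthetic.n_pixels):
        states = _long_to_states(ana, px)
        g = green[green["pixel_id"] == px]
        gs = pd.Series(g["value"].to_numpy(),
                       index=pd.DatetimeIndex(g["month"]).to_period("M"))
        res = infer_pixel(states, gs, opts.max_lag, opts.min_rho,
                          opts.threshold, opts.percentile)
        row = {"pixel_id": px,
               "depth_class": res.depth_class or "NONE",
               "responsive": res.responsive,
               "capacity_mm": res.capacity_mm,
               "lead_time_months": res.lead_time}
        prof = (res.profile.loc[res.depth_class]
                if res.depth_class else res.profile.max(axis=0))
        for lag in range(1, 13):
            row[f"rho_lag{lag}"] = prof[lag] if lag in prof.index else np.nan
        rows.append(row)
    write_table(pd.DataFrame(rows), outdir / "inference.csv", "inference")
    _write_manifest(outdir, "infer", config)


def _monthly_predictors(config: RunConfig, outdir: Path, pixel: int,
                        depth_class: str) -> dict:
    """Monthly predictor series per forecast method for one pixel."""
    from .synthetic import generate_forcings
    syn = config.synthetic
    ana = read_table(outdir / "analysis_states.csv", "states_long")
    ol = read_table(outdir / "openloop_states.csv", "states_long")
    near = read_table(outdir / "obs_near_surface.csv", "obs_near_surface")
    col = read_table(outdir / "obs_column_total.csv", "obs_column_total")
    a_states = _long_to_states(ana, pixel)
    o_states = _long_to_states(ol, pixel)
    z = depth_class if depth_class != "NONE" else "TOP_SHALLOW"
    preds = {
        "da_storage": monthly_mean(integrate_storage(a_states, z)),
        "openloop_storage": monthly_mean(integrate_storage(o_states, z)),
    }
    nearp = near[near["pixel_id"] == pixel]
    preds["obs_near_surface"] = monthly_mean(
        pd.Series(nearp["value"].to_numpy(),
                  index=pd.DatetimeIndex(nearp["date"])))
    colp = col[col["pixel_id"] == pixel]
    preds["obs_column_total"] = pd.Series(
        colp["value"].to_numpy(),
        index=pd.DatetimeIndex(colp["month"]).to_period("M"))
    forc = generate_forcings(syn, pixel)
    preds["api"] = monthly_api(forc["precip"], config.forecast.api_decay)
    return preds


def stage_forecast(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "forecast")
    inf = read_table(outdir / "inference.csv", "inference")
    green = read_table(outdir / "greenness.csv", "greenness")
    rows = []
    for px in range(config.synthetic.n_pixels):
        g = green[green["pixel_id"] == px]
        gs = pd.Series(g["value"].to_numpy(),
                       index=pd.DatetimeIndex(g["month"]).to_period("M"))
        z = inf.loc[inf["pixel_id"] == px, "depth_class"].iloc[0]
        preds = _monthly_predictors(config, outdir, px, z)
        res = hindcast_evaluate(gs, preds, leads=config.forecast.leads,
                                n_segments=config.forecast.n_segments)
        sk = res.skill.copy()
        sk["pixel_id"] = px
        rows.append(sk)
    write_table(pd.concat(rows), outdir / "skill.csv", "skill")
    _write_manifest(outdir, "forecast", config)


def stage_evaluate(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "evaluate")
    skill = read_table(outdir / "skill.csv", "skill")
    thr = config.forecast.skill_threshold
    rows = []
    for (method, lead), sub in skill.groupby(["method", "lead"]):
        frac = float((sub["rho"] > thr).mean())
        rows.append({"method": method, "lead": int(lead),
                     "skilful_fraction": frac, "n_pixels": len(sub)})
    write_table(pd.DataFrame(rows).sort_values(["lead", "method"]),
                outdir / "skill_summary.csv", "summary")
    _write_manifest(outdir, "evaluate", config)


_STAGE_FUNCS = {"simulate": stage_simulate, "assimilate": stage_assimilate,
                "infer": stage_infer, "forecast": stage_forecast,
                "evaluate": stage_evaluate}


def run_pipeline(config: RunConfig, outdir, stages=STAGES) -> Path:
    """Execute the requested stages in canonical order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage in stages:
            logger.info("running stage %s", stage)
            _STAGE_FUNCS[stage](config, outdir)
    return outdir
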