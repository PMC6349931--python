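# Methods

This note documents the models, the synthetic study conditions, and the
numerical and design choices behind `vegwater`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Column water balance

One pixel carries five stores (mm equivalent water thickness): ponded
surface water, soil layers at 0–5 cm (capacity 25 mm), 5–100 cm (250 mm)
and 1–10 m (800 mm), and unconfined groundwater (uncapped). The model is
a surrogate for a full ecohydrological scheme: it keeps distinct storage
time constants per layer, vertical contrast between fast and slow stores,
and exact mass accounting, and omits energy balance, canopy/biomass
dynamics, interception and snowpack (snowfall is folded into rain — the
target domain is drylands).

Daily explicit stepping in a fixed flux order (the order matters at the
second decimal and is part of the model definition):

1. **Infiltration**: a fixed fraction (default 0.05) of the day's water
   input is routed to surface water; the rest fills the soil layers in
   cascade top → shallow → deep, with saturation excess recharging
   groundwater.
2. **Evapotranspiration**: demand `pet · a_i · s_i/(s_i + h_i)` per layer
   — `a_i` the cover-weighted root-access fraction (two vegetation
   classes, shallow- and deep-rooted, enter only through these fractions),
   `h_i` a half-saturation constant (10/80/300 mm) — capped by supply and
   rescaled so total ET never exceeds PET.
3. **Drainage**: linear in the donor store (0.2/0.02/0.004 day⁻¹ top to
   deep), cascading top-down with spill past full receivers; deep drainage
   recharges groundwater.
4. **Capillary rise**: 0.001 day⁻¹ of groundwater, capped by the
   deep-layer deficit.
5. **Discharge**: 0.002 day⁻¹ of groundwater, plus a 0.2 day⁻¹ decay of
   surface water (lumped evaporation/outflow).

Per step, Δ(total storage) = input − ET − surface-water loss − discharge
holds to float round-off (measured ≈ 1e-13 mm; the contract in the tests
is 1e-6 mm). The layer capacities and coefficients are fixture choices
made once for qualitative realism — the resulting anomaly
autocorrelation time scales are roughly days (surface, top), weeks
(shallow), months (deep) and seasons (groundwater), which is what makes
the depth classes statistically distinguishable downstream. They are not
calibrated to any published model output.

PET is FAO-56 reference-crop Penman–Monteith. The forcing record carries
no humidity, so relative humidity is a configured constant (default 0.6).

## Synthetic truth and observations

The generator emulates a semi-arid pixel: seasonally modulated wet-day
occurrence (base probability 0.25 ± 0.15) with Gamma-distributed amounts
(shape 0.8, mean 8 mm on wet days, ~500 mm yr⁻¹), sinusoidal temperature
(22 ± 8 °C) and radiation (18 ± 6 MJ m⁻² day⁻¹) with Gaussian noise. Two
years of spin-up precede the 6-year study period (the length the
satellite-era analysis is built around); the study-period series is
identical whether or not spin-up is generated.

Monthly NDVI is constructed as
`clim[month] + a · S̃_z*(t − L) + ε`, clipped to [0, 1]: a seasonal
climatology (base 0.25, amplitude 0.10, peaking ~2 months after the rain),
plus a linear response to the monthly anomaly `S̃` of water storage
integrated over the pixel's hidden depth class `z*`, lagged by a response
lag `L` (default 1 month), plus Gaussian noise. The gain `a` is scaled so
the storage-driven term has a fixed sd (default 0.06 NDVI); the default
noise sd is 0.012 NDVI (20 % of the signal). Storage anomalies are formed
against the study-period climatology, the same convention the inference
stage uses. The generative model is exactly the structure the inference
assumes, so depth-class recovery is well-posed at low noise.

Observations: daily near-surface records are the top-layer storage plus
Gaussian noise (per-record sd drawn from 1–2 mm, 10 % random gaps);
monthly column records are the calendar-month mean of the daily column
total plus noise (sd 10–20 mm), one per complete month (partial trailing
months are dropped with a warning); 8-day surface-water records pass the
ponded store through a saturating transform `f = 1 − exp(−s/20 mm)` with
sd 0.02, clipped to [0, 1]. Not emulated: sensor footprints, orbital
geometry, the coarse spatial support of gravimetric products, or
spatially correlated errors — so passing tests demonstrate the
correctness of the inference chain, not its robustness to real-product
error structure.

The assimilating model is driven by a deliberately degraded forcing
product: daily precipitation multiplied by a 0.75 bias factor and
mean-one lognormal noise (σ = 0.6), temperature offset by +1 °C. A purely
multiplicative bias would leave rank-based skill nearly unchanged, so the
daily amount/timing noise is what creates the open-loop-vs-assimilation
contrast the twin experiments measure.

## Assimilation

Surface water is nudged toward the inverse-transformed 8-day fraction
with gain 0.9 (the gain is a configuration choice; only "high" is
specified by the problem). Near-surface and column observations enter a
perturbed-observation Ensemble Kalman Smoother with a fixed calendar-month
window: the state vector stacks daily (top, shallow, deep, groundwater)
over the month (4 × days), the observation operator selects the observed
day's top-layer storage and averages daily column totals (surface water
included in the total but excluded from the updated state), and the gain
is built from ensemble sample covariances with 100 members generated by
perturbing precipitation (mean-one lognormal, σ = 0.3), temperature
(±1 °C) and radiation (mean-one ±10 %, floored at 0); PET is recomputed
per member. Updated storages are clipped to [0, capacity]. No inflation
or localisation by default (single column, ≤ 31-day window); inflation is
available in configuration. End-of-month posterior members initialise the
next window.

Assimilation intentionally opens the physical budget; every applied
change (EnKS day-increments, nudging insertions, clipping mass) is
written to an increments ledger alongside the ensemble-mean flux ledger,
so the analysis-mean trajectory satisfies
Δ(total) = (input − ET − losses) + Σ(increments) each day to float
precision. `assimilation_closure` verifies this.

Known limitation: with an *already-perfect* model, the open-loop mean is
near-optimal for the slow stores and spurious ensemble covariances from
the heavily weighted daily observations can leave shallow/groundwater
RMSE at parity with open loop. The meaningful (and tested) contract is
improvement when model forcings err, which is the realistic regime.

## Accessible storage and forecasting

Five nested integrations discretise "depth": surface water only; top;
top+shallow; top+shallow+deep; all sub-surface stores including
groundwater. For each, monthly-mean storage anomalies are correlated with
greenness anomalies at lags 1–12 (Spearman, average ranks for ties,
pairwise deletion; overlaps below 12 months are an error; zero rank
variance yields a flagged missing value). The optimal depth maximises the
profile's max-over-lags score (ties break to the shallower class); pixels
whose best ρ is below 0.3 are flagged "less responsive to water".
Capacity is the 98th percentile (linear interpolation between order
statistics) of the monthly accessible-storage series; lead time counts
consecutive lags from lag 1 with ρ > 0.6 (contiguity chosen because the
lead-time notion is "how far ahead skill persists"; 0 means skill only
for the current month).

The forecast model `dV_t = dV_t0 + β₁ S_z,t0 + β₂` is fitted per pixel
and lead by least squares with the persistence coefficient fixed at 1
(the equation as stated); a constant predictor degenerates to
persistence-plus-intercept with a warning. The antecedent precipitation
index uses `API_t = 0.9·API_{t−1} + P_t` daily, sampled at month end
(a monthly variant is available). Hindcasts split the record into three
contiguous segments (trailing months join the last); each segment is
forecast with coefficients *and climatologies* (greenness and predictor)
estimated from the other two segments only, and pooled held-out absolute
forecasts (anomaly + training climatology, clipped to [0, 1]) are scored
with Spearman ρ against observations. Absolute-scale scoring is required
for the climatology baseline to be non-degenerate. The forecasts
themselves necessarily use the held-out month's own current anomaly
(that is what persistence means); leakage-freedom is defined — and
tested — as invariance of the fitted coefficients and training
climatology to held-out data.

## Validation experiments

Defined once in `vegwater.experiments`, used by both the acceptance tests
and `scripts/acceptance.py`:

- **Smoother exactness**: a 30-day AR(1) storage state (φ = 0.95, sd 10)
  observed every 2nd day (sd 3) plus one monthly-mean observation (sd 5);
  the EnKS update with 10⁴ members is compared with batch Gaussian
  conditioning on the analytic AR(1) covariance — an independent
  implementation algebraically equal to the exact fixed-interval smoother.
- **Depth recovery**: 50 pixels, 6 years, hidden classes cycling through
  all five; greenness noise at 20/50/100/200 % of signal sd with common
  random numbers (the truth run and unit noise vector are fixed per pixel,
  only the scale varies). Checked: ≥ 90 % recovery at 20 % noise and
  monotone degradation.
- **Mass closure**: 10⁴ random-forcing steps from random admissible
  states, plus a 3-year assimilation run closed with its increments
  ledger; both must close to 1e-6 mm.
- **Skill ordering / twin experiment**: 20 pixels over 6 years whose
  vegetation draws on the deeper classes (top+shallow and deeper) with a
  3-month response lag — the perennial-dryland regime in which
  multi-month forecasts are possible at all. With a 1-month lag the
  current greenness anomaly already carries the storage information and
  every variant of the forecast equation collapses to a near-monotone
  transform of persistence; the seasonal response lag is where storage
  knowledge pays. Checked: pooled lead-3 ρ of the assimilated-storage
  forecast exceeds open-loop, API, persistence and climatology; and
  assimilation RMSE beats open loop for shallow, deep and groundwater
  stores.
- **Determinism**: two full pipeline runs with one seed must produce
  byte-identical CSVs (2 pixels, 3 years, 20 members — determinism is a
  plumbing property, not a statistical one).

Problem sizes were chosen so the whole suite completes in roughly a
minute and a half on one CPU while keeping Monte-Carlo error comfortably
inside the asserted margins.

## Other design notes

- All randomness flows from `numpy` `SeedSequence` spawning keyed on
  (seed, pixel, stream), so any stage can regenerate its inputs
  deterministically instead of reading them from disk.
- CSV is the canonical interchange (long format, ISO-8601 dates,
  shortest-repr floats re-read with round-trip parsing); a gridded
  NetCDF-style writer was considered and dropped as redundant for
  single-column analyses.
- Surface-water inflow is not part of the problem statement anywhere; the
  fixed runoff fraction plus linear decay is the simplest form that gives
  the 8-day fraction observations something to constrain.
- The dryness index (fraction of climatological months with PET strictly
  exceeding precipitation, ties excluded) and the max-NDVI ≥ 0.25
  vegetation rule jointly define the analysis domain
  (dryness > 0.3 AND vegetated).
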