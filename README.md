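# vegwater

Forecasting dryland vegetation condition months ahead from the water
stored below the surface.

In water-limited ecosystems, the greenness of vegetation (NDVI) responds
to the moisture it can actually reach — which may be ponded surface water,
the top few centimetres of soil, the shallow or deep root zone, or
groundwater. Satellites observe water over contrasting vertical domains:
daily near-surface (0–5 cm) soil moisture, monthly changes in the total
water column, and the areal fraction of open surface water every 8 days.
None of them observes the root zone directly. `vegwater` implements, as a
single-column, fully synthetic and testable pipeline, the inference chain
that combines them:

1. **Water balance** — a layered bucket model (surface water; 0–5 cm,
   5–100 cm and 1–10 m soil layers; unconfined groundwater) with exact
   per-step mass closure.
2. **Data assimilation** — surface-water nudging plus an Ensemble Kalman
   Smoother with a fixed one-month window: the state vector stacks the
   daily sub-surface storages of the whole month, so the single monthly
   column-total observation and all daily near-surface observations update
   every day of the month through ensemble cross-covariances (100 members,
   generated by perturbing precipitation, temperature and radiation).
3. **Accessible-storage inference** — monthly anomalies of storage
   integrated over nested depth classes are rank-correlated with
   subsequent greenness anomalies (lagged Spearman ρ, lags 1–12); the
   best-correlated depth defines the vegetation-accessible storage, its
   98th percentile the capacity in mm, and the run of lags with ρ > 0.6
   the skilful forecast lead time.
4. **Forecasting** — the deterministic anomaly forecast

   dV<sub>t</sub> = dV<sub>t₀</sub> + β₁·S<sub>z,t₀</sub> + β₂

   (current greenness anomaly with unit coefficient, plus the accessible
   storage anomaly) evaluated against persistence, monthly climatology, an
   antecedent precipitation index (decay 0.9), open-loop model storage and
   raw-observation predictors in a three-segment hindcast, scored with
   Spearman ρ on held-out absolute greenness.

Because real satellite products are deliberately out of scope, a
synthetic-data module generates the truth twin: meteorological forcings,
a truth water-balance run, NDVI whose anomalies are driven by the storage
over a hidden per-pixel depth class, and noisy observations of all three
satellite kinds. Every downstream claim is tested against this known
truth.

## Worked example

```python
import numpy as np
from vegwater import (SyntheticConfig, generate_truth, simulate_observations,
                      assimilate_series, infer_pixel)
from vegwater.synthetic import model_forcings

cfg = SyntheticConfig(n_pixels=1, n_years=6, seed=42,
                      hidden_depth_classes=("TOP_SHALLOW_DEEP",))
truth = generate_truth(cfg, pixel=0)
obs = simulate_observations(truth.states, cfg, pixel=0)
analysis = assimilate_series(model_forcings(truth.forcings, cfg, 0), obs,
                             seed=1)
result = infer_pixel(analysis.analysis.iloc[1:], truth.greenness)
print(f"hidden class:    {truth.hidden_class}")
print(f"inferred class:  {result.depth_class}")
print(f"capacity (mm):   {result.capacity_mm:.1f}")
print(f"lead time (mo):  {result.lead_time}")
```

prints

```
hidden class:    TOP_SHALLOW_DEEP
inferred class:  TOP_SHALLOW_DEEP
capacity (mm):   343.0
lead time (mo):  2
```

The pixel's vegetation was constructed to respond to water integrated
over the top three soil layers; the assimilation analysis (run with a
deliberately degraded precipitation product) recovers that depth class,
estimates a 343 mm storage capacity (the 98th percentile of the monthly
accessible-storage series), and finds that the lagged rank correlation
stays above 0.6 for 2 months ahead.

The same chain is available from the shell:

```sh
vegwater all --seed 1 --outdir runs/demo
```

which writes per-stage CSV outputs (truth states, observations,
assimilation analysis and increments ledger, per-pixel inference results,
skill tables and a skill summary) plus a manifest with the config hash.

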