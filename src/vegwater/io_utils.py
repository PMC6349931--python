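"""CSV interchange with schema checking.

All stage outputs are long-format CSV with ISO-8601 dates; values round-trip
at full double precision (pandas' shortest-repr float formatting).
"""

from __future__ import annotations

import pandas as pd

SCHEMAS = {
    "states_long": ["date", "pixel_id", "variable", "value_mm"],
    "greenness": ["month", "pixel_id", "value"],
    "obs_near_surface": ["date", "pixel_id", "value", "error_sd"],
    "obs_column_total": ["month", "pixel_id", "value", "error_sd"],
    "obs_surface_fraction": ["date", "pixel_id", "value", "error_sd"],
    "increments": ["date", "pixel_id", "store", "increment_mm", "source"],
    "inference": ["pixel_id", "depth_class", "responsive", "capacity_mm",
                  "lead_time_months"] + [f"rho_lag{i}" for i in range(1, 13)],
    "skill": ["pixel_id", "method", "lead", "rho", "n"],
    "summary": ["method", "lead", "skilful_fraction", "n_pixels"],
    "mask": ["pixel_id", "dryness", "max_ndvi", "in_domain"],
}

_DATE_COLUMNS = {"date": "%Y-%m-%d", "month": "%Y-%m"}


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    cols = SCHEMAS[schema]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"schema {schema}: missing columns {sorted(missing)}")
    out = df[cols].copy()
    for c, fmt in _DATE_COLUMNS.items():
        if c in out.columns and len(out):
            out[c] = pd.to_datetime(out[c].astype(str)).dt.strftime(fmt)
    out.to_csv(path, index=False)


def read_table(path, schema: str) -> pd.DataFrame:
    cols = SCHEMAS[schema]
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"schema {schema}: missing columns {sorted(missing)} "
                         f"in {path}")
    for c, fmt in _DATE_COLUMNS.items():
        if c in df.columns and len(df):
            try:
                df[c] = pd.to_datetime(df[c], format=fmt)
            except (ValueError, TypeError) as exc:
                bad = None
                for i, v in enumerate(df[c]):
                    try:
                        pd.to_datetime(str(v), format=fmt)
                    except (ValueError, TypeError):
                        bad = i
                        break
                raise ValueError(
                    f"malformed {c} value at row {bad} of {path}") from exc
    return df
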