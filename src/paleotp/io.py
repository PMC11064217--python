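"""Tabular readers/writers for core profiles and TP series.

All files are comma-delimited UTF-8 CSV with a header row and exact
column names.  Core profile schema: ``depth_cm, age_ce, p_conc_mg_g,
mar_g_cm2_yr``.  Series schema: ``when, value`` plus one ``core_<id>``
column per core when per-core records are present; per-core cells may
be empty where a core does not cover a grid year.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import CoreProfile, TimeSeries, TPSeries, ValidationError

__all__ = [
    "read_core_csv",
    "write_core_csv",
    "read_series_csv",
    "write_series_csv",
    "SchemaError",
]

CORE_COLUMNS = ("depth_cm", "age_ce", "p_conc_mg_g", "mar_g_cm2_yr")


class SchemaError(ValueError):
    """A file is missing required columns or contains missing values."""


def read_core_csv(path, core_id: str, collection_year: float) -> CoreProfile:
    """Read one dated core profile; rows are sorted by depth before validation."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if df[list(CORE_COLUMNS)].isna().any().any():
        rows = df.index[df[list(CORE_COLUMNS)].isna().any(axis=1)].tolist()
        raise SchemaError(f"{path}: missing values in required columns at rows {rows}")
    df = df.sort_values("depth_cm", kind="mergesort").reset_index(drop=True)
    return CoreProfile(
        core_id=core_id,
        collection_year=float(collection_year),
        depth_cm=df["depth_cm"].to_numpy(float),
        age_ce=df["age_ce"].to_numpy(float),
        p_conc=df["p_conc_mg_g"].to_numpy(float),
        mar=df["mar_g_cm2_yr"].to_numpy(float),
    )


def write_core_csv(profile: CoreProfile, path) -> None:
    pd.DataFrame(
        {
            "depth_cm": profile.depth_cm,
            "age_ce": profile.age_ce,
            "p_conc_mg_g": profile.p_conc,
            "mar_g_cm2_yr": profile.mar,
        }
    ).to_csv(path, index=False, float_format="%.12g")


def write_series_csv(series: TPSeries | TimeSeries, path) -> None:
    """Write a series; TPSeries per-core columns are named ``core_<id>``.

    Per-core series must share the aggregate time grid (cells left empty
    where a core has no value).  Read-back reproduces values to 1e-9.
    """
    if isinstance(series, TimeSeries):
        df = pd.DataFrame({"when": series.when, "value": series.value})
    else:
        agg = series.aggregate
        df = pd.DataFrame({"when": agg.when, "value": agg.value})
        for cid, ts in series.per_core.items():
            col = np.full(len(agg), np.nan)
            idx = np.searchsorted(agg.when, ts.when)
            ok = (idx < len(agg)) & np.isclose(agg.when[np.minimum(idx, len(agg) - 1)], ts.when)
            if not np.all(ok):
                raise ValidationError(
                    f"per-core series {cid!r} has timestamps off the aggregate grid"
                )
            col[idx] = ts.value
            df[f"core_{cid}"] = col
    df.to_csv(path, index=False, float_format="%.12g")


def read_series_csv(path, label: str = "", method: str | None = None):
    """Read a series CSV.

    Returns a :class:`TimeSeries` (default) or, when ``method`` is given,
    a :class:`TPSeries` with any ``core_*`` columns as per-core records.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for c in ("when", "value"):
        if c not in df.columns:
            raise SchemaError(f"{path}: missing required column {c!r}")
    if df[["when", "value"]].isna().any().any():
        raise SchemaError(f"{path}: missing values in required columns")
    df = df.sort_values("when", kind="mergesort").reset_index(drop=True)
    agg = TimeSeries(label or path.stem, df["when"].to_numpy(float), df["value"].to_numpy(float))
    if method is None:
        return agg
    per_core: dict[str, TimeSeries] = {}
    for c in df.columns:
        if c.startswith("core_"):
            m = df[c].notna().to_numpy()
            per_core[c[len("core_"):]] = TimeSeries(
                f"{agg.label}:{c}", df["when"].to_numpy(float)[m], df[c].to_numpy(float)[m]
            )
    return TPSeries(method=method, aggregate=agg, per_core=per_core)
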