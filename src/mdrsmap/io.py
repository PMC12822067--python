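"""Readers and writers for the package's delimited text formats.

Abundance tables are taxa x samples with the taxon id in the first column
and ISO-8601 sample dates in the header; temperature series are two-column
CSVs (date, temp_C).  Writers and readers round-trip exactly.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_temperature",
    "write_temperature",
    "align_temperature",
]


def read_abundance_table(path) -> pd.DataFrame:
    """Read a taxa x dated-samples table (tab- or comma-delimited)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    try:
        dates = pd.to_datetime(df.columns, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable sample dates in header of {path}: {exc}") from exc
    df.columns = dates
    df = df.sort_index(axis=1)
    vals = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"non-finite abundance values in {path}")
    if (vals < 0).any():
        bad = df.index[(vals < 0).any(axis=1)][0]
        raise ValueError(f"negative abundance for taxon {bad!r} in {path}")
    return df


def write_abundance_table(table: pd.DataFrame, path, sep: str = "\t") -> None:
    out = table.copy()
    out.columns = pd.DatetimeIndex(out.columns).strftime("%Y-%m-%d")
    out.index.name = "taxon_id"
    out.to_csv(path, sep=sep)


def read_temperature(path) -> pd.Series:
    """Read a two-column (date, temp_C) CSV; duplicate dates are averaged."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"temperature file {path} must have two columns (date, temp_C)")
    try:
        dates = pd.to_datetime(df.iloc[:, 0], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable dates in {path}: {exc}") from exc
    s = pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=dates)
    s = s.groupby(level=0).mean().sort_index()
    s.name = "temp_C"
    return s


def write_temperature(series: pd.Series, path) -> None:
    out = pd.DataFrame(
        {"date": pd.DatetimeIndex(series.index).strftime("%Y-%m-%d"), "temp_C": series.to_numpy()}
    )
    out.to_csv(path, index=False)


def align_temperature(temps: pd.Series, dates: pd.DatetimeIndex) -> pd.Series:
    """Daily-complete temperature over the span of ``dates`` (forward-filled).

    Errors when the temperature record does not overlap the sample dates;
    logs how many missing days were filled.
    """
    dates = pd.DatetimeIndex(dates)
    if temps.index.max() < dates.min() or temps.index.min() > dates.max():
        raise ValueError("temperature record does not overlap the sample date range")
    full = pd.date_range(dates.min(), dates.max(), freq="D")
    aligned = temps.reindex(full)
    n_missing = int(aligned.isna().sum())
    if n_missing:
        logger.info("forward-filling %d missing temperature days", n_missing)
    aligned = aligned.ffill().bfill()
    return aligned
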