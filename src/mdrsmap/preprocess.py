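"""Reduce a raw taxa-by-time relative-abundance table to an analysis-ready matrix.

Three steps mirror standard practice for state-space reconstruction of
amplicon time series: (1) keep only the common taxa (detection and occupancy
criteria), (2) aggregate irregular sampling dates onto a fixed-interval bin
grid, (3) z-score every taxon so all series share the same magnitude.

Bins follow a half-open convention [start, start + width) anchored at the
first sample date.  Empty bins are filled by linear interpolation between
their flanking non-empty bins (ends held at the nearest value); the
``completeness`` flags record which bins actually contained a sample so that
interpolated bins can be excluded from skill scoring downstream.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedSeries",
    "filter_common_taxa",
    "select_bin_width",
    "bin_series",
    "bin_auxiliary",
    "standardize",
    "destandardize",
]


@dataclass
class BinnedSeries:
    """Taxa x bins matrix on a fixed-width date grid.

    ``scale_record`` is ``None`` for raw binned values and a DataFrame with
    per-taxon ``mean``/``sd`` columns after :func:`standardize`.
    """

    values: pd.DataFrame  # taxa x bin-start dates
    bin_width: int  # days
    completeness: np.ndarray  # bool per bin: had >= 1 sample
    scale_record: pd.DataFrame | None = None

    @property
    def bin_starts(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.values.columns)

    @property
    def taxon_ids(self) -> list:
        return list(self.values.index)

    @property
    def is_standardized(self) -> bool:
        return self.scale_record is not None


def filter_common_taxa(
    table: pd.DataFrame,
    detection: float = 0.001,
    occupancy: float = 0.5,
    detection_mode: str = "present_mean",
    annotations: pd.DataFrame | None = None,
    drop_unresolved: bool = False,
) -> pd.DataFrame:
    """Keep taxa passing the detection and occupancy criteria.

    A taxon is kept when (i) its mean relative abundance exceeds
    ``detection`` — by default the mean over samples where it is present
    (``detection_mode='present_mean'``; ``'overall_mean'`` averages over all
    samples) — and (ii) it is present (value > 0) in at least an
    ``occupancy`` fraction of samples.  Taxa flagged as taxonomically
    unresolved in ``annotations['resolved']`` are additionally dropped when
    ``drop_unresolved`` is set.
    """
    if not 0 <= detection < 1:
        raise ValueError("detection must be in [0, 1)")
    if not 0 < occupancy <= 1:
        raise ValueError("occupancy must be in (0, 1]")
    if detection_mode not in ("present_mean", "overall_mean"):
        raise ValueError(f"unknown detection_mode {detection_mode!r}")
    present = table > 0
    presence_frac = present.mean(axis=1)
    if detection_mode == "present_mean":
        mean_ab = table.where(present).mean(axis=1).fillna(0.0)
    else:
        mean_ab = table.mean(axis=1)
    pass_detection = mean_ab > detection
    pass_occupancy = presence_frac >= occupancy
    keep = pass_detection & pass_occupancy
    if drop_unresolved:
        if annotations is None or "resolved" not in annotations:
            raise ValueError("drop_unresolved requires annotations with a 'resolved' column")
        keep &= annotations["resolved"].reindex(table.index).fillna(False).astype(bool)
    if not keep.any():
        raise ValueError(
            "no taxa pass the common-taxon criteria "
            f"(failed detection: {int((~pass_detection).sum())}, "
            f"failed occupancy: {int((~pass_occupancy).sum())}, "
            f"total taxa: {len(table)})"
        )
    return table.loc[keep]


def _bin_index(times: pd.DatetimeIndex, width: int) -> np.ndarray:
    days = (times - times[0]).days.to_numpy()
    return days // width


def select_bin_width(sample_times, candidates) -> int:
    """Pick the bin width (days) that preserves the most data points.

    For each candidate width the fixed grid anchored at the first sample
    date is laid out and the number of non-empty bins counted; the width
    with the maximum count wins, ties going to the smaller width.
    """
    candidates = sorted(int(c) for c in candidates)
    if not candidates or candidates[0] < 1:
        raise ValueError("candidates must be positive integers")
    times = pd.DatetimeIndex(sample_times)
    best_width, best_count = None, -1
    for width in candidates:
        count = len(np.unique(_bin_index(times, width)))
        if count > best_count:
            best_width, best_count = width, count
    return best_width


def bin_series(table: pd.DataFrame, width: int, aggregator: str = "mean") -> BinnedSeries:
    """Aggregate samples onto a fixed ``width``-day grid.

    Bins are half-open intervals [start, start + width) anchored at the first
    sample date; bin values are the ``aggregator`` (default arithmetic mean)
    of the samples falling inside.  Empty bins are linearly interpolated
    (ends held at the nearest value) and flagged incomplete.  More than 20%
    empty bins logs a warning; more than 50% is an error.
    """
    if width < 1:
        raise ValueError("width must be >= 1 day")
    times = pd.DatetimeIndex(table.columns)
    if not times.is_monotonic_increasing:
        raise ValueError("sample timestamps must be increasing")
    idx = _bin_index(times, width)
    n_bins = int(idx.max()) + 1
    grouped = table.T.groupby(idx).agg(aggregator).T
    grouped = grouped.reindex(columns=range(n_bins))
    completeness = ~grouped.isna().all(axis=0).to_numpy()
    frac_empty = 1.0 - completeness.mean()
    if frac_empty > 0.5:
        raise ValueError(f"{frac_empty:.0%} of bins are empty; choose a different bin width")
    if frac_empty > 0.2:
        logger.warning("%.0f%% of bins are empty and will be interpolated", 100 * frac_empty)
    filled = grouped.interpolate(axis=1, method="linear", limit_direction="both")
    starts = times[0] + pd.to_timedelta(np.arange(n_bins) * width, unit="D")
    filled.columns = starts
    return BinnedSeries(values=filled, bin_width=width, completeness=completeness)


def bin_auxiliary(series: pd.Series, reference: BinnedSeries) -> pd.Series:
    """Average an auxiliary daily series (e.g. temperature) onto the bin grid
    of ``reference``; empty bins are linearly interpolated."""
    times = pd.DatetimeIndex(series.index)
    starts = reference.bin_starts
    width = reference.bin_width
    days = (times - starts[0]).days.to_numpy()
    idx = days // width
    ok = (idx >= 0) & (idx < len(starts))
    if not ok.any():
        raise ValueError("auxiliary series does not overlap the bin grid")
    agg = pd.Series(series.to_numpy()[ok]).groupby(idx[ok]).mean()
    out = agg.reindex(range(len(starts))).interpolate(limit_direction="both")
    out.index = starts
    return out


def standardize(series: BinnedSeries) -> BinnedSeries:
    """Z-score every taxon row (population-SD convention, divide by n).

    The original mean and SD of each taxon are stored in ``scale_record`` so
    that inferred coefficients can be converted back to the raw-abundance
    scale.  A zero-variance taxon is an error (its state-space coordinate
    would be degenerate).
    """
    vals = series.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=0)
    bad = sd <= 0
    if bad.any():
        names = ", ".join(map(str, vals.index[bad][:5]))
        raise ValueError(f"zero-variance taxa cannot be standardized: {names}")
    z = vals.sub(mean, axis=0).div(sd, axis=0)
    record = pd.DataFrame({"mean": mean, "sd": sd})
    return replace(series, values=z, scale_record=record)


def destandardize(series: BinnedSeries) -> BinnedSeries:
    """Invert :func:`standardize` using the stored scale record."""
    if series.scale_record is None:
        raise ValueError("series carries no scale_record")
    rec = series.scale_record
    vals = series.values.mul(rec["sd"], axis=0).add(rec["mean"], axis=0)
    return replace(series, values=vals, scale_record=None)
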