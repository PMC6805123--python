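"""From raw detection streams and rasters to model-ready inputs.

Detections are collapsed into independent *events* per site and species
using a separation interval (5 minutes by default): a detection opens a new
event only when the gap to the previous detection is strictly greater than
the interval, so a gap of exactly the interval still belongs to the same
event.  Covariates are standardized to mean 0 / SD 1 with the population-SD
convention, and the transform is recorded so prediction-time inputs reuse
the training statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .grid import LandscapeGrid

__all__ = [
    "collapse_events",
    "CovariateStandardizer",
    "standardize_covariates",
    "screen_collinearity",
    "sample_raster_at_sites",
]


def collapse_events(
    records: pd.DataFrame,
    interval_minutes: float = 5.0,
    site_col: str = "site_id",
    species_col: str = "species",
    time_col: str = "timestamp",
) -> pd.DataFrame:
    """Collapse detections into per-site, per-species event counts.

    ``records`` needs site, species and timestamp columns (timestamps
    parseable by pandas; sorting is internal, so input order is
    irrelevant).  Returns one row per (site, species) with the event count.
    """
    if interval_minutes < 0:
        raise ValueError("interval must be non-negative")
    for col in (site_col, species_col, time_col):
        if col not in records.columns:
            raise ValueError(f"records lack column {col!r}")
    if len(records) == 0:
        return pd.DataFrame(columns=[site_col, species_col, "events"])
    times = pd.to_datetime(records[time_col])
    if times.isna().any():
        raise ValueError("unparseable timestamps in detection records")
    work = records[[site_col, species_col]].copy()
    work["_t"] = times
    work = work.sort_values([site_col, species_col, "_t"], kind="mergesort")
    gap = work.groupby([site_col, species_col], sort=False)["_t"].diff()
    threshold = pd.Timedelta(minutes=interval_minutes)
    new_event = gap.isna() | (gap > threshold)  # strictly greater opens an event
    work["events"] = new_event.astype(int)
    out = (
        work.groupby([site_col, species_col], sort=True)["events"]
        .sum()
        .reset_index()
    )
    return out


class CovariateStandardizer(BaseEstimator, TransformerMixin):
    """Center/scale covariate columns to mean 0, SD 1.

    ``ddof`` selects the SD convention (0 = population, the default).  The
    fitted means and scales are the standardization record applied to any
    later (e.g. prediction-time) table.
    """

    def __init__(self, ddof: int = 0):
        self.ddof = ddof

    def fit(self, table: pd.DataFrame, y=None) -> "CovariateStandardizer":
        table = pd.DataFrame(table)
        means = table.mean(axis=0)
        scales = table.std(axis=0, ddof=self.ddof)
        bad = scales[scales <= 0]
        if len(bad) > 0:
            raise ValueError(
                f"zero-variance column(s): {list(bad.index)}; cannot standardize"
            )
        self.columns_ = list(table.columns)
        self.means_ = means
        self.scales_ = scales
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        table = pd.DataFrame(table)
        missing = set(self.columns_) - set(table.columns)
        if missing:
            raise ValueError(f"table lacks fitted columns {sorted(missing)}")
        out = (table[self.columns_] - self.means_) / self.scales_
        return out

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        table = pd.DataFrame(table)
        return table[self.columns_] * self.scales_ + self.means_

    def record(self) -> pd.DataFrame:
        """The standardization record as a (mean, sd) table."""
        return pd.DataFrame({"mean": self.means_, "sd": self.scales_})


def standardize_covariates(
    table: pd.DataFrame, ddof: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize all columns; returns (transformed table, record)."""
    tf = CovariateStandardizer(ddof=ddof).fit(table)
    return tf.transform(table), tf.record()


def screen_collinearity(
    table: pd.DataFrame, threshold: float = 0.7
) -> list[tuple[str, str, float]]:
    """All unordered column pairs whose |Pearson r| reaches the threshold.

    An empty list means the covariate set passes the screen.
    """
    table = pd.DataFrame(table)
    if table.shape[1] < 2:
        raise ValueError("need at least two columns to screen")
    if table.shape[0] < 3:
        raise ValueError("need at least three rows for a meaningful correlation")
    corr = np.corrcoef(table.to_numpy(dtype=float), rowvar=False)
    cols = list(table.columns)
    offending = []
    for i, j in itertools.combinations(range(len(cols)), 2):
        r = float(corr[i, j])
        if abs(r) >= threshold:
            offending.append((cols[i], cols[j], r))
    return offending


def sample_raster_at_sites(
    grid: LandscapeGrid,
    x: np.ndarray,
    y: np.ndarray,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Nearest-cell index for site coordinates in metres.

    ``origin`` is the (x, y) of the grid's top-left (north-west) corner;
    x grows east, y grows south.  Returns flat 0-based cell indices.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    col = np.floor((x - origin[0]) / grid.cell_size).astype(int)
    row = np.floor((y - origin[1]) / grid.cell_size).astype(int)
    return grid.cell_of_rowcol(row, col)
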