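"""Relative-frequency histogram of the log-transformed classifier variable.

The decomposition is fit to a histogram, not to the raw sample, so the
binning rules matter and are fixed here: natural-log transform after a
plausibility filter on the raw scale, Freedman–Diaconis bin width
``h = 2*IQR/n^(1/3)``, bin count ``ceil((max - min)/h)``, bins anchored at
the sample minimum. Interior bins are half-open [left, right); the last bin
is closed on the right so the maximum is never lost. The IQR uses linear
interpolation between order statistics (quantile "type 7").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RelFreqHistogram", "preprocess", "fd_bin_width", "build_histogram", "read_table"]

logger = logging.getLogger(__name__)

#: Raw-scale plausibility bounds (original units): values outside are
#: treated as outliers/artefacts and excluded before log-transforming.
DEFAULT_VMIN = 0.1
DEFAULT_VMAX = 100.0


@dataclass(frozen=True)
class RelFreqHistogram:
    """Equal-width relative-frequency histogram on the log scale.

    ``rel_freq`` holds per-bin sample proportions (they sum to one for any
    histogram built from data by :func:`build_histogram`); ``h`` is the
    common bin width and ``n`` the number of samples binned.
    """

    edges: np.ndarray
    rel_freq: np.ndarray
    h: float
    n: int
    centers: np.ndarray = field(init=False)
    n_bin: int = field(init=False)

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        rel_freq = np.asarray(self.rel_freq, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be a strictly increasing 1-d array")
        if rel_freq.size != edges.size - 1:
            raise ValueError("rel_freq must have one entry per bin")
        if not self.h > 0:
            raise ValueError("bin width h must be positive")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "rel_freq", rel_freq)
        object.__setattr__(self, "centers", 0.5 * (edges[:-1] + edges[1:]))
        object.__setattr__(self, "n_bin", rel_freq.size)


def preprocess(values, vmin: float = DEFAULT_VMIN, vmax: float = DEFAULT_VMAX) -> np.ndarray:
    """Filter raw positive measurements to [vmin, vmax] and take natural logs.

    Values outside the closed interval are excluded (counted and logged);
    the relative order of retained samples is preserved.
    """
    if not vmin > 0:
        raise ValueError("vmin must be positive (log of the bound must exist)")
    if not vmax > vmin:
        raise ValueError("vmax must exceed vmin")
    arr = np.asarray(values, dtype=float)
    mask = np.isfinite(arr) & (arr >= vmin) & (arr <= vmax)
    n_excluded = int(arr.size - mask.sum())
    if n_excluded:
        logger.info("excluded %d of %d values outside [%g, %g]", n_excluded, arr.size, vmin, vmax)
    kept = arr[mask]
    if kept.size == 0:
        raise ValueError("no data in range")
    return np.log(kept)


def fd_bin_width(logvals) -> float:
    """Freedman–Diaconis bin width 2*IQR(x) / n^(1/3) on log-values."""
    x = np.asarray(logvals, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples for a meaningful IQR")
    q25, q75 = np.percentile(x, [25.0, 75.0])  # linear interpolation (type 7)
    iqr = q75 - q25
    if iqr <= 0:
        raise ValueError("degenerate data: IQR is zero")
    return 2.0 * iqr / x.size ** (1.0 / 3.0)


def build_histogram(logvals, h: float | None = None) -> RelFreqHistogram:
    """Bin log-values into ``ceil(range/h)`` equal bins anchored at min(x).

    ``h`` defaults to the Freedman–Diaconis width. Deterministic: the same
    data always yields the same histogram.
    """
    x = np.asarray(logvals, dtype=float)
    if x.size == 0:
        raise ValueError("no data to bin")
    if not np.all(np.isfinite(x)):
        raise ValueError("log-values must be finite")
    if h is None:
        h = fd_bin_width(x)  # enforces n >= 4 and a non-degenerate IQR
    elif not h > 0:
        raise ValueError("bin width h must be positive")
    lo, hi = float(np.min(x)), float(np.max(x))
    n_bin = max(int(math.ceil((hi - lo) / h)), 1)
    edges = lo + h * np.arange(n_bin + 1)
    # floor-indexing gives half-open interior bins; the clip folds x == max
    # (index n_bin) into the last bin, closing it on the right
    idx = np.clip(np.floor((x - lo) / h).astype(int), 0, n_bin - 1)
    counts = np.bincount(idx, minlength=n_bin)
    return RelFreqHistogram(edges=edges, rel_freq=counts / x.size, h=float(h), n=int(x.size))


def read_table(
    path,
    value_col: str,
    age_col: str | None = None,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a CSV/TSV of measurements; rows with unparsable values are dropped.

    The delimiter is sniffed from the header line when not given (tab vs
    comma). Returns a DataFrame with a ``value`` column and, if requested,
    an ``age`` column.
    """
    if delimiter is None:
        with open(path) as fh:
            delimiter = "\t" if "\t" in fh.readline() else ","
    df = pd.read_csv(path, sep=delimiter)
    if value_col not in df.columns:
        raise ValueError(f"value column {value_col!r} not found in {list(df.columns)}")
    cols = {"value": pd.to_numeric(df[value_col], errors="coerce")}
    if age_col is not None:
        if age_col not in df.columns:
            raise ValueError(f"age column {age_col!r} not found in {list(df.columns)}")
        cols["age"] = pd.to_numeric(df[age_col], errors="coerce")
    out = pd.DataFrame(cols)
    n_bad = int(out["value"].isna().sum())
    if n_bad:
        logger.warning("dropped %d rows with unparsable values", n_bad)
    return out.dropna().reset_index(drop=True)
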