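"""Five-number realized-niche envelopes per (species, ecoregion, variable).

The envelope of a sample of extracted environmental values is its minimum,
25th percentile, mean, 75th percentile, and maximum.  Percentiles use the
linear-interpolation definition shared by R's ``quantile(type = 7)`` and
NumPy's default: with the sample sorted as ``x_1 <= ... <= x_n`` and
``h = (n - 1) p + 1``,

    Q(p) = x_floor(h) + (h - floor(h)) * (x_floor(h)+1 - x_floor(h))

so summaries match what standard statistical environments produce.
"""

from __future__ import annotations

import math
from collections.abc import Iterable

import numpy as np
import pandas as pd

__all__ = ["quantile", "summarize_niche", "filter_min_observations", "SUMMARY_COLUMNS"]

#: Output schema of :func:`summarize_niche`, in order.
SUMMARY_COLUMNS = ["species", "eco_id", "eco_name", "variable_code", "units",
                   "n_obs", "min", "p25", "mean", "p75", "max"]


def quantile(values, p: float) -> float:
    """Linear-interpolation sample quantile (R type 7).

    Parameters
    ----------
    values
        Non-empty collection of finite reals.
    p
        Probability in [0, 1]; ``p=0`` returns the minimum, ``p=1`` the
        maximum.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("quantile of an empty sample is undefined")
    if not np.isfinite(x).all():
        raise ValueError("quantile requires finite values")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    h = (n - 1) * p + 1.0          # 1-based fractional order statistic
    lo = int(math.floor(h))
    if lo >= n:                     # p == 1 (or fp round-up): top order statistic
        return float(x[n - 1])
    frac = h - lo
    return float(x[lo - 1] + frac * (x[lo] - x[lo - 1]))


def _envelope(vals: np.ndarray) -> tuple[int, float, float, float, float, float]:
    return (int(vals.size), float(vals.min()), quantile(vals, 0.25),
            float(vals.mean()), quantile(vals, 0.75), float(vals.max()))


def summarize_niche(extractions: pd.DataFrame) -> pd.DataFrame:
    """Summarize extracted values into envelope rows.

    Parameters
    ----------
    extractions
        Long-format table with columns ``species``, ``eco_id``,
        ``variable_code``, ``value`` and optionally ``eco_name`` and
        ``units``.  ``value`` may contain NaN (points in nodata cells of
        that variable's layer); missing values are excluded per variable.

    Returns
    -------
    pandas.DataFrame
        One row per (species, eco_id, variable_code) with at least one
        non-missing value, columns :data:`SUMMARY_COLUMNS`.  ``n_obs`` is
        the per-variable non-missing count.  Triples whose values are all
        missing emit no row.  Row order is sorted by the group key, so the
        result is invariant to input record order.
    """
    df = extractions.dropna(subset=["value"])
    names = {}
    if "eco_name" in extractions.columns:
        names = (extractions.dropna(subset=["eco_name"])
                 .drop_duplicates("eco_id").set_index("eco_id")["eco_name"].to_dict())
    units = {}
    if "units" in extractions.columns:
        units = (extractions.drop_duplicates("variable_code")
                 .set_index("variable_code")["units"].to_dict())
    rows = []
    for (species, eco_id, var), grp in df.groupby(["species", "eco_id", "variable_code"],
                                                  sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        n, vmin, p25, mean, p75, vmax = _envelope(vals)
        rows.append((species, eco_id, names.get(eco_id), var, units.get(var),
                     n, vmin, p25, mean, p75, vmax))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def filter_min_observations(rows: pd.DataFrame, threshold: int,
                            count_basis: pd.Series | dict) -> pd.DataFrame:
    """Drop envelope rows of under-observed species-ecoregion pairs.

    A pair survives only when its occurrence-record count in ``count_basis``
    is strictly greater than ``threshold`` ("more than 10 observations" at
    the default 10, i.e. n >= 11).  All variables of a dropped pair are
    dropped together.  The basis is the per-(species, eco_id) record count
    before per-variable missing-value exclusion, so a row's ``n_obs`` may be
    smaller than the threshold for sparse layers; it is reported, not
    re-filtered.

    Parameters
    ----------
    rows
        Output of :func:`summarize_niche`.
    threshold
        Strict lower bound on the pair's record count.
    count_basis
        Mapping ``(species, eco_id) -> record count``, e.g. from
        ``labelled.records.groupby(["species", "eco_id"]).size()``.
    """
    if not isinstance(count_basis, pd.Series):
        count_basis = pd.Series(count_basis)
    surviving = set(count_basis[count_basis > threshold].index)
    keep = [
        (species, eco_id) in surviving
        for species, eco_id in zip(rows["species"], rows["eco_id"])
    ]
    return rows.loc[keep].reset_index(drop=True)


def pair_counts(labelled_records: pd.DataFrame) -> pd.Series:
    """Occurrence-record count per assigned (species, eco_id) pair."""
    df = labelled_records.dropna(subset=["eco_id"])
    return df.groupby(["species", "eco_id"]).size()
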