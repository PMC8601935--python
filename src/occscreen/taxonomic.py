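"""Temporal and taxonomic screening heuristics.

Four per-(identifier, period) series:

* ``assess_record_number`` — raw recording intensity through time.
* ``assess_species_number`` — taxonomic coverage (distinct species).
* ``assess_species_id`` — taxonomic resolution: the share (or count) of
  records identified to species level, a missing species label meaning
  "not identified to species".
* ``assess_rarity_bias`` — whether rare species are over-recorded relative
  to their commonness. Commonness follows the regional-occupancy proxy:
  the number of grid cells in which a species has been recorded. If
  recording were proportional to commonness the per-species record count
  would be a linear function of commonness; the heuristic reports the
  strength of that linear relation, either as the r-squared of an OLS fit
  of count on commonness (0 = high bias, 1 = none) or as the Pearson
  correlation (-1..1, closer to 1 = less bias). Both measure only the
  *linear* relation, so the per-species scatter is returned for
  inspection of curvature.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import HeuristicResult, OccurrenceTable, PeriodSet, require_periods
from .spatial import cell_indices, snap_origin

MIN_SPECIES_FOR_INDEX = 3  # a correlation over fewer points is meaningless


def _count_grid(tab: OccurrenceTable, values: pd.Series) -> pd.DataFrame:
    """Tidy (identifier x period) frame of per-group sums of ``values``."""
    df = tab.data.assign(_v=values.to_numpy())
    counts = (
        df.groupby(["identifier", "period"], observed=False)["_v"]
        .sum()
        .reset_index(name="count")
    )
    # complete grid: identifiers present after filtering x all periods
    counts["count"] = counts["count"].astype(int)
    return counts.sort_values(["identifier", "period"]).reset_index(drop=True)


def _normalize(counts: pd.DataFrame, col: str = "count") -> pd.DataFrame:
    out = counts.copy()
    peak = out.groupby("identifier", observed=True)[col].transform("max")
    out["normalized"] = np.where(peak > 0, out[col] / peak, np.nan)
    return out


def assess_record_number(
    tab: OccurrenceTable,
    periods: PeriodSet | None = None,
    normalize: bool = False,
) -> HeuristicResult:
    """Number of records per (identifier, period).

    ``normalize`` divides each identifier's counts by its maximum across
    periods, anchoring every series' peak at 1 so groups of very different
    size can be compared on one axis.
    """
    tab = require_periods(tab, periods)
    counts = _count_grid(tab, pd.Series(1, index=tab.data.index))
    if normalize:
        counts = _normalize(counts)
    meta = {"heuristic": "record_number", "normalize": normalize,
            "rejected": tab.reject_counts()}
    return HeuristicResult("record_number", counts, meta)


def assess_species_number(
    tab: OccurrenceTable,
    periods: PeriodSet | None = None,
    normalize: bool = False,
) -> HeuristicResult:
    """Distinct species per (identifier, period); unidentified records drop."""
    tab = require_periods(tab, periods)
    counts = (
        tab.data.groupby(["identifier", "period"], observed=False)["species"]
        .nunique(dropna=True)
        .reset_index(name="count")
        .sort_values(["identifier", "period"])
        .reset_index(drop=True)
    )
    if normalize:
        counts = _normalize(counts)
    meta = {"heuristic": "species_number", "normalize": normalize,
            "rejected": tab.reject_counts()}
    return HeuristicResult("species_number", counts, meta)


def assess_species_id(
    tab: OccurrenceTable,
    periods: PeriodSet | None = None,
    mode: str = "proportion",
    normalize: bool = False,
) -> HeuristicResult:
    """Proportion (or count) of records identified to species level.

    A record counts as identified when its species label is present.
    Proportions are undefined (missing, not zero) in empty periods.
    """
    if mode not in ("proportion", "count"):
        raise ValueError(f"mode must be 'proportion' or 'count', got {mode!r}")
    tab = require_periods(tab, periods)
    grouped = tab.data.groupby(["identifier", "period"], observed=False)["species"]
    agg = grouped.agg(identified="count", total="size").reset_index()
    if mode == "proportion":
        agg["proportion"] = np.where(agg["total"] > 0,
                                     agg["identified"] / agg["total"], np.nan)
        data = agg[["identifier", "period", "proportion"]]
    else:
        data = agg.rename(columns={"identified": "count"})[
            ["identifier", "period", "count"]]
        if normalize:
            data = _normalize(data)
    meta = {"heuristic": "species_id", "mode": mode, "rejected": tab.reject_counts()}
    return HeuristicResult("species_id", data.reset_index(drop=True), meta)


def species_commonness(
    tab: OccurrenceTable,
    resolution: float,
    scope: str = "all",
    origin: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-species occupied-grid-cell counts (the commonness proxy).

    Commonness of species *s* is the number of distinct cells, at the given
    resolution on the canonical grid origin, that contain at least one
    record of *s* within the stated scope — per identifier over the whole
    temporal extent (``scope="all"``) or separately per period
    (``scope="per_period"``). Unidentified records are excluded.

    Returns columns: identifier, [period,] species, commonness.
    """
    if resolution <= 0:
        raise ValueError(f"grid resolution must be positive, got {resolution}")
    if scope not in ("all", "per_period"):
        raise ValueError(f"scope must be 'all' or 'per_period', got {scope!r}")
    df = tab.data[tab.data["species"].notna()].copy()
    if df.empty:
        cols = ["identifier", "species", "commonness"]
        if scope == "per_period":
            cols.insert(1, "period")
        return pd.DataFrame(columns=cols)
    if origin is None:
        origin = (snap_origin(df["x"].to_numpy(), resolution),
                  snap_origin(df["y"].to_numpy(), resolution))
    ix, iy = cell_indices(df["x"].to_numpy(), df["y"].to_numpy(), resolution, origin)
    df["_cell"] = [f"{i}:{j}" for i, j in zip(ix, iy)]
    keys = ["identifier", "species"] if scope == "all" else ["identifier", "period", "species"]
    if scope == "per_period" and "period" not in df.columns:
        raise ValueError("per_period commonness requires period-assigned records")
    out = (
        df.groupby(keys, observed=True)["_cell"]
        .nunique()
        .reset_index(name="commonness")
    )
    return out


def _congruence(counts: np.ndarray, commonness: np.ndarray, method: str) -> float:
    """Linear congruence of per-species record count with commonness."""
    if len(counts) < MIN_SPECIES_FOR_INDEX:
        return np.nan
    if np.ptp(counts) == 0 or np.ptp(commonness) == 0:
        warnings.warn(
            "rarity index undefined: zero variance in counts or commonness",
            stacklevel=3,
        )
        return np.nan
    r = stats.pearsonr(commonness, counts).statistic
    # For a single predictor the OLS coefficient of determination is r^2.
    return float(r**2) if method == "r2" else float(r)


def assess_rarity_bias(
    tab: OccurrenceTable,
    periods: PeriodSet | None = None,
    resolution: float = 1.0,
    method: str = "r2",
    scope: str = "all",
) -> HeuristicResult:
    """Congruence of per-species record counts with commonness, per period.

    ``method="r2"`` gives the coefficient of determination of an OLS
    regression of record count on commonness (0 = high bias, 1 = low);
    ``method="pearson"`` the correlation coefficient (-1..1). Periods with
    fewer than three recorded species, or degenerate variance, yield a
    missing index with a warning. The per-species scatter backing each
    index is returned in ``extras["scatter"]``.
    """
    if method not in ("r2", "pearson"):
        raise ValueError(f"method must be 'r2' or 'pearson', got {method!r}")
    tab = require_periods(tab, periods)
    common = species_commonness(tab, resolution, scope)

    df = tab.data[tab.data["species"].notna()]
    counts = (
        df.groupby(["identifier", "period", "species"], observed=False)
        .size()
        .reset_index(name="n_records")
    )
    counts = counts[counts["n_records"] > 0]
    join_keys = (["identifier", "species"] if scope == "all"
                 else ["identifier", "period", "species"])
    scatter = counts.merge(common, on=join_keys, how="left")

    rows = []
    period_labels = list(tab.data["period"].cat.categories)
    for ident in tab.identifiers:
        for per in period_labels:
            sub = scatter[(scatter["identifier"] == ident) & (scatter["period"] == per)]
            idx = _congruence(sub["n_records"].to_numpy(dtype=float),
                              sub["commonness"].to_numpy(dtype=float), method)
            rows.append({"identifier": ident, "period": per,
                         "index": idx, "n_species": len(sub)})
    data = pd.DataFrame(rows)
    meta = {"heuristic": "rarity_bias", "method": method, "scope": scope,
            "resolution": resolution, "rejected": tab.reject_counts()}
    return HeuristicResult("rarity_bias", data, meta, extras={"scatter": scatter})
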