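"""Shared data model for occurrence-record bias screening.

Every heuristic in this package consumes the same validated six-field
occurrence table — species, x, y, year, spatialUncertainty, identifier —
split into user-defined year periods and grouped by the identifier column
(a taxon, dataset, country, or any other comparison label). This module
owns that contract: column mapping from arbitrary source names (including
Darwin Core terms), validation with an explicit reject set, spatial
uncertainty filtering, and period assignment.

Coordinates are taken at face value in whatever CRS the user supplies; no
reprojection is performed and all downstream distances are planar Euclidean
in CRS units. For lon/lat data over large latitudinal extents this distorts
distances — a caveat, not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

REQUIRED_FIELDS = ("species", "x", "y", "year", "spatialUncertainty", "identifier")

#: Source-column names recognised without explicit configuration, keyed by
#: canonical field. Darwin Core terms first, then the canonical names
#: themselves, then common informal variants.
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "species": ("species", "scientificName", "Species"),
    "x": ("x", "decimalLongitude", "longitude", "lon"),
    "y": ("y", "decimalLatitude", "latitude", "lat"),
    "year": ("year", "Year"),
    "spatialUncertainty": (
        "spatialUncertainty",
        "coordinateUncertaintyInMeters",
        "coordinateUncertaintyInMetres",
    ),
    "identifier": ("identifier", "datasetName", "Identifier"),
}

DEFAULT_IDENTIFIER = "all"


class ConfigurationError(ValueError):
    """A field mapping or option does not match the supplied data."""


class EmptyInputError(ValueError):
    """No usable records remain after validation or filtering."""


@dataclass(frozen=True)
class FieldMapping:
    """Maps the six canonical occurrence fields to source-column names."""

    species: str = "species"
    x: str = "x"
    y: str = "y"
    year: str = "year"
    spatialUncertainty: str = "spatialUncertainty"
    identifier: str = "identifier"

    def as_dict(self) -> dict[str, str]:
        return {f: getattr(self, f) for f in REQUIRED_FIELDS}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, str]) -> "FieldMapping":
        unknown = set(mapping) - set(REQUIRED_FIELDS)
        if unknown:
            raise ConfigurationError(f"unknown field(s) in mapping: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def infer(cls, columns: Iterable[str]) -> "FieldMapping":
        """Guess a mapping from column names using Darwin Core aliases."""
        cols = list(columns)
        resolved: dict[str, str] = {}
        for fld, aliases in DEFAULT_ALIASES.items():
            for alias in aliases:
                if alias in cols:
                    resolved[fld] = alias
                    break
            else:
                raise ConfigurationError(
                    f"cannot infer a source column for required field '{fld}'; "
                    f"supply an explicit mapping (recognised names: {aliases})"
                )
        return cls(**resolved)


@dataclass(frozen=True)
class Period:
    """Inclusive range of calendar years."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"period start {self.start} exceeds end {self.end}")
        if not self.label:
            object.__setattr__(self, "label", f"{self.start}-{self.end}")

    def contains(self, year: int) -> bool:
        return self.start <= year <= self.end


class PeriodSet:
    """Ordered, non-overlapping inclusive year ranges.

    The ranges must ascend and may not overlap: every temporally explicit
    heuristic treats them as a partition of the years of interest, and a
    record falling in two periods would be double-counted. The minimum
    period length is one year (``start == end``).
    """

    def __init__(self, periods: Sequence[tuple[int, int] | Period]):
        parsed: list[Period] = []
        for p in periods:
            if isinstance(p, Period):
                parsed.append(p)
            else:
                start, end = p
                parsed.append(Period(int(start), int(end)))
        if not parsed:
            raise ValueError("at least one period is required")
        for prev, nxt in zip(parsed, parsed[1:]):
            if nxt.start <= prev.end:
                raise ValueError(
                    f"periods must be ascending and non-overlapping: "
                    f"{prev.label} then {nxt.label}"
                )
        self.periods: tuple[Period, ...] = tuple(parsed)

    def __len__(self) -> int:
        return len(self.periods)

    def __iter__(self):
        return iter(self.periods)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.periods]

    def assign(self, years: pd.Series) -> pd.Series:
        """Map each year to its period label; NaN where unassignable."""
        bins = pd.Series(pd.NA, index=years.index, dtype="object")
        for p in self.periods:
            inside = years.notna() & (years >= p.start) & (years <= p.end)
            bins[inside] = p.label
        return bins

    @classmethod
    def decadal(cls, first: int = 1950, last: int = 2019) -> "PeriodSet":
        """Decade-long periods covering [first, last], e.g. 1950-1959 … 2010-2019."""
        starts = range(first, last + 1, 10)
        return cls([(s, min(s + 9, last)) for s in starts])


@dataclass
class OccurrenceTable:
    """Validated occurrence records plus the rejects removed along the way.

    ``data`` always has the six canonical columns (plus ``period`` once
    :func:`assign_periods` has run). ``rejects`` carries the original rows
    that failed validation or filtering with a ``reject_reason`` column, so
    no record is ever silently dropped:
    ``len(data) + len(rejects)`` equals the validated input size.
    """

    data: pd.DataFrame
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=[*REQUIRED_FIELDS, "reject_reason"])
    )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def identifiers(self) -> list[str]:
        return sorted(self.data["identifier"].unique())

    def reject_counts(self) -> dict[str, int]:
        if self.rejects.empty:
            return {}
        return self.rejects["reject_reason"].value_counts().to_dict()

    def with_rejects(self, rows: pd.DataFrame, reason: str) -> pd.DataFrame:
        rows = rows.copy()
        rows["reject_reason"] = reason
        frames = [df for df in (self.rejects, rows) if not df.empty]
        if not frames:
            return self.rejects
        return pd.concat(frames, ignore_index=True)


@dataclass
class HeuristicResult:
    """Tidy per-(identifier, period) output of one heuristic.

    ``data`` is the table a plot would draw; ``meta`` records the heuristic
    name, options, drop counts and seed so a run is reproducible from its
    result alone; ``extras`` carries secondary tables (e.g. the per-species
    count-vs-commonness scatter behind the rarity index).
    """

    name: str
    data: pd.DataFrame
    meta: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def _is_missing_text(s: pd.Series) -> pd.Series:
    txt = s.astype("string")
    return s.isna() | (txt.str.strip() == "") | txt.str.upper().isin(["NA", "NAN"])


def validate_occurrences(
    raw: pd.DataFrame,
    mapping: FieldMapping | Mapping[str, str] | None = None,
) -> OccurrenceTable:
    """Validate a raw table into the canonical six-field form.

    Parameters
    ----------
    raw
        Source table with at least the six mapped columns.
    mapping
        Source-column name per canonical field. When omitted, Darwin Core
        and canonical names are matched automatically.

    Records with missing or non-finite coordinates, or negative spatial
    uncertainty, move to the reject set with a reason. Blank or sentinel
    species strings become missing; missing identifiers receive the default
    group label so ungrouped datasets work without configuration.

    Raises
    ------
    ConfigurationError
        If a mapped column is absent from ``raw``.
    EmptyInputError
        If ``raw`` had rows but none survived validation.
    """
    if mapping is None:
        mapping = FieldMapping.infer(raw.columns)
    elif not isinstance(mapping, FieldMapping):
        mapping = FieldMapping.from_dict(mapping)

    for fld, col in mapping.as_dict().items():
        if col not in raw.columns:
            raise ConfigurationError(
                f"mapped column '{col}' for field '{fld}' not found in input"
            )

    tab = pd.DataFrame(
        {fld: raw[col].reset_index(drop=True) for fld, col in mapping.as_dict().items()}
    )

    # Already-canonical numeric columns pass through unchanged (idempotence).
    tab["x"] = pd.to_numeric(tab["x"], errors="coerce")
    tab["y"] = pd.to_numeric(tab["y"], errors="coerce")
    tab["year"] = pd.to_numeric(tab["year"], errors="coerce").round().astype("Int64")
    tab["spatialUncertainty"] = pd.to_numeric(tab["spatialUncertainty"], errors="coerce")

    tab.loc[_is_missing_text(tab["species"]), "species"] = pd.NA
    tab["species"] = tab["species"].astype("string")

    ident_missing = _is_missing_text(tab["identifier"])
    tab.loc[ident_missing, "identifier"] = DEFAULT_IDENTIFIER
    tab["identifier"] = tab["identifier"].astype("string")

    bad_coord = ~(np.isfinite(tab["x"].to_numpy(dtype=float)) & np.isfinite(tab["y"].to_numpy(dtype=float)))
    bad_unc = tab["spatialUncertainty"].notna() & (tab["spatialUncertainty"] < 0)

    out = OccurrenceTable(data=tab.loc[~bad_coord & ~bad_unc].reset_index(drop=True))
    rejects = out.rejects
    if bad_coord.any():
        rejects = _append_reason(rejects, tab.loc[bad_coord], "invalid_coordinates")
    if (bad_unc & ~bad_coord).any():
        rejects = _append_reason(rejects, tab.loc[bad_unc & ~bad_coord], "negative_uncertainty")
    out.rejects = rejects

    if len(raw) > 0 and len(out.data) == 0:
        raise EmptyInputError("no valid records remain after validation")
    return out


def _append_reason(rejects: pd.DataFrame, rows: pd.DataFrame, reason: str) -> pd.DataFrame:
    rows = rows.copy()
    rows["reject_reason"] = reason
    frames = [df for df in (rejects, rows) if not df.empty]
    if not frames:
        return rejects
    return pd.concat(frames, ignore_index=True)


def filter_by_uncertainty(
    tab: OccurrenceTable,
    threshold: float | None = None,
    drop_missing: bool = False,
) -> OccurrenceTable:
    """Drop records whose spatial uncertainty exceeds ``threshold``.

    Records with missing uncertainty are kept unless ``drop_missing`` —
    the filter removes only values known to be above the threshold.
    ``threshold=None`` is a no-op.
    """
    if threshold is None:
        return OccurrenceTable(tab.data.copy(), tab.rejects.copy())
    if threshold <= 0:
        raise ValueError(f"uncertainty threshold must be positive, got {threshold}")

    unc = tab.data["spatialUncertainty"]
    too_coarse = unc.notna() & (unc > threshold)
    missing = unc.isna()
    drop = too_coarse | (missing & drop_missing)

    rejects = tab.rejects.copy()
    if too_coarse.any():
        rejects = _append_reason(rejects, tab.data.loc[too_coarse], "uncertainty_above_threshold")
    if drop_missing and missing.any():
        rejects = _append_reason(rejects, tab.data.loc[missing], "missing_uncertainty")
    return OccurrenceTable(tab.data.loc[~drop].reset_index(drop=True), rejects)


def assign_periods(tab: OccurrenceTable, periods: PeriodSet) -> OccurrenceTable:
    """Label each record with its period; reject unassignable years.

    Bounds are inclusive on both ends. Records with missing year, or a year
    outside every period, move to the reject set (reasons ``missing_year``
    and ``year_out_of_range``), keeping the partition accountable:
    assigned + rejected = input.
    """
    if not isinstance(periods, PeriodSet):
        periods = PeriodSet(periods)
    labels = periods.assign(tab.data["year"])
    missing_year = tab.data["year"].isna()
    out_of_range = labels.isna() & ~missing_year

    data = tab.data.loc[labels.notna()].copy()
    data["period"] = pd.Categorical(
        labels.loc[labels.notna()], categories=periods.labels, ordered=True
    )

    rejects = tab.rejects.copy()
    if missing_year.any():
        rejects = _append_reason(rejects, tab.data.loc[missing_year], "missing_year")
    if out_of_range.any():
        rejects = _append_reason(rejects, tab.data.loc[out_of_range], "year_out_of_range")
    return OccurrenceTable(data.reset_index(drop=True), rejects)


def require_periods(tab: OccurrenceTable, periods: PeriodSet | None) -> OccurrenceTable:
    """Assign periods if not already assigned; error when nothing remains."""
    if "period" not in tab.data.columns:
        if periods is None:
            raise ValueError("a PeriodSet is required (table has no period column)")
        tab = assign_periods(tab, periods)
    if len(tab.data) == 0:
        raise EmptyInputError("no records fall inside the requested periods")
    return tab


def read_occurrences(
    path,
    mapping: FieldMapping | Mapping[str, str] | None = None,
    max_uncertainty: float | None = None,
    drop_missing_uncertainty: bool = False,
) -> OccurrenceTable:
    """Read a CSV of occurrence records and validate it in one step."""
    raw = pd.read_csv(path)
    tab = validate_occurrences(raw, mapping)
    if max_uncertainty is not None:
        tab = filter_by_uncertainty(tab, max_uncertainty, drop_missing_uncertainty)
    return tab


def write_rejects(tab: OccurrenceTable, path) -> None:
    """Write the reject set, with its reject_reason column, to CSV."""
    tab.rejects.to_csv(path, index=False)


def warn_if_geographic(tab: OccurrenceTable) -> None:
    """Warn when coordinates look like lon/lat spanning many degrees.

    Planar Euclidean distances on unprojected coordinates are distorted at
    large latitudinal extents; the heuristics still run, but the nearest
    neighbour index should then be interpreted cautiously.
    """
    x, y = tab.data["x"], tab.data["y"]
    if len(x) == 0:
        return
    looks_lonlat = x.abs().max() <= 180 and y.abs().max() <= 90
    if looks_lonlat and (y.max() - y.min()) > 20:
        warnings.warn(
            "coordinates look geographic (lon/lat) over a >20 degree latitudinal "
            "extent; Euclidean distances in degrees will be distorted",
            stacklevel=3,
        )
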