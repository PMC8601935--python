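"""Geographic coverage and spatial-randomness heuristics.

Two complementary screens live here. ``assess_spatial_cov`` grids the
records at a user resolution and maps either per-period record density or
the number of periods in which each cell was sampled — the question being
whether the same portion of geographic space is sampled through time.
``assess_spatial_bias`` asks how far each (identifier, period) point
pattern departs from complete spatial randomness (CSR) using the nearest
neighbour index (NNI): the ratio of the observed mean nearest-neighbour
distance to its expectation under CSR. Because study regions are rarely
rectangles, the CSR expectation is obtained by simulation — ``nsim``
uniform patterns of equal size are drawn inside the study mask and the
denominator is the mean of their mean nearest-neighbour distances. Index
values below 1 indicate clustering, 1 is random, and the ceiling for a
maximally dispersed (hexagonal-lattice) pattern is about 2.15.

Grid convention: cells are half-open, lower-inclusive,
``[x0 + i*res, x0 + (i+1)*res)``, anchored at the mask origin when a mask
is supplied and otherwise at the coordinate minima snapped down to a
multiple of the resolution. Distances are planar Euclidean in CRS units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import HeuristicResult, OccurrenceTable, PeriodSet, require_periods


# ---------------------------------------------------------------------------
# Study mask: regular in/out grid read from ESRI ASCII text rasters
# ---------------------------------------------------------------------------

@dataclass
class StudyMask:
    """Regular grid of in/out cells delimiting the spatial domain.

    ``grid`` is boolean, row 0 at the top (north), True = inside the study
    area. ``x0, y0`` anchor the lower-left corner; cells are square with
    side ``cell_size``. ``crs`` is an opaque tag carried through to outputs.
    """

    x0: float
    y0: float
    cell_size: float
    grid: np.ndarray
    crs: str = ""
    _in_cells: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("mask cell size must be positive")
        if not self.grid.any():
            raise ValueError("mask has no in-cells")
        rows, cols = np.nonzero(self.grid)
        # lower-left corner of each in-cell, row 0 = top
        ny = self.grid.shape[0]
        xs = self.x0 + cols * self.cell_size
        ys = self.y0 + (ny - 1 - rows) * self.cell_size
        self._in_cells = np.column_stack([xs, ys])

    @property
    def n_in_cells(self) -> int:
        return len(self._in_cells)

    @property
    def area(self) -> float:
        return self.n_in_cells * self.cell_size**2

    @property
    def extent(self) -> tuple[float, float, float, float]:
        ny, nx = self.grid.shape
        return (self.x0, self.x0 + nx * self.cell_size,
                self.y0, self.y0 + ny * self.cell_size)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean in-mask test for an (n, 2) point array."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ny, nx = self.grid.shape
        col = np.floor((pts[:, 0] - self.x0) / self.cell_size).astype(int)
        row_from_bottom = np.floor((pts[:, 1] - self.y0) / self.cell_size).astype(int)
        row = ny - 1 - row_from_bottom
        ok = (col >= 0) & (col < nx) & (row >= 0) & (row < ny)
        out = np.zeros(len(pts), dtype=bool)
        out[ok] = self.grid[row[ok], col[ok]]
        return out

    @classmethod
    def rectangle(cls, x0: float, x1: float, y0: float, y1: float,
                  cell_size: float = 1.0, crs: str = "") -> "StudyMask":
        """All-inside rectangular mask covering [x0, x1] x [y0, y1]."""
        nx = max(1, int(round((x1 - x0) / cell_size)))
        ny = max(1, int(round((y1 - y0) / cell_size)))
        return cls(x0, y0, cell_size, np.ones((ny, nx), dtype=bool), crs)


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Parse an ESRI ASCII grid (.asc): returns (array, header dict).

    Header keys are lower-cased; the array keeps row 0 at the top as in the
    file. NODATA cells become NaN.
    """
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                data_lines.append(line)
    arr = np.loadtxt(data_lines).reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value")
    if nodata is not None:
        arr = np.where(arr == nodata, np.nan, arr)
    return arr, header


def write_ascii_grid(path, arr: np.ndarray, x0: float, y0: float,
                     cell_size: float, nodata: float = -9999.0) -> None:
    arr = np.asarray(arr, dtype=float)
    out = np.where(np.isnan(arr), nodata, arr)
    with open(path, "w") as fh:
        fh.write(f"ncols {arr.shape[1]}\nnrows {arr.shape[0]}\n")
        fh.write(f"xllcorner {x0}\nyllcorner {y0}\ncellsize {cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, out, fmt="%.10g")


def read_mask(path, crs: str = "") -> StudyMask:
    """Read a StudyMask from an ESRI ASCII grid; NODATA/NaN = outside."""
    arr, header = read_ascii_grid(path)
    grid = np.isfinite(arr)
    return StudyMask(header["xllcorner"], header["yllcorner"],
                     header["cellsize"], grid, crs)


# ---------------------------------------------------------------------------
# Gridded spatio-temporal coverage
# ---------------------------------------------------------------------------

def snap_origin(values: np.ndarray, resolution: float) -> float:
    """Lowest multiple of ``resolution`` not exceeding min(values)."""
    return float(np.floor(np.min(values) / resolution) * resolution)


def cell_indices(x: np.ndarray, y: np.ndarray, resolution: float,
                 origin: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Half-open, lower-inclusive cell index of each point."""
    ix = np.floor((np.asarray(x, dtype=float) - origin[0]) / resolution).astype(int)
    iy = np.floor((np.asarray(y, dtype=float) - origin[1]) / resolution).astype(int)
    return ix, iy


@dataclass
class GridSummary:
    """Per-(identifier, period) record counts on a regular grid.

    ``data`` columns: identifier, period, cell_x, cell_y (lower-left cell
    corners), count. Cell sums per group equal the number of assigned
    records for that group — gridding never loses records.
    """

    data: pd.DataFrame
    resolution: float
    origin: tuple[float, float]
    n_periods: int
    mask: StudyMask | None = None

    def periods_sampled(self) -> pd.DataFrame:
        """Per identifier and cell, the number of periods with >= 1 record.

        When a mask is present, in-mask cells never sampled by an
        identifier are reported with 0 so that "surveyed region, no data"
        is distinct from "outside the study area" (cells outside the mask
        are simply absent).
        """
        if self.data.empty:
            return pd.DataFrame(columns=["identifier", "cell_x", "cell_y", "n_periods"])
        tally = (
            self.data.groupby(["identifier", "cell_x", "cell_y"], observed=True)["period"]
            .nunique()
            .reset_index(name="n_periods")
        )
        if self.mask is not None:
            frames = []
            cells = pd.DataFrame(self.mask._in_cells, columns=["cell_x", "cell_y"])
            for ident, sub in tally.groupby("identifier", observed=True):
                merged = cells.merge(sub.drop(columns="identifier"),
                                     on=["cell_x", "cell_y"], how="left")
                merged["n_periods"] = merged["n_periods"].fillna(0).astype(int)
                merged.insert(0, "identifier", ident)
                frames.append(merged)
            tally = pd.concat(frames, ignore_index=True)
        return tally


def grid_counts(
    tab: OccurrenceTable,
    resolution: float,
    periods: PeriodSet | None = None,
    mask: StudyMask | None = None,
) -> GridSummary:
    """Count records per grid cell for every (identifier, period)."""
    if resolution <= 0:
        raise ValueError(f"grid resolution must be positive, got {resolution}")
    tab = require_periods(tab, periods) if len(tab.data) else tab
    df = tab.data
    if mask is not None:
        origin = (mask.x0, mask.y0)
    elif len(df):
        origin = (snap_origin(df["x"].to_numpy(), resolution),
                  snap_origin(df["y"].to_numpy(), resolution))
    else:
        origin = (0.0, 0.0)
    n_periods = len(df["period"].cat.categories) if "period" in df else 0
    if df.empty:
        empty = pd.DataFrame(columns=["identifier", "period", "cell_x", "cell_y", "count"])
        return GridSummary(empty, resolution, origin, n_periods, mask)

    ix, iy = cell_indices(df["x"].to_numpy(), df["y"].to_numpy(), resolution, origin)
    cells = pd.DataFrame({
        "identifier": df["identifier"].to_numpy(),
        "period": df["period"].to_numpy(),
        "cell_x": origin[0] + ix * resolution,
        "cell_y": origin[1] + iy * resolution,
    })
    counts = (
        cells.groupby(["identifier", "period", "cell_x", "cell_y"], observed=True)
        .size()
        .reset_index(name="count")
    )
    return GridSummary(counts, resolution, origin, n_periods, mask)


def assess_spatial_cov(
    tab: OccurrenceTable,
    resolution: float,
    periods: PeriodSet | None = None,
    mask: StudyMask | None = None,
) -> GridSummary:
    """Gridded spatio-temporal coverage: density and periods-sampled maps."""
    return grid_counts(tab, resolution, periods, mask)


# ---------------------------------------------------------------------------
# Nearest neighbour index against a simulated CSR null
# ---------------------------------------------------------------------------

def mean_nn_distance(points: np.ndarray) -> float:
    """Mean Euclidean distance from each point to its nearest other point.

    Duplicate coordinates are legitimate (distance 0). Requires >= 2 points.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 2:
        raise ValueError("mean nearest-neighbour distance needs at least 2 points")
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=2)
    return float(dist[:, 1].mean())


def simulate_random_points(mask: StudyMask, n: int,
                           rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Draw ``n`` points uniformly over the union of the mask's in-cells.

    Cells are equal-area, so a uniform draw picks a cell uniformly and a
    position uniformly within it. Reproducible under a fixed seed.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(rng)
    if n == 0:
        return np.empty((0, 2))
    idx = rng.integers(0, mask.n_in_cells, size=n)
    offsets = rng.random((n, 2)) * mask.cell_size
    return mask._in_cells[idx] + offsets


def expected_csr_nn_distance(area: float, n: int) -> float:
    """Closed-form CSR expectation (1/2)*sqrt(A/n) — valid only for
    unbounded or edge-negligible domains; used as an oracle, not in the
    index itself."""
    return 0.5 * np.sqrt(area / n)


def nearest_neighbour_index(
    points: np.ndarray,
    mask: StudyMask,
    nsim: int = 99,
    ci_level: float = 0.90,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Simulation-based NNI for one point pattern.

    Draws ``nsim`` uniform patterns of equal size inside the mask. The
    index is observed mean NN distance divided by the mean of the simulated
    mean NN distances. The confidence interval is distribution-free:
    empirical quantiles of the per-simulation ratios observed/simulated_i.
    """
    if nsim < 2:
        raise ValueError("nsim must be at least 2")
    if not (0 < ci_level < 1):
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rng = np.random.default_rng(rng)
    observed = mean_nn_distance(pts)
    sims = np.array([
        mean_nn_distance(simulate_random_points(mask, len(pts), rng))
        for _ in range(nsim)
    ])
    ratios = observed / sims
    alpha = (1 - ci_level) / 2
    return {
        "n_points": len(pts),
        "observed": observed,
        "expected": float(sims.mean()),
        "index": float(observed / sims.mean()),
        "ci_low": float(np.quantile(ratios, alpha)),
        "ci_high": float(np.quantile(ratios, 1 - alpha)),
        "simulated": sims,
    }


def assess_spatial_bias(
    tab: OccurrenceTable,
    mask: StudyMask,
    periods: PeriodSet | None = None,
    nsim: int = 99,
    ci_level: float = 0.90,
    seed: int | None = None,
) -> HeuristicResult:
    """Nearest neighbour index per (identifier, period).

    Groups with fewer than two records yield missing values rather than
    errors. Observed duplicate coordinates are kept: a pattern inflated by
    duplicated localities genuinely is more clustered than CSR.
    """
    tab = require_periods(tab, periods)
    rng = np.random.default_rng(seed)
    rows = []
    sims_store: dict[tuple[str, str], np.ndarray] = {}
    period_labels = list(tab.data["period"].cat.categories)
    for ident in tab.identifiers:
        sub_id = tab.data[tab.data["identifier"] == ident]
        for per in period_labels:
            pts = sub_id.loc[sub_id["period"] == per, ["x", "y"]].to_numpy(dtype=float)
            if len(pts) < 2:
                rows.append({"identifier": ident, "period": per, "n_points": len(pts),
                             "observed": np.nan, "expected": np.nan, "index": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan})
                continue
            res = nearest_neighbour_index(pts, mask, nsim, ci_level, rng)
            sims_store[(ident, per)] = res.pop("simulated")
            rows.append({"identifier": ident, "period": per, **res})
    data = pd.DataFrame(rows)
    meta = {
        "heuristic": "spatial_bias", "nsim": nsim, "ci_level": ci_level,
        "seed": seed, "mask_cells": mask.n_in_cells, "mask_area": mask.area,
        "rejected": tab.reject_counts(),
    }
    return HeuristicResult("spatial_bias", data, meta, extras={"simulated": sims_store})
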