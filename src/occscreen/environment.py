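"""Environmental-space bias assessment.

Occurrence data can cover geographic space evenly yet still sample an
unrepresentative slice of *environmental* space (climate, terrain, ...).
This module reduces a multivariate environmental table to principal
components and summarises, per (identifier, period), where the records sit
on a chosen component pair — by default as Gaussian ellipses delimiting
95% of each group's scores, optionally against a background sample that
defines the environmental space available in the domain of interest.

Two interpretations, depending on inputs: with a background sample the
question is whether records are drawn from a representative portion of the
available environmental space (the rotation is fitted on the background
and records are projected into it); without one, only whether the *sampled*
environmental space drifts between periods (rotation fitted on the pooled
occurrence rows, so per-period ellipses share one set of axes and are
comparable).

The PCA operates on the correlation matrix (centred, unit-scaled
variables): environmental layers come in incommensurate units and an
unscaled decomposition would be dominated by the largest-magnitude
variable. Ellipses assume bivariate normality of the scores; when that is
doubtful the raw score points can be plotted instead, and per-period
skewness/kurtosis of the selected scores is reported to help judge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .core import OccurrenceTable, PeriodSet, require_periods
from .spatial import read_ascii_grid


# ---------------------------------------------------------------------------
# Environmental values at record coordinates
# ---------------------------------------------------------------------------

@dataclass
class RasterStack:
    """Aligned single-grid multi-band raster of environmental variables.

    ``bands`` maps variable name to a 2-D float array (row 0 at the top,
    NaN = no data); all bands share origin ``(x0, y0)`` and ``cell_size``.
    """

    bands: dict[str, np.ndarray]
    x0: float
    y0: float
    cell_size: float

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("raster stack needs at least one band")
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) != 1:
            raise ValueError(f"raster bands disagree on grid shape: {shapes}")

    @classmethod
    def from_ascii_grids(cls, paths: dict[str, str]) -> "RasterStack":
        """Load named ESRI ASCII grids; all must share one grid."""
        bands, header0 = {}, None
        for name, path in paths.items():
            arr, header = read_ascii_grid(path)
            if header0 is None:
                header0 = header
            elif any(abs(header[k] - header0[k]) > 1e-9
                     for k in ("xllcorner", "yllcorner", "cellsize", "ncols", "nrows")):
                raise ValueError(f"raster '{name}' is not aligned with the first band")
            bands[name] = arr
        return cls(bands, header0["xllcorner"], header0["yllcorner"], header0["cellsize"])

    def sample(self, x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
        """Band values at the cell containing each point; NaN outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        first = next(iter(self.bands.values()))
        ny, nx = first.shape
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = ny - 1 - np.floor((y - self.y0) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < nx) & (row >= 0) & (row < ny)
        out = {}
        for name, band in self.bands.items():
            vals = np.full(len(x), np.nan)
            vals[inside] = band[row[inside], col[inside]]
            out[name] = vals
        return pd.DataFrame(out)


def extract_env(tab: OccurrenceTable, rasters: RasterStack) -> pd.DataFrame:
    """Environmental values for each record, aligned by row position.

    Records outside the raster extent or on no-data cells yield all-NaN
    rows (they stay in place so alignment with the occurrence table holds);
    their count is attached as ``DataFrame.attrs["n_missing"]``.
    """
    env = rasters.sample(tab.data["x"].to_numpy(), tab.data["y"].to_numpy())
    env.attrs["n_missing"] = int(env.isna().any(axis=1).sum())
    return env


# ---------------------------------------------------------------------------
# PCA of environmental space
# ---------------------------------------------------------------------------

@dataclass
class Ellipse:
    """Gaussian coverage ellipse on a 2-D score plane.

    Boundary = {center + r L u : |u| = 1}, L Lᵀ = cov, r² the chi-square
    (2 df) quantile at ``level``. A singular covariance gives a flat or
    point ellipse — returned, with a warning, rather than raised.
    """

    center: np.ndarray
    cov: np.ndarray
    level: float
    radius: float

    def boundary(self, n: int = 200) -> np.ndarray:
        t = np.linspace(0, 2 * np.pi, n)
        circle = np.column_stack([np.cos(t), np.sin(t)])
        vals, vecs = np.linalg.eigh(self.cov)
        L = vecs @ np.diag(np.sqrt(np.clip(vals, 0, None)))
        return self.center + self.radius * circle @ L.T

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points) - self.center
        cov_inv = np.linalg.pinv(self.cov)
        d2 = np.einsum("ij,jk,ik->i", pts, cov_inv, pts)
        return d2 <= self.radius**2


def ellipse_params(scores: np.ndarray, level: float = 0.95) -> Ellipse:
    """Fit the Gaussian ellipse enclosing ``level`` of a 2-D score cloud.

    Under bivariate normality the squared Mahalanobis distance is
    chi-square with 2 degrees of freedom, so the boundary radius is the
    square root of that distribution's ``level`` quantile.
    """
    pts = np.atleast_2d(np.asarray(scores, dtype=float))
    if pts.shape[1] != 2:
        raise ValueError("ellipse_params expects exactly 2 score columns")
    if len(pts) < 3:
        raise ValueError("ellipse needs at least 3 rows")
    if not (0 < level < 1):
        raise ValueError(f"level must be in (0, 1), got {level}")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    if np.linalg.matrix_rank(cov) < 2:
        warnings.warn("degenerate (singular-covariance) ellipse", stacklevel=2)
    radius = float(np.sqrt(stats.chi2.ppf(level, df=2)))
    return Ellipse(center=center, cov=cov, level=level, radius=radius)


@dataclass
class EnvSpace:
    """PCA of environmental space with per-(identifier, period) ellipses."""

    loadings: pd.DataFrame            # variables x components
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame              # identifier, period, PC1..PCk
    background_scores: pd.DataFrame | None
    components: tuple[int, int]
    ellipses: dict = field(default_factory=dict)   # (identifier, period) -> Ellipse
    background_ellipse: Ellipse | None = None
    meta: dict = field(default_factory=dict)


def _fit_rotation(X: np.ndarray, var_names: list[str]):
    """Correlation-matrix PCA with a deterministic sign convention."""
    scaler = StandardScaler().fit(X)
    if np.any(scaler.var_ == 0) or np.any(~np.isfinite(scaler.var_)):
        keep = (scaler.var_ > 0) & np.isfinite(scaler.var_)
        dropped = [v for v, k in zip(var_names, keep) if not k]
        warnings.warn(f"dropping zero-variance variable(s): {dropped}", stacklevel=3)
        var_names = [v for v, k in zip(var_names, keep) if k]
        X = X[:, keep]
        scaler = StandardScaler().fit(X)
    if X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 non-degenerate variables")
    pca = PCA(n_components=X.shape[1]).fit(scaler.transform(X))
    comps = pca.components_            # components x variables
    # sign convention: the largest-magnitude loading of each component is positive
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] *= -1
    pca.components_ = comps
    return scaler, pca, var_names


def fit_pca(
    env: pd.DataFrame,
    background: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray | None, np.ndarray]:
    """Correlation-matrix PCA of environmental variables.

    With a background table the rotation is fitted on the background and
    occurrence rows are projected into that space; otherwise on the pooled
    occurrence rows. Rows with any missing variable are excluded from the
    fit and get NaN scores.

    Returns ``(loadings, variance_ratio, scores, background_scores,
    complete_row_mask)``; loadings are a variables x components frame.
    """
    var_names = list(env.columns)
    if background is not None and list(background.columns) != var_names:
        raise ValueError("background columns must match the occurrence env columns")

    complete = env.notna().all(axis=1).to_numpy()
    X = env.loc[complete].to_numpy(dtype=float)
    if len(X) < 3:
        raise ValueError("PCA needs at least 3 complete environmental rows")

    if background is not None:
        bg_complete = background.notna().all(axis=1).to_numpy()
        B = background.loc[bg_complete].to_numpy(dtype=float)
        if len(B) < 3:
            raise ValueError("background needs at least 3 complete rows")
        scaler, pca, kept = _fit_rotation(B, var_names)
        keep_idx = [var_names.index(v) for v in kept]
        bg_scores = pca.transform(scaler.transform(B[:, keep_idx]))
        occ_scores_c = pca.transform(scaler.transform(X[:, keep_idx]))
    else:
        scaler, pca, kept = _fit_rotation(X, var_names)
        keep_idx = [var_names.index(v) for v in kept]
        bg_scores = None
        occ_scores_c = pca.transform(scaler.transform(X[:, keep_idx]))

    k = pca.n_components_
    scores = np.full((len(env), k), np.nan)
    scores[complete] = occ_scores_c
    loadings = pd.DataFrame(
        pca.components_.T, index=kept, columns=[f"PC{i+1}" for i in range(k)]
    )
    return loadings, pca.explained_variance_ratio_, scores, bg_scores, complete


def assess_env_bias(
    tab: OccurrenceTable,
    env: pd.DataFrame,
    background: pd.DataFrame | None = None,
    periods: PeriodSet | None = None,
    components: tuple[int, int] = (1, 2),
    level: float = 0.95,
    as_points: bool = False,
) -> EnvSpace:
    """Map occurrence records in reduced environmental space per period.

    ``env`` must align row-by-row with ``tab.data``. Ellipses (or, with
    ``as_points``, just the scores) are produced per (identifier, period)
    on the requested component pair, plus one for the background when
    supplied. Groups with fewer than 3 complete rows get no ellipse.
    """
    tab = require_periods(tab, periods)
    if len(env) != len(tab.data):
        raise ValueError(
            f"env table has {len(env)} rows but the period-assigned occurrence "
            f"table has {len(tab.data)}; align them before calling"
        )
    loadings, evr, scores, bg_scores, complete = fit_pca(env, background)
    k = loadings.shape[1]
    c1, c2 = components
    if not (1 <= c1 <= k and 1 <= c2 <= k):
        raise ValueError(f"requested components {components} exceed available 1..{k}")

    score_df = pd.DataFrame(scores, columns=loadings.columns)
    score_df.insert(0, "period", tab.data["period"].to_numpy())
    score_df.insert(0, "identifier", tab.data["identifier"].to_numpy())

    pair = [f"PC{c1}", f"PC{c2}"]
    ellipses: dict = {}
    shape_stats = []
    if not as_points:
        for (ident, per), sub in score_df.groupby(["identifier", "period"], observed=True):
            pts = sub[pair].dropna().to_numpy()
            if len(pts) >= 3:
                ellipses[(ident, str(per))] = ellipse_params(pts, level)
            for comp in pair:
                vals = sub[comp].dropna()
                if len(vals) >= 3:
                    shape_stats.append({
                        "identifier": ident, "period": str(per), "component": comp,
                        "skewness": float(stats.skew(vals)),
                        "kurtosis": float(stats.kurtosis(vals)),
                    })

    bg_df = None
    bg_ellipse = None
    if bg_scores is not None:
        bg_df = pd.DataFrame(bg_scores, columns=loadings.columns)
        if not as_points and len(bg_df) >= 3:
            bg_ellipse = ellipse_params(bg_df[pair].to_numpy(), level)

    missing_per_period = (
        pd.DataFrame({"period": tab.data["period"].to_numpy(),
                      "missing_env": ~complete})
        .groupby("period", observed=False)["missing_env"].sum().to_dict()
    )
    meta = {
        "heuristic": "env_bias",
        "interpretation": ("representativeness of available environmental space"
                           if background is not None
                           else "stability of the sampled environmental space"),
        "scaling": "correlation (centred, unit variance)",
        "rotation_source": "background" if background is not None else "pooled occurrences",
        "level": level, "as_points": as_points, "components": components,
        "missing_env_rows_per_period": {str(k_): int(v) for k_, v in missing_per_period.items()},
        "score_shape": pd.DataFrame(shape_stats),
        "rejected": tab.reject_counts(),
    }
    return EnvSpace(loadings, evr, score_df, bg_df, (c1, c2),
                    ellipses, bg_ellipse, meta)
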