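"""Figures and reports for heuristic results.

Every plotting function writes an image *and* the exact tidy CSV it
renders, side by side with the same stem — the figure is for eyeballing,
the CSV for re-plotting or downstream analysis. ``plot_heuristic``
dispatches on the result type; ``write_report`` bundles a directory of
results into a single markdown document.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import HeuristicResult
from .environment import EnvSpace
from .spatial import GridSummary


def _save_pair(fig, data: pd.DataFrame, stem: Path) -> tuple[Path, Path]:
    png = stem.with_suffix(".png")
    csv = stem.with_suffix(".csv")
    fig.savefig(png, dpi=150, bbox_inches="tight")
    plt.close(fig)
    data.to_csv(csv, index=False)
    return png, csv


def _value_column(data: pd.DataFrame) -> str:
    for col in ("normalized", "proportion", "index", "count"):
        if col in data.columns:
            return col
    raise ValueError(f"no plottable value column in {list(data.columns)}")


def plot_series(res: HeuristicResult, stem: str | Path) -> tuple[Path, Path]:
    """Time-series plot: one line per identifier, one x-tick per period."""
    data = res.data
    if data.empty:
        raise ValueError(f"empty result for heuristic {res.name!r}")
    col = _value_column(data)
    periods = list(pd.unique(data["period"]))
    fig, ax = plt.subplots(figsize=(7, 4))
    for ident, sub in data.groupby("identifier", observed=True):
        sub = sub.set_index("period").reindex(periods)
        ax.plot(range(len(periods)), sub[col], marker="o", label=str(ident))
    ax.set_xticks(range(len(periods)), periods, rotation=45, ha="right")
    ax.set_xlabel("period")
    ax.set_ylabel(col)
    ax.set_title(res.name.replace("_", " "))
    ax.legend(title="identifier")
    return _save_pair(fig, data, Path(stem))


def plot_nni(res: HeuristicResult, stem: str | Path) -> tuple[Path, Path]:
    """NNI per period with its confidence ribbon and the CSR line at 1."""
    data = res.data
    if data.empty:
        raise ValueError("empty spatial-bias result")
    periods = list(pd.unique(data["period"]))
    fig, ax = plt.subplots(figsize=(7, 4))
    xs = np.arange(len(periods))
    for ident, sub in data.groupby("identifier", observed=True):
        sub = sub.set_index("period").reindex(periods)
        ax.plot(xs, sub["index"], marker="o", label=str(ident))
        ax.fill_between(xs, sub["ci_low"], sub["ci_high"], alpha=0.2)
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xticks(xs, periods, rotation=45, ha="right")
    ax.set_xlabel("period")
    ax.set_ylabel("nearest neighbour index")
    ax.set_title("spatial bias (NNI, <1 clustered, >1 dispersed)")
    ax.legend(title="identifier")
    return _save_pair(fig, data, Path(stem))


def _cell_image(sub: pd.DataFrame, res: float, value_col: str):
    """Dense array + extent from sparse lower-left cell corners."""
    cx, cy = sub["cell_x"].to_numpy(), sub["cell_y"].to_numpy()
    gx0, gy0 = cx.min(), cy.min()
    nx = int(round((cx.max() - gx0) / res)) + 1
    ny = int(round((cy.max() - gy0) / res)) + 1
    img = np.full((ny, nx), np.nan)
    ix = np.round((cx - gx0) / res).astype(int)
    iy = np.round((cy - gy0) / res).astype(int)
    img[iy, ix] = sub[value_col].to_numpy()
    extent = (gx0, gx0 + nx * res, gy0, gy0 + ny * res)
    return img, extent


def plot_coverage(
    gs: GridSummary, stem: str | Path, mode: str = "density"
) -> tuple[Path, Path]:
    """Spatial coverage maps.

    ``mode="density"``: per-identifier rows of per-period record-count
    maps. ``mode="periods"``: one periods-sampled map per identifier,
    legend capped at the number of periods.
    """
    if mode not in ("density", "periods"):
        raise ValueError(f"mode must be 'density' or 'periods', got {mode!r}")
    if gs.data.empty:
        raise ValueError("empty grid summary")
    res = gs.resolution
    if mode == "periods":
        tally = gs.periods_sampled()
        idents = sorted(tally["identifier"].unique())
        fig, axes = plt.subplots(1, len(idents), figsize=(5 * len(idents), 4),
                                 squeeze=False)
        for ax, ident in zip(axes[0], idents):
            sub = tally[tally["identifier"] == ident]
            img, extent = _cell_image(sub, res, "n_periods")
            im = ax.imshow(img, origin="lower", extent=extent,
                           vmin=0, vmax=gs.n_periods, interpolation="nearest")
            ax.set_title(str(ident))
            fig.colorbar(im, ax=ax, label="periods sampled")
        return _save_pair(fig, tally, Path(stem))

    idents = sorted(gs.data["identifier"].unique())
    periods = list(pd.unique(gs.data["period"]))
    fig, axes = plt.subplots(len(idents), len(periods),
                             figsize=(3 * len(periods), 3 * len(idents)),
                             squeeze=False)
    vmax = gs.data["count"].max()
    for i, ident in enumerate(idents):
        for j, per in enumerate(periods):
            ax = axes[i][j]
            sub = gs.data[(gs.data["identifier"] == ident) & (gs.data["period"] == per)]
            if sub.empty:
                ax.set_axis_off()
                continue
            img, extent = _cell_image(sub, res, "count")
            ax.imshow(img, origin="lower", extent=extent, vmin=0, vmax=vmax,
                      interpolation="nearest")
            if i == 0:
                ax.set_title(str(per), fontsize=9)
            if j == 0:
                ax.set_ylabel(str(ident), fontsize=9)
    return _save_pair(fig, gs.data, Path(stem))


def plot_env_space(es: EnvSpace, stem: str | Path) -> tuple[Path, Path]:
    """PC-plane view: per-(identifier, period) ellipses or score points."""
    c1, c2 = es.components
    pair = [f"PC{c1}", f"PC{c2}"]
    fig, ax = plt.subplots(figsize=(6, 6))
    if es.background_scores is not None:
        ax.scatter(es.background_scores[pair[0]], es.background_scores[pair[1]],
                   s=4, c="lightgray", label="background")
        if es.background_ellipse is not None:
            b = es.background_ellipse.boundary()
            ax.plot(b[:, 0], b[:, 1], c="gray", ls="--", label="background ellipse")
    if es.ellipses:
        for (ident, per), ell in es.ellipses.items():
            b = ell.boundary()
            ax.plot(b[:, 0], b[:, 1], label=f"{ident} {per}")
    else:
        for (ident, per), sub in es.scores.groupby(["identifier", "period"],
                                                   observed=True):
            ax.scatter(sub[pair[0]], sub[pair[1]], s=6, label=f"{ident} {per}")
    evr = es.explained_variance_ratio
    ax.set_xlabel(f"{pair[0]} ({evr[c1-1]:.0%} var)")
    ax.set_ylabel(f"{pair[1]} ({evr[c2-1]:.0%} var)")
    ax.set_title("environmental space")
    ax.legend(fontsize=7, loc="best")
    return _save_pair(fig, es.scores, Path(stem))


def plot_heuristic(result, stem: str | Path, **options) -> tuple[Path, Path]:
    """Render any heuristic result to an image + its underlying CSV."""
    if isinstance(result, GridSummary):
        return plot_coverage(result, stem, **options)
    if isinstance(result, EnvSpace):
        return plot_env_space(result, stem, **options)
    if isinstance(result, HeuristicResult):
        if result.name == "spatial_bias":
            return plot_nni(result, stem)
        return plot_series(result, stem)
    raise TypeError(f"cannot plot object of type {type(result).__name__}")


def write_report(outdir: str | Path, entries: list[dict],
                 title: str = "Occurrence-data bias screening report") -> Path:
    """Assemble a markdown report from plotted heuristics.

    ``entries`` are dicts with keys ``name``, ``png``, ``csv`` and
    optionally ``meta`` (JSON-serialisable options/drop counts).
    """
    outdir = Path(outdir)
    lines = [f"# {title}", ""]
    for e in entries:
        lines.append(f"## {e['name'].replace('_', ' ')}")
        lines.append("")
        lines.append(f"![{e['name']}]({Path(e['png']).name})")
        lines.append("")
        lines.append(f"Data: [{Path(e['csv']).name}]({Path(e['csv']).name})")
        if e.get("meta"):
            meta = {k: v for k, v in e["meta"].items()
                    if isinstance(v, (str, int, float, bool, dict, list, type(None)))}
            lines.append("")
            lines.append("```json")
            lines.append(json.dumps(meta, indent=2, default=str))
            lines.append("```")
        lines.append("")
    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path
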