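"""Synthetic occurrence datasets with controllable, known biases.

The generators here serve two purposes. ``gen_unbiased`` produces the
reference dataset every heuristic should judge "clean": coordinates
uniform over the study extent (CSR), years uniform over the range, every
record identified to species level, and species drawn in proportion to a
fixed commonness structure — the behaviour of an idealised recording
scheme free of the biases this package screens for. ``gen_biased``
perturbs that scheme one mechanism at a time (spatial clustering around
hotspots, decaying identification rates, rare-species oversampling, an
environmental drift in where sampling happens), giving adversarial
datasets with a known direction of effect for each heuristic.

Species commonness follows a geometric rank-abundance series — a few
common species, a long tail of rare ones — the canonical shape of real
assemblages, so the rarity heuristic sees realistic contrast.

Every generator is a pure function of its configuration, whose seed is
mandatory: the same config yields byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import OccurrenceTable, PeriodSet, validate_occurrences
from .spatial import StudyMask, simulate_random_points


@dataclass
class SynthConfig:
    """Parameters of the synthetic recording scheme.

    Defaults mirror a typical multi-decade aggregated download: two
    identifier groups of 2,500 records each, seven decadal periods over
    1950-2019, a 100x100-unit square extent, and a 50-species pool whose
    geometric commonness weights (ratio 0.9) span roughly two orders of
    magnitude. Bias knobs are all off by default; ``gen_biased`` requires
    at least one to be active.
    """

    extent: tuple[float, float, float, float] = (0.0, 100.0, 0.0, 100.0)
    mask: StudyMask | None = None
    year_range: tuple[int, int] = (1950, 2019)
    n_species: int = 50
    commonness_decay: float = 0.9
    groups: dict[str, int] = field(default_factory=lambda: {"group_1": 2500, "group_2": 2500})
    uncertainty: float = 100.0
    seed: int = 0
    # bias knobs (gen_biased)
    n_clusters: int | None = None          # spatial clustering: number of hotspots
    cluster_sd: float = 2.0                # hotspot spread, extent units
    id_decay: tuple[float, float] | None = None   # P(identified) at first/last year
    rarity_exponent: float | None = None   # 0 = none; 1 = flat; >1 inverts abundance
    env_shift: float | None = None         # fraction of x-extent drifted by last year

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.groups.values()):
            raise ValueError("group record counts must be non-negative")
        if self.n_species < 1:
            raise ValueError("need at least one species")
        if not (0 < self.commonness_decay <= 1):
            raise ValueError("commonness_decay must be in (0, 1]")
        if self.id_decay is not None and not all(0 <= p <= 1 for p in self.id_decay):
            raise ValueError("id_decay probabilities must be in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @property
    def species_weights(self) -> np.ndarray:
        w = self.commonness_decay ** np.arange(self.n_species)
        return w / w.sum()

    def species_names(self) -> np.ndarray:
        width = len(str(self.n_species))
        return np.array([f"species_{i+1:0{width}d}" for i in range(self.n_species)])


def decadal_periods(first: int = 1950, last: int = 2019) -> PeriodSet:
    """The standard seven-decade period set used throughout the examples."""
    return PeriodSet.decadal(first, last)


def _uniform_points(cfg: SynthConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.mask is not None:
        return simulate_random_points(cfg.mask, n, rng)
    x0, x1, y0, y1 = cfg.extent
    return np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])


def _assemble(cfg: SynthConfig, frames: list[pd.DataFrame]) -> OccurrenceTable:
    raw = pd.concat(frames, ignore_index=True)
    return validate_occurrences(raw)


def gen_unbiased(cfg: SynthConfig) -> OccurrenceTable:
    """Reference dataset free of the screened biases.

    CSR coordinates, uniform years, full species-level identification,
    constant spatial uncertainty, species sampled proportionally to their
    commonness weights. Requesting zero records yields an empty table.
    """
    rng = np.random.default_rng(cfg.seed)
    frames = []
    names = cfg.species_names()
    for group, n in cfg.groups.items():
        pts = _uniform_points(cfg, n, rng)
        frames.append(pd.DataFrame({
            "species": names[rng.choice(cfg.n_species, n, p=cfg.species_weights)],
            "x": pts[:, 0],
            "y": pts[:, 1],
            "year": rng.integers(cfg.year_range[0], cfg.year_range[1] + 1, n),
            "spatialUncertainty": cfg.uncertainty,
            "identifier": group,
        }))
    if not frames or sum(cfg.groups.values()) == 0:
        empty = pd.DataFrame(columns=["species", "x", "y", "year",
                                      "spatialUncertainty", "identifier"])
        return validate_occurrences(empty)
    return _assemble(cfg, frames)


def gen_biased(cfg: SynthConfig) -> OccurrenceTable:
    """Dataset with one or more known bias mechanisms switched on.

    * ``n_clusters`` — records scatter around that many uniformly placed
      hotspots (a Thomas-like parent/offspring process) instead of CSR;
      drives the nearest neighbour index below 1.
    * ``id_decay=(p0, p1)`` — the probability a record is identified to
      species falls linearly from p0 (first year) to p1 (last year).
    * ``rarity_exponent`` g — species sampling weights become w**(1-g):
      g=0 reproduces proportional sampling, g=1 samples all species
      equally (rare species over-recorded), g>1 inverts the abundance
      ranking; weakens the count-commonness congruence.
    * ``env_shift`` s — the sampled x-window drifts towards +x by s of
      the extent width over the year range, displacing later periods
      along any x-correlated environmental gradient.
    """
    active = [cfg.n_clusters, cfg.id_decay, cfg.rarity_exponent, cfg.env_shift]
    if all(a is None for a in active):
        raise ValueError("gen_biased requires at least one active bias knob")
    rng = np.random.default_rng(cfg.seed)
    names = cfg.species_names()
    y_first, y_last = cfg.year_range
    span = max(1, y_last - y_first)
    x0, x1, y0, y1 = cfg.extent

    weights = cfg.species_weights
    if cfg.rarity_exponent is not None:
        w = weights ** (1.0 - cfg.rarity_exponent)
        weights = w / w.sum()

    frames = []
    for group, n in cfg.groups.items():
        years = rng.integers(y_first, y_last + 1, n)
        frac = (years - y_first) / span

        if cfg.n_clusters is not None:
            parents = _uniform_points(cfg, cfg.n_clusters, rng)
            assignment = rng.integers(0, cfg.n_clusters, n)
            pts = parents[assignment] + rng.normal(0, cfg.cluster_sd, (n, 2))
            pts[:, 0] = np.clip(pts[:, 0], x0, np.nextafter(x1, x0))
            pts[:, 1] = np.clip(pts[:, 1], y0, np.nextafter(y1, y0))
        elif cfg.env_shift is not None:
            width = x1 - x0
            drift = cfg.env_shift * width * frac
            window = width * (1 - cfg.env_shift)
            xs = x0 + drift + rng.random(n) * window
            pts = np.column_stack([xs, rng.uniform(y0, y1, n)])
        else:
            pts = _uniform_points(cfg, n, rng)

        species = names[rng.choice(cfg.n_species, n, p=weights)].astype(object)
        if cfg.id_decay is not None:
            p0, p1 = cfg.id_decay
            p_ident = p0 + (p1 - p0) * frac
            species[rng.random(n) >= p_ident] = None

        frames.append(pd.DataFrame({
            "species": species, "x": pts[:, 0], "y": pts[:, 1], "year": years,
            "spatialUncertainty": cfg.uncertainty, "identifier": group,
        }))
    return _assemble(cfg, frames)


def gen_hex_lattice(extent: tuple[float, float, float, float], n: int) -> np.ndarray:
    """Hexagonal lattice of about ``n`` points filling ``extent``.

    The maximally dispersed arrangement at a given density: every point's
    nearest neighbours sit at exactly the lattice spacing d, chosen so the
    per-point cell area (sqrt(3)/2) d^2 tiles the extent with ~n points.
    """
    if n < 3:
        raise ValueError("a lattice needs at least 3 points")
    x0, x1, y0, y1 = extent
    area = (x1 - x0) * (y1 - y0)
    d = np.sqrt(2 * area / (np.sqrt(3) * n))
    h = d * np.sqrt(3) / 2
    pts = []
    row = 0
    y = y0 + h / 2
    while y < y1:
        xs = np.arange(x0 + d / 2 + (row % 2) * d / 2, x1, d)
        pts.append(np.column_stack([xs, np.full(len(xs), y)]))
        y += h
        row += 1
    return np.vstack(pts)


#: The six worked-example rows shipped as an inline fixture: leaf-nosed bat
#: records in lon/lat with metre uncertainties, all from one family.
_EXAMPLE_ROWS = [
    ("Anoura caudifer",        -65.4000, -17.0667, 1993, 11839, "Phyllostomidae"),
    ("Carollia perspicillata", -65.5497, -17.1072, 1993,  1043, "Phyllostomidae"),
    ("Carollia perspicillata", -65.4000, -17.0667, 1993, 11839, "Phyllostomidae"),
    ("Sturnira erythromos",    -65.8692, -17.2119, 1993,  1043, "Phyllostomidae"),
    ("Platyrrhinus dorsalis",  -65.5497, -17.1072, 1993,  1043, "Phyllostomidae"),
    ("Artibeus lituratus",     -56.0000, -25.4667, 1995, 11010, "Phyllostomidae"),
]


def example_records() -> pd.DataFrame:
    """Six-row bat-occurrence example table (raw, pre-validation form)."""
    return pd.DataFrame(
        _EXAMPLE_ROWS,
        columns=["species", "x", "y", "year", "spatialUncertainty", "identifier"],
    )
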