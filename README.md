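# occscreen

Screening heuristics for sampling bias in species occurrence data.

Occurrence records aggregated from museums, atlases and citizen-science
portals are convenience samples, not probability samples: recording effort
concentrates on accessible places, attractive or rare species, and recent
years. Before such data are used to estimate species' distributions or
their trends, they should be screened for bias. `occscreen` computes a
suite of per-period, per-group diagnostics across the four dimensions in
which occurrence data can mislead — taxonomic, temporal, spatial and
environmental — and returns each as a tidy table plus a figure. The
outputs are ancillary evidence to be read with expert judgement; none of
them is a pass/fail verdict.

It is aimed at ecologists and biodiversity-informatics practitioners
working with Darwin-Core-style tables (e.g. GBIF downloads).

## The heuristics

All heuristics operate on a six-field table — `species`, `x`, `y`, `year`,
`spatialUncertainty`, `identifier` — after splitting the records into
user-defined year periods and grouping by the `identifier` label (taxon,
dataset, country, …):

| heuristic | dimension | statistic per (identifier, period) |
|---|---|---|
| `assess_record_number` | temporal | record count *n* (optionally peak-normalised) |
| `assess_species_number` | taxonomic | distinct species count |
| `assess_species_id` | taxonomic | proportion (or count) of records identified to species |
| `assess_rarity_bias` | taxonomic | congruence of per-species count *n_s* with commonness *c_s* |
| `assess_spatial_cov` | spatial×temporal | gridded record density / periods-sampled maps |
| `assess_spatial_bias` | spatial | nearest neighbour index (NNI) vs a simulated CSR null |
| `assess_env_bias` | environmental | PCA score ellipses per period, optionally vs background |

Two statistics carry the interpretive weight:

* **Nearest neighbour index.** With observed mean nearest-neighbour
  distance d̄_obs and m records, the package simulates `nsim` uniform
  patterns of m points inside a study mask and reports
  NNI = d̄_obs / mean(d̄_sim). Simulation replaces the Clark–Evans
  closed form ½√(A/m) because real study regions have irregular
  boundaries. NNI < 1 indicates clustering, 1 spatial randomness, and the
  ceiling ≈ 2.15 corresponds to a maximally dispersed hexagonal
  arrangement. A distribution-free 90 % interval comes from the empirical
  quantiles of d̄_obs / d̄_sim,i.

* **Rarity-recording congruence.** Commonness c_s is the number of grid
  cells occupied by species s (a regional-occupancy proxy). If recording
  were proportional to commonness, n_s would be linear in c_s; the index
  is either the r² of the OLS regression of n_s on c_s (0 = high bias,
  1 = none) or the Pearson correlation of the two.

Environmental bias uses a correlation-matrix PCA of per-record
environmental variables; per-period 95 % Gaussian ellipses (radius²
= χ²₂(0.95)) show whether sampling drifts through environmental space, or
— when a background sample defines the available space — whether it is
representative at all.

## Worked example

Generate a synthetic dataset with two deliberate pathologies — spatially
clustered sampling and identification rates decaying from 100 % to 60 %
across 1950–2019 — then screen it:

```python
import occscreen as oc
from occscreen.synth import SynthConfig

tab = oc.gen_biased(SynthConfig(seed=42, id_decay=(1.0, 0.6), n_clusters=25))
tab = oc.assign_periods(tab, oc.decadal_periods())

sid = oc.assess_species_id(tab)
print(sid.data[sid.data.identifier == "group_1"])

mask = oc.StudyMask.rectangle(0, 100, 0, 100, cell_size=10)
nni = oc.assess_spatial_bias(tab, mask, nsim=99, seed=1)
print(nni.data[nni.data.identifier == "group_1"])
```

Output (abridged):

```text
identifier    period  proportion
   group_1 1950-1959    0.969780
   group_1 1980-1989    0.806878
   group_1 2010-2019    0.597059

   period  n_points  index  ci_low  ci_high
1950-1959       364  0.383   0.369    0.400
1980-1989       378  0.383   0.364    0.402
2010-2019       340  0.407   0.387    0.426
```

Both injected biases are flagged: the species-level identification
proportion falls monotonically from 0.97 to 0.60, and the NNI sits far
below 1 (≈ 0.39, CI excluding 1) in every period — the hotspot-clustered
records are much more aggregated than a random pattern of the same
density. An unbiased dataset (`gen_unbiased`) instead yields proportions
of exactly 1.0 and NNI ≈ 1 with intervals covering 1.

The same analyses run from the shell:

```sh
occscreen synth --biased --clusters 25 --id-decay 1.0 0.6 --seed 42 --out occ.csv
occscreen all --input occ.csv --periods 1950-1959,1960-1969,1970-1979,1980-1989,1990-1999,2000-2009,2010-2019 \
    --outdir screening_out
```

which writes one CSV + PNG pair per heuristic, a `rejects.csv`, a
markdown report, and a `run_log.yaml` from which the run can be
reproduced exactly.

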