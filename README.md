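# spatialphylo

Spatial phylogenetics of endemism: locating evolutionary **cradles**
(centres of neoendemism) and **museums** (centres of palaeoendemism) of a
flora or fauna from three ingredients — a dated phylogeny, georeferenced
occurrence records, and (optionally) environmental rasters.

The package is aimed at biogeographers and conservation scientists who
want a scriptable, testable alternative to GUI spatial-phylogenetics
workflows: grid occurrences, compute per-cell diversity and endemism
metrics, assess them against a margin-preserving null model, delimit
phyloregions from phylogenetic turnover, and contrast the environments of
the resulting hotspot classes.

## The metrics

For a grid cell *c* with branch set *B(c)* (every branch on the tip-to-root
path of any species present), branch lengths *L_b* and branch ranges *R_b*
(number of cells a branch occupies):

- **PD** (Faith) `= Σ_{b∈B(c)} L_b` — summed branch length.
- **PE** (Rosauer) `= Σ_{b∈B(c)} L_b / R_b` — branch length weighted by
  inverse range; across all cells PE sums exactly to the total tree length.
- **WE** `= Σ_{species in c} 1/range`, **CWE** `= WE / SR` — species-level
  analogues (SR = richness).
- **RPD, RPE** — PD or PE divided by the same quantity on a *comparison
  tree* with identical topology whose branches all share the average
  length. RPD > 1 flags a concentration of longer-than-average branches.
- **RWT** — range-weighted phylogenetic turnover between cells *i, j*:
  with weights `w_b = L_b/R_b`, `D = 1 − 2A/(2A+B+C)` where *A* is shared
  weight and *B, C* the weights unique to either cell. UPGMA clustering of
  *D* yields phyloregions.

Significance comes from a curveball (fixed row/column sums) randomization
of the cells × species matrix: each observed metric is ranked against 999
null draws with the half-tie convention, and cells with RPE rank > 0.99
are classified palaeoendemic (museums: long range-restricted branches),
rank < 0.01 neoendemic (cradles: short range-restricted branches). A
two-step CANAPE-style categorical mode (`neo/palaeo/mixed/super`) is also
available.

## Worked example

Generate a synthetic study system with planted structure — short-branch
radiations confined to a cool highland block, long isolated lineages in
warm lowland refuges — and run the full pipeline on it:

```sh
spatialphylo simulate --seed 1 --out scratch/sim
spatialphylo run \
    --tree scratch/sim/tree.nwk \
    --occurrences scratch/sim/occurrences.csv \
    --raster elevation=scratch/sim/elevation.asc \
    --raster temperature=scratch/sim/temperature.asc \
    --out scratch/run --seed 1 --n-rand 999 --k 3
```

The run prints (abridged):

```
spatialphylo run summary
========================
cells analysed: 357
species matched to tree: 64 (unmatched: 0)
tree: 64 tips, 111 branches, total length 30.0289
randomizations: 999 (mode paper, seed 1)

endemism classes:
      neo: 10
   palaeo: 3
       ns: 344

phyloregion sizes:
  region 1: 354 cells
  region 2: 1 cells
  region 3: 2 cells

environment contrasts (neo vs palaeo, Welch's t-test):
  variable               t        df             p
  elevation        588.383       6.3     4.331e-16
  temperature     -206.093      10.7     1.333e-20
```

Reading: the randomization flags 10 cells as cradles and 3 as museums
(the planted highland radiations and lowland refuges, plus a few cells
reached by the same restricted branches); the turnover clustering
separates the two planted endemism centres from the background region;
and the recovered cradles sit ~2300 m higher and ~14 °C colder than the
museums, with Welch tests rejecting decisively. Full per-cell tables
(`cell_metrics.csv`, `significance.csv`), GeoJSON maps, the turnover
matrix and the dendrogram are written to the output directory.

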