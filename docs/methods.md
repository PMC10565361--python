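# Methods

This note documents the models, conventions and design choices behind
`spatialphylo`, in the spirit of a statistical-software methods appendix.
It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Trees and branch bookkeeping

A phylogeny is stored as parallel node arrays; a *branch* is the edge above
a non-root node, so a tree with *n* nodes has *n − 1* branches and the
root's subtending edge (if the Newick carries one) is excluded from the
branch count and the total length. This matches the convention under which
Faith's PD of an assemblage is the summed length of all edges on the
tip-to-root paths of the species present. Zero-length branches are legal
and contribute zero to every metric.

Pruning to a taxon set collapses unary nodes by summing child and parent
lengths; a root left with a single child is replaced by that child (the
accumulated stem is dropped, consistently with the root-edge convention).
Total length therefore never increases under pruning. Species names are
matched between tree and occurrences exactly, after trimming whitespace
and replacing underscores with spaces; a match report lists the labels
private to either side.

The RPD/RPE *comparison tree* keeps the topology and assigns every branch
the mean length `total_length / branch_count`, conserving total length.
Some descriptions of the relative metrics speak of a "difference" between
the observed and comparison values; this package computes the **ratio**,
which is the form interpretable against rank thresholds (a cell with
RPD > 1 carries longer-than-average branches) and the form the categorical
neo/palaeo scheme was built on.

## Gridding

Cells are half-open squares `[edge, edge + res)` on the WGS84 graticule,
identified by `(floor(lon/res), floor(lat/res))` — aligned to the (0, 0)
origin rather than the data's bounding box, so cell ids are reproducible
across datasets. A guard of 1e-9 cell-widths absorbs float noise at cell
edges. Only occupied cells are retained; no land/sea mask is applied
(masking is data-driven). Duplicate records of a species in a cell
collapse to one presence while raw record tallies are kept for the
sampling-redundancy index `1 − SR/records`, a proxy for inventory
completeness. At 0.1° a cell is ≈ 11 km × 11 km at the equator (~121 km²).
Regridding by an integer factor takes the union of presences over each
block and sums record counts.

By default all metrics share one taxon set: species absent from the tree
are excluded everywhere (a warning reports the count), so SR/WE/CWE and
the phylogenetic metrics describe the same community matrix.

## Metrics

With branch set *B(c)* of cell *c*, lengths *L_b* and ranges *R_b*:
PD `= Σ L_b`, PE `= Σ L_b/R_b`, WE `= Σ_species 1/range`, CWE `= WE/SR`,
RPD and RPE the ratios to the comparison tree with **identical incidences
and ranges** (only lengths change). Two conservation laws hold exactly and
serve as oracles in the tests: summing PE over all cells returns the total
tree length, and summing WE returns the species count, because a weight
`1/R` is counted exactly `R` times. All per-cell metrics are computed in
one vectorized pass over a dense cells × branches incidence (obtained as a
boolean matrix product of the cells × species matrix with the
species × branches ancestry matrix); per-cell scalar functions exist for
testing.

## Randomization and classification

The null model must hold richness and range size fixed, because PE and RPE
are driven by both; the package uses **curveball trades**: each trade picks
two cells and randomly re-deals the species unique to either between them,
which preserves both margins exactly and, iterated, samples matrices
uniformly from the fixed-margin fill class. The trade count is five times
the number of presences. Observed values are ranked against `n_rand = 999`
null draws with the half-tie convention
`p = (#{null < obs} + 0.5·#{null = obs}) / n_rand`; ties are detected with
a relative tolerance of 1e-9 so recomputed identical values register as
ties. No multiple-testing correction is applied across cells; the run
manifest says so.

Two classification modes:

* **paper** (default): palaeo iff the RPE rank exceeds 0.99, neo iff it
  falls below 0.01, else not significant. These thresholds imply a
  two-tailed α of 0.02.
* **canape**: the two-step categorical scheme — a cell is eligible iff its
  PE on the original *or* comparison tree ranks above 0.95 (one-tailed);
  eligible cells are neo below an RPE rank of 0.025, palaeo above 0.975,
  super if both PE ranks exceed 0.99, otherwise mixed.

High RPE marks an excess of **long** range-restricted branches
(palaeoendemism — a museum); low RPE marks **short** range-restricted
branches (neoendemism — a cradle). One narrative sentence in the source
literature inverts this mapping; the package follows the categorical
method and the figure captions, which agree with each other.

One integer seed drives a `numpy` SeedSequence from which per-draw streams
are derived; results are bit-identical across runs with the same seed and
configuration.

## Turnover and phyloregions

Between-cell dissimilarity uses phylogenetic-endemism weights
`w_b = L_b/R_b` in a Sørensen complement `D = 1 − 2A/(2A + B + C)`
(A shared, B/C unique weight). D is 0 for identical branch composition, 1
for disjoint composition, and is computed for all pairs in one vectorized
pass (the per-pair function is retained for testing). Observed weights are
used; averaging over randomizations is possible upstream but not asserted
as the canonical form. Clustering is average linkage (UPGMA) via SciPy,
the standard choice in phyloregionalization; the linkage is configurable
in principle but only the average form is exposed. Region maps for k
regions come from `cut_tree`, whose cuts are nested: the (k+1)-region map
refines the k-region map. The number of regions is a user parameter (three
primary regions is a common preset, not a hard-coded value).

## Environmental overlay

Rasters are ESRI ASCII grids (plain text, corner- or centre-registered) in
the same geographic coordinates as the cell grid; a cell's value is the
mean of the raster pixels whose centres fall inside it, excluding nodata —
a deterministic stand-in for converting significance grids to points and
sampling rasters at them. Boxplot summaries use linear-interpolation
(type-7) quartiles and 1.5×IQR whiskers clipped to the data. The
two-group test is **Welch's unequal-variance t-test** with
Welch–Satterthwaite degrees of freedom — the form identified by fractional
d.f. in reported tables even when labelled "Student's t-test" — and is
cross-checked in the tests against an independent reference implementation
to 1e-9. Exact p-values are always reported.

## Synthetic study systems

The generator emulates the ingredients of a tropical-flora analysis on a
20 × 20 grid of 0.1° cells with three taxon roles:

* **Background** (40 species): a random pair-join ultrametric tree of
  height 1.0; each species occupies a random contiguous rectangle of
  cells, so background ranges are spatially coherent and span the
  environmental gradient.
* **Neo radiations** (4 clades × 5 tips, terminal length 0.1): each clade
  is grafted as the sister of a widespread background species at height
  0.2, so *every* range-restricted branch of the radiation (terminals and
  crown stem) is short, while all deeper branches are shared with the
  widespread host. The whole clade co-occurs in one highland home of 1–2
  cells — the products of an in-situ radiation.
* **Palaeo relicts** (4 lineages, stalk length 2.0 — 20× the neo terminal
  length): isolated long branches hanging from the root, grouped in pairs
  into shared lowland refuges of 1–2 cells.

Two design points matter for detectability and were chosen on structural
grounds. First, a radiation hung from the tree root would carry a long
range-restricted stem that acts palaeo-like and cancels its own
neo signal; sister-grafting into a widespread lineage removes that
artefact and is also the realistic topology for neoendemics. Second,
because RPE is a ratio, a cell with one short rare branch is roughly as
extreme as a cell with five — so a null draw that happens to drop a single
rare tip into a cell mimics an isolated planted tip, and isolated planted
taxa cannot reach rank extremes of 1/999. Co-occurrence is what the null
cannot reproduce: the probability of a margin-preserving draw placing
three or more rare tips in one cell is far below 1/999.

Rasters are co-registered at 4 pixels per cell side: elevation has block
means 2500 m (highland) and 200 m (lowland) with a linear ramp between and
Gaussian noise (sd 50 m); temperature follows a −0.6 °C/100 m lapse from a
28 °C base (so it is strongly anti-correlated with elevation); rainfall
varies smoothly with latitude only and is therefore independent of the
elevation design. Truth labels live in the tip names (`bg`/`neo`/`palaeo`
prefixes) so any tool in the chain preserves them, and the generator also
returns the planted cell sets for scoring.

What passing tests on these fixtures shows — and does not. The generator
produces clean blocks, rectangular ranges, no sampling bias, no spatial
autocorrelation in the noise, and planted effects chosen to be
unambiguous (terminal-branch ratio 20×, 1–2-cell ranges, a 2300 m
elevation gap); recovery there demonstrates that the pipeline's
machinery — gridding, incidence algebra, ranks, classification, overlay —
is correct, not that real floras yield comparable power. A `hard_mode`
preset shrinks the gaps for sensitivity studies. Real-data features the
generator does not emulate include collection-effort bias, taxonomic
name noise, range fragmentation, and climate–rainfall coupling.

## Problem sizes and numerical choices

The default scenario (~360 occupied cells, 64 species, 999 randomizations)
runs the full null suite in well under a minute on one CPU; the acceptance
script's calibration stage repeats it on three no-structure scenarios and
reports the pooled flag rate. Ranks use the half-tie convention
throughout; RPD/RPE are undefined (NaN, cell flagged) where the comparison
value is zero, which only occurs for empty branch sets; UPGMA tie-breaking
follows the deterministic SciPy ordering with cells entered in sorted
cell-id order. All file outputs are plain text (CSV, GeoJSON, Newick,
Matrix Market, ESRI ASCII).

## Known limitations

* The curveball null conditions on both margins but not on spatial
  autocorrelation; spatially structured nulls are out of scope.
* Raster reprojection is not supported: rasters must already be in the
  grid's geographic coordinates.
* Observed-weight RWT only; the randomized-PE averaging variant is left as
  an upstream option.
* No abundance-weighted metrics; incidence only.
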