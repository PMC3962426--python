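# Methods

This note documents the models, numerical choices and limitations behind
`phytoregions`, in the order the pipeline runs.

## Gridding and projection

Occurrence records are reduced to normalized species binomials: the name
is truncated at the first infraspecific rank marker (`subsp.`, `ssp.`,
`var.`, `f.`, ...), the genus capitalised and the epithet lower-cased;
names that do not resolve to two tokens (bare genera, `sp.`
placeholders, epithets containing digits) are rejected. No resolution
against external taxonomies is attempted — the rule is a deterministic,
reproducible stand-in for curatorial name cleaning.

Cleaning partitions the input exactly into survivors and a rejection log
with reason codes (`invalid_name`, `missing_coordinates`, `outside_mask`,
`spatial_outlier`). The spatial-outlier rule is **off by default**
because there is no canonical definition of a "spatial outlier" in
herbarium data; when enabled, a record is dropped if its distance from
its species' centroid (in projected meters) exceeds `outlier_sd` times
the population standard deviation of those distances. Species with fewer
than three records, or with zero distance spread, are never filtered —
the SD is not meaningful there.

Projection uses the Albers equal-area conic on the GRS80 ellipsoid,
implemented from Snyder's closed-form authalic-latitude formulation, with
the standard continental-Australia parameter set (central meridian 132°E,
standard parallels 18°S/36°S, origin latitude 0°) as the config-exposed
default. Equal-area is essential because downstream statistics treat
cells as exchangeable units of area. The inverse transform solves the
authalic function by fixed-point iteration to ~1e−12 rad; forward ∘
inverse round-trips to well under a meter, and the test suite checks the
forward transform against an independent numerical-integration route and
against frozen geodesic distances along the standard parallels.

Cells are half-open squares, 0-based `(row, col)` indices, row-major; a
record exactly on an interior boundary belongs to the higher-index cell.
Cell size defaults to 100 km. Duplicate records of a species in a cell
collapse to a single presence but count toward the per-cell record total,
from which redundancy = 1 − richness/records is computed; the redundancy
report's headline is the fraction of cells at or above a threshold
(default 0.6, a conventional "good sampling" level).

## Turnover

Simpson's beta, β_sim = min(b,c)/(min(b,c)+a), with β_sim = 1 when no
species are shared. The matrix is computed from a boolean Gram product in
row chunks (memory linear in chunk size, results bit-identical for any
chunking) and the per-pair a/b/c counts are retained for audit. Empty
cells are a hard error — they must have been excluded during gridding.

## Clustering

WPGMA: merge the closest pair; the merged cluster's distance to any other
is the unweighted mean of its children's distances. Merge height is the
pair dissimilarity itself (not half), so heights live on the same [0, 1]
scale as β_sim and branch lengths (parent height − own height) are
directly interpretable as turnover jumps. WPGMA on a proper dissimilarity
cannot invert heights; an inversion beyond 1e−9 raises an error rather
than being silently reordered.

**Ties.** Dissimilarities equal within 1e−12 are ties (floating-point
safety; exact-value ties are the conceptual target). Among tied pairs the
one whose **union** has the highest CWE is merged. CWE of a cell set =
Σ_t r_t/R_t ÷ (number of taxa present), where r_t/R_t is the fraction of
taxon t's total cell range inside the set. Scoring the union (rather than
the better component) was chosen because the merged cluster is the object
whose endemicity the tie-break is meant to maximise; `cwe_on="components"`
is available as a documented switch. Residual ties fall back to
lexicographic order of sorted member identifiers, which makes repeated
runs byte-identical — verified on tie-saturated matrices.

**Region extraction.** Two modes: cut into exactly *k* clusters (split
the highest node first), or report all maximal clusters whose subtending
branch length ≥ `min_branch`, leaving uncovered cells unassigned (−1).
No numeric rule is imposed for "clearly separated": `min_branch` is a
user parameter. Diagnostics give, per region, its size, merge height,
branch length and a contiguity score — the largest rook-adjacent
connected component over the region size.

Newick serialization writes branch lengths at 12 significant digits and
orders children by smallest member identifier; round-trip through an
independent parser preserves topology and lengths to 1e−9.

## Classification comparison

Both schemes must live on the same grid; polygon references are
rasterized by cell-center containment (later-listed polygons win
overlaps, with a warning). Agreement: each reference sub-region is
matched to the derived region covering a plurality of its cells (ties
broken toward the larger derived region, then label order); overall
agreement = 100 × Σ matched cells ∕ Σ sub-region cells, restricted to
cells labeled in both schemes (reference schemes may legitimately have
gaps). The wording "overlapped with only one of our regions" admits a
stricter reading — credit only sub-regions wholly inside one derived
region — which is provided as `mode="strict"`; plurality is the default
because it yields a graded [0, 100] statistic rather than an
all-or-nothing one.

## Environmental correlates

Point-sampled environmental values (a raster is a regular point lattice)
are averaged per cell; cells with no samples are explicit missing values
excluded from all statistics, shrinking the global support n. Each
(region, variable) pair is scored with the standardized Getis-Ord Gi*
with binary membership weights over the whole region:

z = (Σ_{j∈region} x_j − m·x̄) / (S·sqrt((n·m − m²)/(n − 1)))

with m the region size, x̄ the global mean and S the global **population**
standard deviation (the original statistic's normalization; the sample-SD
variant is a one-line seam). z is location- and scale-invariant. |z| > 2
is flagged significant — the conventional cutoff used with this
statistic, kept as stated rather than 1.96 — and no multiple-testing
correction is applied by default (a Bonferroni flag exists). The
degenerate cases m = n and S = 0 raise errors; profile computation
records them per pair and continues. Under an exchangeable null the
empirical |z| > 2 rate over random fixed-size regions sits near the
nominal ≈ 4.6% tail mass (checked at 5,000 permutations).

## Synthetic study conditions

The generator plants regional structure and is the package's substitute
for a continental occurrence database. Defaults, chosen once as the
standard study conditions: 20 × 25 grid of 100 km cells (500 cells, the
same order of magnitude as a continental analysis), 6 regions (matching
the number of continental phytogeographical regions the method is
typically asked to resolve), 100 species per regional pool (≈ 600 species
total), occupancy 0.8, shared fraction 0.1, noise-record probability
0.05, and 200 records per cell on average — which puts mean per-cell
redundancy near 0.57, i.e. realistic, imperfect sampling coverage.

Regions are contiguous rectangular blocks (most-square factorisation of
the region count against the grid aspect); a Voronoi option provides
irregular layouts for robustness tests. Record counts per cell are
Poisson — the simplest one-parameter intensity model. Records sample
uniformly from the species actually present in the cell, with a noise
probability of sampling from the global pool instead. An
`ensure_coverage` option adds one record per present species so the
gridded incidence equals the planted incidence exactly (used when tests
need that identity; it deliberately breaks the pure Poisson law, so it is
off by default). A cell left empty by occupancy sampling receives one
forced pool species, keeping the incidence matrix valid. Coordinates are
cell centers plus uniform jitter confined to the central 90% of the cell,
in the projected plane directly or inverse-projected to lon/lat to
exercise the ingest path end to end. All streams derive from the scenario
seed through named substreams, so identical parameters give byte-identical
output.

What the generator does **not** emulate: real floristic composition,
collector bias and spatial autocorrelation of sampling effort, taxonomic
error structure, range shapes other than block/Voronoi regions, and
environmental covariance between variables. Passing recovery tests
therefore demonstrate the pipeline's correctness and robustness to the
modelled noise sources, not performance guarantees on real herbarium
data.

One stated generator edge case is intentionally an error rather than a
value: a "region" covering the entire grid has Gi* denominator
sqrt((n·m − m²)/(n − 1)) = 0, so the statistic is undefined (raised as
degenerate), not 0.

## Problem sizes

The test suite and acceptance script run the full pipeline at the
standard 500-cell study conditions across seed ensembles (21 runs in the
recovery test, 5 in the acceptance script) and use 10,000-replicate
Monte-Carlo oracles and 5,000-permutation null calibrations; these sizes
give Monte-Carlo standard errors well inside the asserted tolerances.
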