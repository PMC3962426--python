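# phytoregions

Quantitative bioregionalization from species occurrence records.

Biogeographers partition continents into regions — areas whose biota turn
over sharply at the boundaries — but most historical regionalizations were
drawn by expert judgement. This package implements the quantitative
alternative used for continental floras: grid georeferenced occurrence
records onto an equal-area lattice, measure compositional turnover between
every pair of grid cells, cluster the cells, and extract regions, then
score the result against an existing regionalization and against
environmental gradients. It is aimed at biodiversity informaticians
working from herbarium/museum record dumps (name + longitude + latitude).

## Method

1. **Gridding.** Records are cleaned (binomial name normalization,
   coordinate validation, optional land mask and per-species spatial
   outlier rule), projected with an Albers equal-area conic projection
   (continental-Australia parameters by default) and aggregated into
   100 km × 100 km cells, giving a binary site-by-species matrix. Per-cell
   sampling completeness is summarised by redundancy, 1 − richness/records.
2. **Turnover.** For every cell pair, Simpson's beta

   β_sim = min(b, c) / (min(b, c) + a)

   where *a* is the number of shared species and *b*, *c* the numbers
   unique to each cell. β_sim discounts richness differences and
   nestedness: only true species replacement pushes it toward 1.
3. **Clustering.** WPGMA agglomerative clustering of the β_sim matrix.
   When candidate merges tie on dissimilarity, the pair whose union has
   the highest Corrected Weighted Endemism (CWE = weighted endemism ÷
   richness) is merged, with a lexicographic fallback — so the dendrogram
   is fully deterministic. Regions are subtrees: cut at a chosen region
   count *k*, or take all maximal clusters whose subtending branch length
   exceeds a threshold. Diagnostics report branch length and spatial
   contiguity per region.
4. **Evaluation.** Agreement with a reference regionalization is the
   percentage of reference sub-region cells falling in their matched
   (plurality) derived region. Environmental distinctness of each region
   is scored with the Getis-Ord Gi* statistic on cell-mean environmental
   values; |z| > 2 is treated as significant (α < 0.05).

A first-class synthetic-data generator plants known regional structure
(species pools on contiguous blocks, adjustable sharing, sampling
intensity and noise) so that every stage is testable without external
data.

## Worked example

Generate a synthetic landscape with four planted regions and run the full
pipeline in one command:

```
$ phytoregions synth --outdir demo --seed 5 --rows 8 --cols 10 --regions 4 --emit lonlat
wrote occurrences, reference and environment under demo

$ phytoregions pipeline --occurrences demo/occurrences.csv --coords lonlat \
      --k 4 --outdir demo/run --reference demo/reference.csv --env demo/environment.csv
80 cells, 400 species, 4 regions; well-sampled fraction 0.21
overlap agreement vs reference: 90.00%
Gi* profile: 8 significant of 8 pairs
```

The run writes `dendrogram.nwk` (the WPGMA tree), `regions.csv` (cell →
region labels), `overlap_report.csv` and `gi_star.csv`. The region
diagnostics show four clean, fully contiguous regions of 20 cells each,
merged at turnover heights ≈ 0.39–0.41 and separated from the rest of the
tree by branch lengths ≈ 0.44–0.51 — long branches meaning sharp
compositional boundaries:

```
$ head -5 demo/run/region_diagnostics.csv
label,size,height,branch_length,contiguity
0,20,0.40591703362014514,0.4385756219807227,1.0
1,20,0.3857188985694828,0.5098767992438222,1.0
2,20,0.38840616028116026,0.4560864953197076,1.0
3,20,0.38383058463161307,0.511765113181692,1.0
```

The 90% overlap is exactly what the generator planted: the reference
scheme is the true layout with 10% of cells flipped to a neighbouring
label. The Gi* matrix (significant scores starred) recovers each planted
environmental contrast with the expected signs:

```
$ head -3 demo/run/gi_star_matrix.csv
variable,0,1,2,3
gradientvar,-4.72*,-3.54*,3.89*,4.38*
offsetvar,-6.9*,-2.27*,2.41*,6.76*
```

The same stages are available individually (`grid`, `turnover`,
`cluster`, `compare`, `envcorr`) and as library functions
(`phytoregions.grid_records`, `turnover_matrix`, `wpgma`, `cut_regions`,
`overlap_agreement`, `region_env_profile`, ...).

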