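# Methods

## Scope and data model

`scdnax` analyses targeted single-cell DNA sequencing (scDNA-seq) runs of
the kind produced by droplet platforms such as Mission Bio's Tapestri: a
few hundred to a few thousand cells genotyped over an amplicon panel. The
unit of input is one `.h5` file holding a cells × amplicons read-count
matrix and four cells × variants call layers — variant allele frequency
(`AF`, percent in [0, 100]), read depth (`DP`), genotype quality (`GQ`,
0–99) and the genotype code (`NGT`: 0 wild-type, 1 heterozygous,
2 homozygous alternate, 3 missing). AF is stored as a percent throughout;
algorithms convert to fractions internally where needed.

The on-disk schema is fixed and documented in `scdnax.h5io`; the reader
maps a small set of column-name aliases (`CHROM`/`POS`/`REF`/`ALT`) so
genuine pipeline exports load where the layer names match. On read, any
call with `DP = 0` is coerced to `AF = 0`, `NGT = 3` — a depth-zero call
carries no genotype information — and the number of coercions is reported.
`validate_h5` never raises on a merely invalid file; every problem becomes
a failed check in a report, because the user's first question about a
suspect file is *what* is wrong with it.

## Sequencing QC

Mapping metrics (`n_read_pairs`, `n_read_pairs_mapped`, mapping rate) are
taken from pipeline metadata only — they cannot be recomputed from panel
counts — and are reported as absent rather than zero when the metadata
keys are missing. Depth metrics (total panel reads, mean read pairs per
amplicon per cell, mean reads per cell) come from the count matrix only.
The mean over all cells × amplicons is used for the per-amplicon-per-cell
depth; values are kept at full precision and rounded only at presentation.

## Read-count normalization

Raw amplicon counts confound cell-level library size with amplicon-level
PCR efficiency. The normalization is the standard three-step scheme for
Tapestri-style panels:

1. divide each cell's row by its row total (cells with zero total are
   excluded and listed);
2. divide each amplicon's column by its median over included cells
   (midpoint convention for even counts; zero-median amplicons are
   reported as degenerate and set to 0);
3. multiply by 2, so the per-amplicon median represents diploid copy
   number.

The defining invariant — the per-amplicon median of the output equals 2
(±1e-9) for every non-degenerate amplicon — is asserted in the tests. The
×2 step is applied after amplicon scaling; applying it before would be
absorbed by the median division, so the order is fixed by the invariant
itself. Panel uniformity is the fraction of amplicons whose mean raw
coverage is at least 20% of the panel-wide mean.

## Variant filtering

Filtering is a fixed three-stage single pass (no iteration, so every count
in the report is well-defined and monotone in the thresholds):

1. **call masking** — a call is recoded missing when `DP < min_dp`, or
   `GQ < min_gq`, or it is a mutant call (`NGT ∈ {1,2}`) with
   `AF < min_vaf_mut`. The VAF rule is scoped to mutant calls so that a
   confident wild-type call with VAF 0 is not destroyed. AF/DP/GQ values
   are preserved for transparency; only `NGT` changes.
2. **variant dropping** — a variant is dropped when its genotyped fraction
   (`NGT ≠ 3`) falls below `min_genotyped_cells_frac`, or its mutated
   fraction (`NGT ∈ {1,2}`, denominator all cells) falls outside
   `[min_mutated_cells_frac, max_mutated_cells_frac]`. Using all cells in
   the mutated-fraction denominator keeps that rule independent of the
   genotyped-fraction rule.
3. **cell dropping** — a cell is dropped when its genotyped fraction
   across surviving variants falls below `min_cell_genotyped_frac`. When
   no variant survives, that fraction is taken as 0.

Defaults (DP ≥ 10, GQ ≥ 30, mutant VAF ≥ 20%, ≥ 50% cells genotyped per
variant, mutated fraction in [1%, 100%], ≥ 50% variants genotyped per
cell) follow the convention of the platform's own filtering tools; every
threshold is user-adjustable. Variant annotation (gene, protein change,
coding effect, ClinVar class, dbSNP ID, DANN deleteriousness score in
[0, 1]) is offline and table-driven: an exact-key (chrom, pos, ref, alt)
TSV lookup behind a loader interface, so any annotation source that can
emit the TSV plugs in without network access.

## Clone exploration

Cells are clustered on the VAF matrix of user-selected variants.

* **Missing data** is handled complete-case: any cell missing a selected
  variant is dropped from the matrix (the count is reported). Imputing
  VAFs would manufacture cluster signal.
* **k-means** (the default) runs Lloyd iterations from `n_init = 10`
  k-means++ initializations, keeping the best fit by within-cluster sum
  of squares (WSS). Labels are canonicalized by descending cluster size
  (ties by centroid lexicographic order) so outputs are stable across
  runs and platforms.
* **The elbow curve** reports best-fit WSS for k = 1..k_max. Each k
  additionally tries a warm start built from the previous k's centroids
  plus the point farthest from them; since Lloyd never increases the
  assignment cost of its initialization, this makes the curve
  non-increasing in k by construction rather than by statistical accident.
  k selection itself stays with the user.
* **DBSCAN** is standard Euclidean density clustering; noise points keep
  label −1.
* **Leiden** builds a symmetric (union) unweighted kNN graph and optimizes
  RB-configuration modularity at the given resolution (default 1.0) with
  a seeded partitioner. On well-separated clone blocks the choice of
  `n_neighbors` sets the granularity: a neighborhood much smaller than the
  clone size lets modularity split a clone into sub-communities (this is
  the known behaviour of modularity on sparse geometric graphs, not an
  artifact), so recovering coarse clone structure calls for `n_neighbors`
  on the order of the expected clone size. The clone-recovery analyses in
  this package use `n_neighbors = 150` for ~250-cell clones.
* **PCA** is computed on raw VAF percents (all variants share a unit, so
  no per-variant scaling) by column-centring and SVD; each component's
  largest-magnitude loading is made positive so projections are
  sign-stable. Explained-variance fractions are checked against a
  covariance-eigenvalue computation in the tests.
* **ARI** (adjusted Rand index) quantifies agreement between a clustering
  and simulator ground truth; it is validated against brute-force pair
  counting.

Per-cluster summaries report NGT-code counts per (cluster, variant) —
whose genotype marginal equals the cluster size — and VAF order statistics
(median, quartiles by the midpoint convention, mean).

## Synthetic clone mixtures

The generator emulates the data the workflow targets: a K-clone mixture
with per-clone genotypes over V variants.

* Cell clone membership is categorical over `clone_fractions`.
* Per call, depth is negative-binomial with mean `mean_depth` and size
  `depth_dispersion` (shared with the count model to keep the
  configuration small); alternate reads are binomial given the genotype's
  expected VAF — `100ε` for wild-type, 50 for heterozygous, `100(1−ε)`
  for homozygous, with ε the per-read error rate.
* Allele dropout relabels a heterozygous genotype to hom-ref or hom-alt
  with a fair coin at rate `ado_rate` *before* reads are drawn (genotype-
  level rather than read-level dropout: simpler, and what matters
  downstream is the resulting VAF shift, which is identical).
* Calls are additionally forced missing at `missing_rate`; depth-zero
  calls are always missing. `GQ = min(99, 3·DP)` is a monotone depth proxy
  — filtering only needs a thresholdable score correlated with call
  reliability.
* Amplicon read pairs are negative-binomial with mean
  `counts_mean · e_a · s_i`, where amplicon efficiencies
  `e_a ~ LogNormal(0, 0.25)` and cell size factors
  `s_i ~ LogNormal(0, 0.1)` are each normalized to mean 1.

Defaults describe a four-clone mixture in equal proportions with four
discriminating variants, depth 80, ε = 0.01, 5% allele dropout and 5%
forced missingness — values typical of a healthy targeted scDNA-seq run of
a cell-line mixture. All draws come from one seeded generator; identical
configurations are bit-identical.

What the simulator does **not** model: doublets, barcode collisions, copy
number variation, read-level artifacts (FASTQ is never simulated), and
spatial or batch structure in amplicon efficiency. Tests passing on this
generator therefore demonstrate correctness of the computations and
recoverability of clonal structure under the stated noise model — not
robustness to doublet contamination or CNV-driven VAF shifts in real
tumour data.

## Problem sizes and determinism

The bundled analyses use simulated runs of 1 000 cells (10 independent
seeds for clone recovery), 50 random datasets for round-trip checks, 100
random datasets for the filter oracle, and 100 random matrices for the
normalization invariant — sizes at which the binomial/negative-binomial
means have converged well inside the asserted tolerances. Every random
draw flows from an explicit seed; CLI outputs are byte-reproducible given
identical inputs and seed (the HTML report confines its timestamp to one
marked comment line).

## Known limitations

* CNV calling is out of scope; normalized counts are exploratory only.
* No lineage-tree reconstruction on top of the clone clusters.
* Annotation is only as good as the supplied offline tables; there is no
  live database lookup.
* The Tapestri alias map covers the common layer names; exotic multi-omics
  `.h5` layouts are ignored rather than parsed.
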