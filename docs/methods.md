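# Methods

This note documents the models, conventions and numerical choices behind
`chromtrace`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model and conventions

Genomic intervals are stored 0-based half-open; tables in the published
1-based inclusive convention are converted on load (`load_codebook(...,
one_based=True)` — the switch exists because source tables do not always
declare their convention). Spatial coordinates are nanometres everywhere
internally; trace/foci CSVs declare their unit in a `#unit:` header and µm
input is converted on read. Genomic distance between two regions is the
distance between region midpoints in bp (symmetric, anchor-free). Strand is
ignored. Missing loci are represented by absence, never by sentinel
coordinates.

The barcode contract is the imaging design's: 100 bits, exactly two on-bits
per region, all on-bit pairs distinct. Codebook validation rejects any
weight-≠2 or duplicate-pair corruption.

## Synthetic population generator

The generator emulates the statistical structure of multi-state chromatin
trace populations; it is a distance-statistics model, not a polymer
simulation, because every downstream metric depends only on pairwise
distance statistics.

Per cell and chromosome copy, locus positions are a territory center plus a
3D fractional-Brownian-motion path over genomic position with Hurst index
α, scaled so that the expected pair distance is exactly *A·g^α* (the
per-coordinate variance scale is *A²·π/8*, since the mean of a 3D Gaussian
norm is σ√(8/π)). A per-cell lognormal factor with mean 1 and relative s.d.
`heterogeneity_sd` rescales the path, producing conformational
heterogeneity without biasing mean distances.

Compartments: A/B truth labels alternate in blocks of 5 regions per
chromosome (yielding checkerboard distance structure). Each copy draws a
random pole axis; A loci are displaced by +c·(A/2) along it and B loci by
−c·(A/2), where c is `compartment_strength`. Because the offset is constant
within a label, same-label distances are unchanged and cross-label pairs
inflate only in second order (≈δ²/2d̄²), which keeps the power-law exponent
recoverable within ±0.02 under defaults while making compartment labels
recoverable from the distance matrix at c ≥ 0.5 — both properties are
regression-tested, not assumed. `radial_bias` analogously moves A loci
toward and B loci away from the nucleus center by ±bias·(A/2), producing
the negative radial-score/compartment-score correlation.

Territory centers are drawn per copy (38 per cell) uniformly in a ball of
radius `territory_spread`; homologs get separate territories so trace
linking is a real problem. Dropout is i.i.d. Bernoulli per locus at
1−`locus_detection_rate`.

Defaults encode the study conditions the package targets: α = 0.1 (the
observed genomic-to-spatial scaling of about one-tenth), 473 regions on 19
autosomes at ~5-Mb spacing with two copies per autosome, adenoma-like
states at 0.8× compaction with reduced heterogeneity, an invasive state
with recovered compaction and wider territory spread (larger nuclei).
`compaction_scale` defaults to 1,500 nm·Mb^−α, nuclear radius 4,000 nm —
µm-scale interloci distances typical of mammalian nuclei. The default
detection rate (0.8) is higher than tissue imaging typically achieves; it
is chosen so the >325-region cell filter downstream retains a nontrivial
majority of cells at desk-scale population sizes, and it is a parameter,
not a constant. Test and acceptance populations use 100–300 cells per
state; these sizes are the package's chosen desk-scale study conditions.

What the generator does **not** emulate: aneuploidy/CNVs, TAD/loop-level
structure, cell-cycle effects, segmentation errors, real gene identities,
and spatially correlated detection failures. Passing recovery tests
therefore demonstrates the correctness of the estimators under the stated
generative assumptions, not performance on real tissue data.

The foci generator emits one focus per on-bit per locus with isotropic
Gaussian localization error, independent per-focus miss probability, and
Poisson-uniform false positives per bit; ground truth records which loci
had both foci emitted.

The expression generator draws negative-binomial counts for two groups;
CPD-class genes shift by the programmed log2FC with low dispersion,
control-class genes get the same mean shift as an overdispersed bimodal
mixture (high variance, preserved mean), remaining genes are null. The DE
table carries the true generative means/fold changes with small FDR for
shifted genes, so gene-set calling is testable against construction.

## Decoding and trace linking

Candidate locus calls are (bit-i focus, bit-j focus) pairs within
`pair_radius` (default 300 nm, ~3σ of the pair-distance scale at 50-nm
localization error); candidates across all regions are accepted greedily by
ascending pair distance, each focus consumed at most once, ties broken by
(region, focus order) for determinism. Call position is the pair midpoint;
the pair distance is kept as a quality score (smaller is better). Greedy
resolution was chosen over global matching for simplicity and
verifiability; the brute-force-verified conflict test covers the canonical
shared-bit case.

Linking partitions each chromosome's decoded loci by a deterministic
2-means split (seeded from the two most distant points), accepted only when
it reduces mean within-cluster squared dispersion by ≥2×; otherwise a
single copy is assumed and duplicate regions collapse to the best-quality
locus. This algorithm is an explicit stand-in honoring the decoded-loci →
per-copy-traces contract; the original pipeline's linking method is not
public. Consequence: when homolog territories overlap, linking merges them
and discards one copy per duplicated region. Decoder quality is therefore
benchmarked on raw decoded loci. The benchmark reports recall against all
true loci *and* against decodable loci (both on-bit foci emitted) — the
latter is the information-theoretic basis, since a locus with a missing
focus cannot be decoded by any algorithm (all-locus recall is bounded by
(1−miss)² in expectation).

## Metrics

- COV uses the sample s.d. (n−1): per-pair counts are small.
- Distances pool chromosome copies as independent observations; pairs
  observed fewer than `min_pairs` (default 5) times are masked for
  demixing, fits and compartment calling (the raw mean is still reported
  with its count).
- Power-law fits are least squares in log–log space over unmasked pairs.
- Compartment PCA runs on the pairwise-complete Pearson correlation matrix
  of the observed/expected distance matrix; chromosomes with <4 usable
  regions or zero-variance correlation are flagged degenerate and skipped.
  Signs are fixed per chromosome by nonnegative correlation with the
  activity reference profile (standardized mean of coverage tracks plus
  gene density).
- Polarization uses exact convex-polytope intersection
  (half-space intersection seeded at the Chebyshev center; an empty or
  lower-dimensional intersection gives V_s = 0); a Monte Carlo grid oracle
  backs the tests. A `chr6_first30`-style restriction is available by
  slicing the label array to the first 30 regions of a chromosome before
  calling, matching the convention of equalizing region counts.
- scA/B neighborhoods exclude the query locus, include same-trace loci, use
  strict inequality at the 1,200-nm radius, and can be restricted to
  trans-chromosomal neighbors (`trans_only`). Population compartment scores
  default to the pooled reference group; per-state scores are a caller
  choice.
- Proximity frequencies default to a 500-nm cutoff (configurable; the
  long-range cis variant requires ≥25 Mb separation).
- Matched comparisons use two-sided Wilcoxon signed-rank, unmatched
  rank-sum, dispersion (demixing) Levene; BH controls FDR across the blocks
  of each comparison. Marker-region P values are deliberately *not*
  adjusted (the rule thresholds raw P < 0.1; a BH variant is available for
  sensitivity analysis).
- Trend classification thresholds both legs at |log2FC| ≤ 0.02 for "flat";
  the down-then-up category is the bottleneck pattern.

## Trace2State

"Medium Gaussian SVM, box constraint 1" translates to an RBF-kernel SVM
with C = 1 and kernel scale √(n_features) (γ = 1/n_features on
standardized PCs); the original toolbox's kernel-width semantics are not
portable, so the translation is explicit and configurable. CV is
stratified with seeded fold assignment; a by-source grouping option exists
because batch-wise folding is a plausible alternative the source does not
specify. PCA component signs are fixed by making the largest-|loading|
coefficient positive, so embeddings are reproducible. Leiden uses k = 15
nearest neighbors and resolution 1.0 by default, both reported in the
output metadata; PaCMAP is not among the available embedding backends
(pca2d, t-SNE, UMAP are), and requesting it raises an informative error.

## Trace2Biomarker

Rank normalization keeps cells with strictly more than 325 defined regions
and assigns average ranks within each cell (ties share the mean rank).
Direction of a marker region is the sign of the group-B minus group-A
median of rank-normalized values (the source states the test but not a
direction rule). "Fold change > 3" is applied on the linear scale
(2^log2FC > 3). A gene belongs to the region containing its transcription
start; genes outside all target regions participate only in the
up-regulated set. Homogeneity is the cosine of the expression vector with
the uniform vector — mean/RMS, identically 1/√(1+CV²) with population
moments — chosen over pairwise cell–cell cosine for its closed form and
scale invariance; the pairwise form can be derived from the same matrix if
needed.

## Known limitations

- The linking stand-in under-counts homolog copies in overlapping
  territories (see above); population distance metrics are unaffected when
  computed on simulator or decoder output.
- Compartment calling assumes enough regions per chromosome (≥4) and a
  meaningful power-law fit; micro-panels should use the masked outputs.
- The generator's independence assumptions (dropout, per-cell noise) make
  calibration results exact only under those assumptions.
- Statistical calibration results (e.g., the 10% null marker rate) hold at
  the simulated sample sizes; heavily discrete settings (very few cells)
  will deviate because rank-sum P values are discrete.
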