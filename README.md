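# chromtrace

Analysis of single-cell 3D genomes from genome-wide chromatin tracing.

Chromatin tracing images hundreds of genomic loci in single cells in situ:
each target region carries a weight-2 binary barcode over 100 imaging bits,
decoded foci give the 3D position of every detected locus, and loci are
linked into per-homolog chromatin traces. `chromtrace` takes such data — or
synthetic stand-ins with known ground truth — and computes the structural
metrics used to compare cell states along tumor progression, classifies
cell states from single-cell compartment profiles (**Trace2State**), and
nominates candidate progression driver (CPD) genes whose compartment and
expression change together (**Trace2Biomarker**).

It is written for computational biologists working with imaging-based
3D-genome data (chromatin tracing / DNA MERFISH point clouds) who need a
tested, scriptable implementation of these analyses without the original
imaging stack.

## The quantities at its core

For loci *i*, *j* at genomic separation *g* (Mb) with spatial distances
*d<sub>ij</sub>* pooled over chromosome copies of a cell state:

- **Decompaction score**: mean *d<sub>ij</sub>* per locus pair; on average
  *E[d] = A·g^α* with scaling exponent *α* ≈ 0.1.
- **Heterogeneity score**: coefficient of variation of *d<sub>ij</sub>*
  across copies; the cell-pair form is RMS(*d₁−d₂*) / mean.
- **Demixing score**: s.d. of mean-normalized mean interloci distances per
  chromosome.
- **Compartment score**: per chromosome, the observed/expected distance
  matrix is correlated column-pairwise and the first principal component of
  that correlation matrix gives per-region A/B scores (sign-fixed against a
  chromatin-activity reference; A where score > 0).
- **Polarization index**: PI = √((1−V<sub>s</sub>/V<sub>a</sub>)(1−V<sub>s</sub>/V<sub>b</sub>))
  from the convex hulls of A- and B-labeled loci of one chromosome copy and
  their intersection volume V<sub>s</sub>.
- **Radial score**: locus distance to the cell's locus centroid, normalized
  to a per-cell mean of 1.
- **scA/B score**: for each locus in each cell, the mean population
  compartment score of all other detected loci strictly within a 1,200-nm
  3D neighborhood — the feature space of Trace2State and Trace2Biomarker.

Trace2State filters cells (≥10 traces), imputes missing scA/B values with
0, reduces to 50 principal components, and runs 2D embeddings, a
cross-validated RBF-SVM state classifier, and Leiden clustering into
adenoma-like vs invasive-like conformations. Trace2Biomarker keeps cells
with >325 scored regions, rank-normalizes scA/B per cell, flags marker
regions by rank-sum tests (raw P < 0.1), and intersects scA/B-up marker
regions with upregulated genes (mean count > 10, fold change > 3,
FDR < 0.05; top-21 signatures) to call CPDs.

The bundled generator simulates multi-state trace populations (territory-
anchored fractional-Brownian walks over 473 regions on 19 autosomes, two
copies each, with compartment polarization, radial bias, heterogeneity and
dropout), per-bit foci clouds, and matched expression/DE tables — all with
retained ground truth, so every stage is testable without external data.

## Worked example

```python
import numpy as np
import chromtrace as ct
from chromtrace import metrics as m
from chromtrace.simulate import reference_profile_from_truth

codebook = ct.synthetic_codebook()
states = [ct.StateParams(label="normal", n_cells=100),
          ct.StateParams(label="adenoma", n_cells=100,
                         compaction_scale=1200.0, heterogeneity_sd=0.15)]
cells, truth = ct.simulate_population(states, codebook, seed=0)

normal = [c for c in cells if c.state == "normal"]
ds = m.distance_summary(normal, codebook)
fit = m.fit_power_law(ds)
print(f"power law: d = {fit.amplitude:.0f} nm * g^{fit.exponent:.3f}")

comp = m.compartment_scores(ds, codebook,
                            reference_profile_from_truth(truth, seed=0))
agree = (comp.is_a == truth.region_a)[np.isfinite(comp.scores)].mean()
print(f"compartment label agreement with truth: {agree:.1%}")

fc = m.chromosome_log2fc(cells, codebook, reference_state="normal")
print(f"adenoma compaction log2FC, chromosome median: "
      f"{fc['adenoma'].median():+.3f}")
print(f"chromosomes with negative log2FC: {(fc['adenoma'] < 0).sum()}/19")
```

prints

```
power law: d = 1612 nm * g^0.091
compartment label agreement with truth: 99.2%
adenoma compaction log2FC, chromosome median: -0.331
chromosomes with negative log2FC: 19/19
```

The fitted scaling exponent recovers the generative value of 0.1, the
sign-fixed PC1 compartment labels match the simulated A/B blocks, and the
adenoma state — generated with a 0.8× compaction scale — shows the expected
log₂(0.8) ≈ −0.32 decompaction fold change on every autosome.

A command-line interface mirrors the library
(`chromtrace simulate | decode | metrics | state | biomarker`); run
`chromtrace --help`.

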