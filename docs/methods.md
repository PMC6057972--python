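# Methods

## Repertoire statistics

Clonality is computed on templates with count > 0: H′ = −Σ pᵢ ln pᵢ with
pᵢ the relative template frequency, H = ln S over the S distinct templates,
C = 1 − H′/H. Natural logarithms are forced by H = ln S; the reported H′ is
therefore in nats, though C itself is base-invariant. Two conventions are
worth spelling out:

* **Uniform repertoires** short-circuit to H′ = ln S so that C is exactly 0
  rather than 0 ± 1e−16 from floating-point summation.
* **Monoclonal samples** (S = 1) make the formula 0/0; C is defined as 1
  with a warning, the limit of minimal evenness.

Similarity is computed on cpm-scaled tables (raw counts would let
sequencing depth distort the cohort mean). The template universe at a
timepoint is the union of templates observed (cpm > 0) in any cohort
sample; the mean vector includes the focal sample by default, since the
defining formula averages over the cohort with no exclusion clause. A
leave-one-out mode (`include_self=False`) is provided for sensitivity
analysis; with cohorts of ~8 mice the two differ by a few percent.

## Synthetic data generators

`simulate_sc` draws UMI counts gene-wise from a negative binomial with mean
μ and shape θ (var = μ + μ²/θ), the standard model for both UMI and bulk
counts and the one underlying mainstream differential-expression fits.
Structure is planted multiplicatively on a log-normal baseline:

* per-type marker blocks (default 20 genes, 8-fold),
* an optional condition module — an interferon-stimulated-gene-like set
  shifted per condition or graded per type (`type_module_fc`), which gives
  trajectory fixtures a 1-D transcriptional axis,
* mitochondrial genes (named `mt-*`) whose means are set so they carry a
  specified fraction (default 5 %) of each cell's counts in expectation,
* per-cell log-normal depth factors (σ = 0.35). Depth variation matters:
  without it a cell's UMI total is purely biological and regressing
  expression on it (as the scaling step does) would absorb real signal;
  with it, totals are dominated by capture efficiency as in real droplet
  data.

Planted (marker/module) genes start from the median baseline rather than a
random log-normal draw, so the planted fold change — not a fat-tailed
baseline — carries their signal. Cell numbers per (type, condition) can be
given as a table, which is how condition-composition gradients are built.
The generator does not model batch effects, doublets, ambient RNA, or
sequence-level CDR3 structure; recovery results on synthetic data therefore
demonstrate the pipeline's correctness and statistical behavior, not its
robustness to those artifacts.

`simulate_repertoire` gives clone frequencies ∝ rank^(−α) (default α = 1, a
realistic repertoire skew), multiplies the top-k clone frequencies by a
per-timepoint expansion factor before renormalizing, and draws counts
multinomially at a fixed read depth (so per-sample totals are exact). The
first `n_public_clones` ranks share template identities across mice;
private clones are mouse-specific. The default acceptance cohort — 8 mice,
2 timepoints, 50-fold expansion of the top 3 clones at the later one,
10⁵ reads — mimics a strong clonal response to antigen re-challenge.

`simulate_reference_profiles` produces bulk negative-binomial profiles
(θ = 10, 3 replicates per type) with each type's markers up-shifted only in
that type, for signature-derivation tests.

## Single-cell processing conventions

* The 0.01 gene-mean filter runs on normalized means after cell filtering;
  the same 0.01/3 bounds reappear in HVG selection on normalized data, so a
  single scale is used for both.
* All QC thresholds are strict inequalities: 299 detected genes fails,
  300 passes; mito ratio exactly 0.1 passes.
* Normalization is ln(1 + count·10⁴/total); per cell Σ(e^N − 1) equals the
  scale factor, which is the invariant the tests check.
* The HVG mean-expression band is expressed in units of the panel's average
  normalized expression via `HvgParams.for_panel`: the (0.01, 3] band
  presumes a whole transcriptome (~2·10⁴ genes) where per-gene means
  average ~0.5; since per-cell normalized totals are fixed, a 10³-gene
  synthetic panel has 20-fold higher average means and the band must scale
  with it to keep its meaning. Dispersion (var/mean of e^N − 1) is z-scored
  within 20 equal-frequency mean bins; unbinned z-scoring would confound
  mean with dispersion. Singleton bins get z = 0.
* Cell-cycle scoring is the set mean minus an expression-matched control
  mean (25 mean-expression bins, 50 controls per gene, seeded); the exact
  control-pool conventions of the popular implementations vary, so these
  defaults are documented rather than asserted.
* Covariate regression is per-gene OLS with intercept on (UMI total, mito
  ratio, S−G2M difference); constant covariate columns are dropped,
  residuals are z-scored and clipped at ±10 to bound outlier leverage, and
  genes fitted to numerical perfection (or constant) scale to all-zero
  rather than amplifying rounding noise.
* PCA uses a full SVD with a deterministic sign convention (largest-
  magnitude loading positive).
* Clustering builds a shared-nearest-neighbor graph (Jaccard weights on
  20-NN sets including self) and runs Leiden modularity optimization at the
  requested resolution (Louvain available as a switch). Cluster labels are
  1..k by decreasing size. The exact number of communities at a given
  resolution is algorithm- and implementation-dependent, so recovery is
  always judged by adjusted Rand index against ground truth, never by an
  asserted cluster count.

## Marker statistic

The enrichment logFC compares de-logged mean expression inside vs outside
a cluster in log₂. A pseudocount ε = 10⁻⁹ is added inside both log₂ terms:
the raw formula is undefined when a gene is absent from one side, and a
symmetric ε preserves both rank order and the exact two-cluster
antisymmetry logFC_A = −logFC_B. "Expressed" means raw count > 0 for the
20 % (marker) and 5 % (condition-contrast) fraction filters; the 5 % filter
is applied per sample when sample labels are attached, per condition
otherwise.

## Signature derivation

For each reference cell type, every pairwise comparison yields genes that
are significant (FDR below the cutoff), up-regulated, and among the top-k
by decreasing fold change; the signature is the intersection of all its
pairwise lists, ordered by mean fold change. This construction makes the
monotonicity in top_k and the subset property (every signature gene sits in
every pairwise list) structural invariants. A `top_n_override` truncates
the final list, for settings with few reference types where a short
signature is wanted.

The differential ranking is pluggable (any callable returning per-gene
logFC and FDR). The shipped default is a moderated t-test on log₂-CPM:
per-gene pooled variances are shrunk toward the median pooled variance of
their mean-expression bin with 50 prior degrees of freedom, limma-style.
Two numerical points matter at 2–4 replicates: (1) an unmoderated t-test
cannot reach FDR < 10⁻⁴ at that sample size, so moderation is not optional;
(2) log-CPM is computed with a library-scaled prior count (edgeR's
convention, prior 2), because a plain log₂(CPM + 1) lets a zero-to-one
count jump span several log units in small libraries and wrecks the
variance of low-count genes. Full negative-binomial GLM fitting is
deliberately out of scope — externally fitted tables plug in through the
same interface.

Cluster annotation scores each (cluster, signature) pair as the mean over
signature genes of the cluster-mean expression z-scored across clusters,
and assigns the argmax; the method of assignment is a reconstruction (the
underlying study states that signatures were used but not how), so the full
score matrix and the winning margin are always reported.

## Trajectory

Sub-clustering re-runs normalization, covariate scaling, HVG selection and
PCA on the focal subset (the subset's axes of variation differ from the
global ones), then clusters at resolution 0.5. The MST is computed on
sub-cluster centroids in the subset's PC space over the complete Euclidean
graph by Kruskal's algorithm; inserting edges in lexicographic node order
makes the stable sort break weight ties deterministically. The reported
backbone is the tree's weighted diameter path (two farthest-node sweeps,
ties toward smaller ids, smaller endpoint first) — the natural 1-D reading
of a trajectory. A node is flagged "dispersed" when no condition reaches
50 % of its cells. Per-cell pseudotime values are out of scope.

## Bulk filters

CPM and RPKM follow the standard definitions (RPKM = count·10⁹ / (library
size · gene length)); both are invariant under uniform library scaling,
which is the property the concordance check exploits (a depth-scaled sample
copy has R² = 1). R² is the squared Pearson correlation of log₂(RPKM + 1)
over expressed genes; the log base cancels in Pearson², and the pseudocount
of 1 is documented rather than fitted. The DEG filter is strict on both
cutoffs: a gene at exactly |log₂FC| = 1.5 or FDR = 0.01 is excluded.

## Problem sizes

The test suite and the acceptance script run on deliberately compact
problems — 10³ genes × 4·10² cells for the single-cell pipeline, 2·10³
genes × 15 samples for references, 8 mice × 10⁵ reads for repertoires,
≤ 6-node exhaustive MST enumerations — chosen so each stage's statistical
signal is comfortably above noise while the whole suite completes in
seconds. Scaling to full-size datasets is a matter of input size only; no
algorithm here is quadratic in cells except the SNN construction, which is
kNN-bounded.
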