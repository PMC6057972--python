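# tme

Analysis toolkit for studying how gene therapy reshapes the leukemia tumor
microenvironment, built for immunologists and computational biologists who
work with three kinds of data at once: TCR-beta repertoires, droplet
single-cell RNA-seq of myeloid compartments, and bulk RNA-seq of sorted
populations. Every stage can be exercised on synthetic data with known
ground truth, so the statistical machinery is testable without access to
the original sequencing runs.

## What it computes

**TCR-beta repertoire statistics.** Each unique CDR amino-acid template is
quantified in counts per million (cpm). Clonality is one minus Pielou's
evenness,

    C = 1 − H′/H,    H′ = −Σᵢ pᵢ ln pᵢ,    H = ln S,

where *S* is the number of distinct templates: C = 0 for a perfectly even
repertoire, C → 1 as it becomes monoclonal. Similarity of a sample *s* to
its cohort at timepoint *t* is one minus the Bray–Curtis distance to the
mean template vector,

    Sₜ = 1 − Σᵢ |sᵢ − m̄ᵢ| / Σᵢ (sᵢ + m̄ᵢ),

over the union of templates observed at *t* (equivalent to the
Sørensen–Dice index on presence/absence data). Longitudinal summaries give
per-mouse (ΔC, ΔSₜ) arrows between timepoints.

**Single-cell pipeline.** UMI matrices (10x-style MatrixMarket triplets) go
through cell QC (≥ 300 detected genes, mitochondrial/endogenous ratio
≤ 0.1, both strict), per-cell log-normalization to a 10⁴ scale, a 0.01
minimum on normalized gene means, covariate regression (UMI total, mito
ratio, S−G2M cell-cycle score difference) with per-gene z-scoring,
binned-dispersion HVG selection, 25-component PCA, and shared-nearest-
neighbor Leiden clustering at resolution 0.23. Cluster markers use the
enrichment statistic

    Cᵢⱼ = e^{Nᵢⱼ} − 1,
    logFCᵢ = log₂(mean_{j∈K} Cᵢⱼ) − log₂(mean_{j∉K} Cᵢⱼ),

restricted to genes expressed in ≥ 20 % of the cluster's cells; condition
contrasts reuse the same statistic with a 5 % expression filter and top-100
lists. Cell-type signatures are derived from bulk reference profiles as the
intersection of pairwise differential lists (FDR < 10⁻⁴, top-200 by fold
change), and clusters are annotated by their mean z-scored signature
expression.

**MST trajectory.** A focal cluster is re-processed from raw counts and
re-clustered at resolution 0.5; sub-cluster centroids in the subset's PC
space are joined by the minimum spanning tree, and the tree's diameter path
is reported as the trajectory backbone with per-node size and experimental-
condition composition.

**Bulk preprocessing.** CPM > 1 in ≥ 2 samples expression filter, pairwise
R² on log RPKM, and the strict FDR < 0.01 / |log₂FC| > 1.5 filter applied
to an externally fitted differential-expression table.

## Worked example

```python
from tme import RepSimSpec, simulate_repertoire, longitudinal_summary

spec = RepSimSpec(n_mice=8, timepoints=("T0", "T2"),
                  expansion=(1.0, 50.0), top_k_expanded=3,
                  reads_per_sample=100_000, seed=1)
tables = simulate_repertoire(spec)         # 16 RepertoireTable objects
stats = longitudinal_summary(tables)
print(stats.groupby("timepoint")[["clonality", "similarity"]].mean())
```

prints

```
           clonality  similarity
timepoint
T0          0.236399    0.699126
T2          0.770794    0.977038
```

i.e. expanding the top three clones fifty-fold at the later timepoint
raises mean clonality from 0.24 to 0.77 and drives the cohort's repertoires
toward each other (similarity 0.70 → 0.98), because all mice expand the
same public clones — the signature of a shared antigen-driven response. The
`delta_C` column is positive for all eight mice.

The same kind of recovery holds for the single-cell side: a simulated
matrix of four cell types (100 cells each, 1 000 genes, 8-fold markers) run
through the full pipeline is recovered with adjusted Rand index ≈ 0.97 and
all four clusters annotated with their generating type's signature.

A command-line layer mirrors the library (`tme synth`, `tme
repertoire-stats`, `tme sc-qc`, `tme sc-cluster`, `tme signatures`, `tme
trajectory`, `tme bulk-filter`, `tme deg-filter`); run `tme --help`.

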