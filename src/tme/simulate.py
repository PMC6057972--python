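"""Synthetic data generators with the statistical structure the analyses assume.

Three generators cover the pipeline's inputs:

* :func:`simulate_sc` — negative-binomial UMI counts over planted cell-type
  clusters, with per-type marker fold changes, an optional per-condition
  gene-module shift (an interferon-stimulated-gene-like module), and
  mitochondrial genes carrying a set fraction of each cell's counts in
  expectation. Ground-truth type labels are returned for recovery tests.
* :func:`simulate_repertoire` — clonally structured TCR repertoires: clone
  frequencies follow a power law in rank, the top-k clones can be expanded at
  later timepoints, a set of public clones is shared across mice, and counts
  are multinomial at a fixed read depth.
* :func:`simulate_reference_profiles` — bulk reference expression profiles
  per cell type with planted marker genes, for signature derivation.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import BulkCounts, RepertoireTable, SparseCounts


class ParameterError(ValueError):
    """Raised when a simulation spec violates its invariants."""


@dataclass
class ScSimSpec:
    """Parameters of the single-cell UMI simulator.

    ``cells_per_type`` cells are drawn for every (type, condition) pair.
    Baseline gene means are log-normal(``mean_log_mu``, ``mean_log_sigma``);
    each type's ``markers_per_type`` markers are shifted up ``marker_fc``-fold
    in that type; genes of the condition module are shifted by the per-
    condition fold change in ``condition_module_fc``. ``dispersion`` is the
    negative-binomial shape (var = mu + mu^2 / dispersion).
    """

    n_cell_types: int = 4
    cells_per_type: int | tuple = 100  # int, or (n_types x n_conditions) table
    n_genes: int = 1000
    conditions: tuple[str, ...] = ("CTRL",)
    mean_log_mu: float = -1.5
    mean_log_sigma: float = 1.0
    dispersion: float = 2.0
    markers_per_type: int = 20
    marker_fc: float = 8.0
    condition_module_size: int = 0
    condition_module_fc: dict = field(default_factory=dict)  # condition -> fold change
    type_module_fc: tuple | None = None  # per-type module fold change (gradient axis)
    mito_fraction: float = 0.05
    n_mito_genes: int = 10
    depth_log_sigma: float = 0.35  # per-cell capture-efficiency spread (lognormal)
    seed: int = 0

    def cell_table(self) -> np.ndarray:
        """Cells per (type, condition) as an n_types x n_conditions array."""
        tab = np.asarray(self.cells_per_type)
        if tab.ndim == 0:
            tab = np.full((self.n_cell_types, len(self.conditions)), int(tab))
        if tab.shape != (self.n_cell_types, len(self.conditions)):
            raise ParameterError(
                "cells_per_type table must be n_cell_types x n_conditions"
            )
        return tab.astype(int)

    def validate(self) -> None:
        if self.n_cell_types < 1 or self.n_genes < 1:
            raise ParameterError("counts must be >= 1")
        if (self.cell_table() < 0).any() or self.cell_table().sum() < 1:
            raise ParameterError("cell counts must be >= 0 with at least one cell")
        if self.marker_fc <= 0 or any(fc <= 0 for fc in self.condition_module_fc.values()):
            raise ParameterError("fold changes must be > 0")
        if self.type_module_fc is not None:
            if len(self.type_module_fc) != self.n_cell_types:
                raise ParameterError("type_module_fc needs one entry per cell type")
            if any(fc <= 0 for fc in self.type_module_fc):
                raise ParameterError("fold changes must be > 0")
        if not 0 < self.mito_fraction < 1:
            raise ParameterError("mito_fraction must be in (0, 1)")
        if self.dispersion <= 0:
            raise ParameterError("dispersion must be positive")
        needed = (
            self.n_cell_types * self.markers_per_type
            + self.condition_module_size
            + self.n_mito_genes
        )
        if needed > self.n_genes:
            raise ParameterError("marker/module/mito genes exceed n_genes")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw with mean ``mean`` and shape ``dispersion``."""
    mean = np.maximum(np.asarray(mean, float), 1e-12)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_sc(spec: ScSimSpec) -> tuple[SparseCounts, np.ndarray]:
    """Simulate a genes x cells UMI matrix; returns (counts, true type labels)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    base = rng.lognormal(spec.mean_log_mu, spec.mean_log_sigma, spec.n_genes)
    # gene layout: [type markers | condition module | background | mito at the end]
    marker_sets = [
        np.arange(t * spec.markers_per_type, (t + 1) * spec.markers_per_type)
        for t in range(spec.n_cell_types)
    ]
    module_start = spec.n_cell_types * spec.markers_per_type
    module_genes = np.arange(module_start, module_start + spec.condition_module_size)
    # planted genes start from the typical (median) baseline so the fold
    # change, not a fat-tailed baseline draw, carries the signal
    planted = np.concatenate([*marker_sets, module_genes]).astype(int)
    base[planted] = np.exp(spec.mean_log_mu)
    mito_genes = np.arange(spec.n_genes - spec.n_mito_genes, spec.n_genes)

    # Mitochondrial means set so they carry mito_fraction of counts in expectation.
    endo = np.ones(spec.n_genes, bool)
    endo[mito_genes] = False
    base[mito_genes] = (
        spec.mito_fraction / (1 - spec.mito_fraction) * base[endo].sum() / spec.n_mito_genes
    )

    gene_names = [f"gene{i:04d}" for i in range(spec.n_genes)]
    for k, gi in enumerate(mito_genes):
        gene_names[gi] = f"mt-gene{k:02d}"

    cell_table = spec.cell_table()
    cols, labels, conds = [], [], []
    for t in range(spec.n_cell_types):
        mu_t = base.copy()
        mu_t[marker_sets[t]] *= spec.marker_fc
        if spec.type_module_fc is not None and len(module_genes):
            mu_t[module_genes] *= spec.type_module_fc[t]
        for ci, cond in enumerate(spec.conditions):
            n_cells_tc = int(cell_table[t, ci])
            if n_cells_tc == 0:
                continue
            mu = mu_t.copy()
            fc = spec.condition_module_fc.get(cond, 1.0)
            if len(module_genes):
                mu[module_genes] *= fc
            # per-cell technical depth: UMI totals vary with capture
            # efficiency independently of biology
            depth = rng.lognormal(0.0, spec.depth_log_sigma, n_cells_tc)
            block = _nb_draw(rng, mu[:, None] * depth[None, :], spec.dispersion)
            cols.append(sp.csr_matrix(block))
            labels.extend([t] * n_cells_tc)
            conds.extend([cond] * n_cells_tc)

    matrix = sp.hstack(cols, format="csr")
    n_cells = matrix.shape[1]
    barcodes = pd.Index([f"cell{i:05d}" for i in range(n_cells)])
    counts = SparseCounts(
        matrix=matrix,
        genes=pd.Index(gene_names),
        cells=barcodes,
        cell_conditions=pd.Series(conds, index=barcodes),
        mito=np.array([g.startswith("mt-") for g in gene_names]),
    )
    return counts, np.asarray(labels)


@dataclass
class RepSimSpec:
    """Parameters of the repertoire simulator.

    Clone frequencies are proportional to rank^(-alpha). ``expansion`` gives,
    per timepoint, the factor multiplying the frequencies of the top
    ``top_k_expanded`` clones before renormalization (1.0 = no expansion).
    The first ``n_public_clones`` ranks carry shared template identities
    across mice; the rest are mouse-private.
    """

    n_mice: int = 8
    timepoints: tuple[str, ...] = ("T0", "T2")
    clones_per_mouse: int = 500
    alpha: float = 1.0
    expansion: tuple[float, ...] = (1.0, 1.0)
    top_k_expanded: int = 3
    n_public_clones: int = 50
    reads_per_sample: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        if self.clones_per_mouse < 1:
            raise ParameterError("clones_per_mouse must be >= 1")
        if self.reads_per_sample <= 0:
            raise ParameterError("reads_per_sample must be > 0")
        if len(self.expansion) != len(self.timepoints):
            raise ParameterError("one expansion factor per timepoint required")
        if any(e < 1 for e in self.expansion):
            raise ParameterError("expansion factors must be >= 1")
        if self.alpha <= 0:
            raise ParameterError("power-law exponent must be > 0")
        if not 0 <= self.n_public_clones <= self.clones_per_mouse:
            raise ParameterError("n_public_clones out of range")


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _templates(rng: np.random.Generator, n: int, prefix: str) -> list[str]:
    """Distinct CDR-like amino-acid strings (CASS...F motif, random core)."""
    out = []
    seen = set()
    while len(out) < n:
        core = "".join(rng.choice(_AA, size=8))
        seq = f"CASS{core}F"
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return [f"{prefix}{s}" if prefix else s for s in out]


def simulate_repertoire(spec: RepSimSpec) -> list[RepertoireTable]:
    """Simulate one repertoire table per (mouse, timepoint); multinomial reads."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    public = _templates(rng, spec.n_public_clones, "")
    base_freq = np.arange(1, spec.clones_per_mouse + 1, dtype=float) ** (-spec.alpha)
    base_freq /= base_freq.sum()

    tables = []
    for m in range(spec.n_mice):
        n_private = spec.clones_per_mouse - spec.n_public_clones
        private = _templates(rng, n_private, f"m{m}.") if n_private else []
        clones = np.array(public + private, dtype=object)
        for ti, tp in enumerate(spec.timepoints):
            freq = base_freq.copy()
            freq[: spec.top_k_expanded] *= spec.expansion[ti]
            freq /= freq.sum()
            counts = rng.multinomial(spec.reads_per_sample, freq)
            keep = counts > 0
            tables.append(
                RepertoireTable(
                    sample_id=f"mouse{m}_{tp}",
                    mouse_id=f"mouse{m}",
                    timepoint=tp,
                    templates=clones[keep],
                    counts=counts[keep].astype(float),
                )
            )
    return tables


def simulate_reference_profiles(
    n_cell_types: int = 5,
    n_genes: int = 2000,
    markers_per_type: int = 20,
    fold_change: float = 16.0,
    replicates: int = 3,
    mean_log_mu: float = 2.0,
    mean_log_sigma: float = 1.0,
    dispersion: float = 10.0,
    seed: int = 0,
) -> tuple[BulkCounts, dict[str, list[str]]]:
    """Bulk reference profiles with planted cell-type markers.

    Returns (BulkCounts with ``replicates`` samples per type, truth marker
    genes per type). Each type's markers are up-shifted ``fold_change``-fold
    in that type only.
    """
    if replicates < 2:
        raise ParameterError("need >= 2 replicates per cell type")
    if n_cell_types < 2:
        raise ParameterError("need >= 2 cell types")
    if fold_change <= 0:
        raise ParameterError("fold_change must be > 0")
    if n_cell_types * markers_per_type > n_genes:
        raise ParameterError("markers exceed n_genes")
    rng = np.random.default_rng(seed)

    genes = [f"gene{i:04d}" for i in range(n_genes)]
    base = rng.lognormal(mean_log_mu, mean_log_sigma, n_genes)
    types = [f"type{t}" for t in range(n_cell_types)]
    truth = {
        types[t]: genes[t * markers_per_type : (t + 1) * markers_per_type]
        for t in range(n_cell_types)
    }

    cols = {}
    conditions = {}
    for t, name in enumerate(types):
        mu = base.copy()
        mu[t * markers_per_type : (t + 1) * markers_per_type] *= fold_change
        for r in range(replicates):
            sid = f"{name}_rep{r}"
            cols[sid] = _nb_draw(rng, mu, dispersion)
            conditions[sid] = name
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    bulk = BulkCounts(
        counts=counts,
        gene_lengths=pd.Series(1000.0, index=counts.index),
        sample_conditions=pd.Series(conditions),
    )
    return bulk, truth
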