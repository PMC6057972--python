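"""Readers and writers for the external formats the pipeline touches.

Single-cell matrices come in as 10x-style triplets (MatrixMarket coordinate
file plus one-column gene and barcode tables); repertoires as immunoSEQ-style
TSV exports; bulk counts as gene x sample TSV. Results go out as CSV or JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import BulkCounts, FormatError, MstTrajectory, RepertoireTable, SparseCounts

MITO_PREFIX = "mt-"


def _read_lines(path) -> list[str]:
    with open(path) as fh:
        return [ln.split("\t")[0].strip() for ln in fh if ln.strip()]


def read_mtx_triplet(
    matrix_path,
    genes_path,
    barcodes_path,
    metadata_path=None,
    mito_prefix: str = MITO_PREFIX,
) -> SparseCounts:
    """Load a genes x cells UMI matrix from MatrixMarket triplets.

    ``metadata_path`` (optional TSV: barcode, condition[, sample]) maps each
    barcode to its experimental condition; barcodes missing from the metadata
    are labelled ``"unknown"`` with a warning. Genes whose symbol starts with
    ``mito_prefix`` (case-insensitive) are flagged mitochondrial.
    """
    try:
        mat = scipy.io.mmread(matrix_path)
    except Exception as exc:  # malformed header / body
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    genes = _read_lines(genes_path)
    barcodes = _read_lines(barcodes_path)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"MTX header declares {mat.shape} but gene/barcode files list "
            f"{len(genes)} x {len(barcodes)} entries"
        )
    mat = sp.csr_matrix(mat)
    mat.sum_duplicates()
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError("UMI counts must be integral")

    conditions = pd.Series("unknown", index=pd.Index(barcodes), dtype=object)
    samples = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
        meta = meta.set_index(meta.columns[0])
        known = meta.index.intersection(conditions.index)
        missing = conditions.index.difference(meta.index)
        if len(missing):
            warnings.warn(
                f"{len(missing)} barcodes absent from metadata; labelled 'unknown'"
            )
        conditions.loc[known] = meta.loc[known, meta.columns[0]].values
        if meta.shape[1] >= 2:
            samples = pd.Series("unknown", index=conditions.index, dtype=object)
            samples.loc[known] = meta.loc[known, meta.columns[1]].values
    mito = np.array([g.lower().startswith(mito_prefix.lower()) for g in genes])
    return SparseCounts(
        matrix=mat,
        genes=pd.Index(genes),
        cells=pd.Index(barcodes),
        cell_conditions=conditions,
        mito=mito,
        cell_samples=samples,
    )


def write_mtx_triplet(counts: SparseCounts, out_dir) -> None:
    """Write a SparseCounts back to matrix.mtx / genes.tsv / barcodes.tsv / metadata.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", sp.coo_matrix(counts.matrix), field="integer")
    (out / "genes.tsv").write_text("".join(f"{g}\n" for g in counts.genes))
    (out / "barcodes.tsv").write_text("".join(f"{b}\n" for b in counts.cells))
    meta = pd.DataFrame({"barcode": counts.cells, "condition": counts.cell_conditions.values})
    if counts.cell_samples is not None:
        meta["sample"] = counts.cell_samples.values
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)


_TEMPLATE_COLS = ("template", "amino_acid", "aminoAcid", "aa", "cdr3_amino_acid")
_COUNT_COLS = ("count", "templates", "count (templates/reads)", "reads", "template_count")


def read_repertoire_tsv(
    path,
    sample_id: str | None = None,
    mouse_id: str = "",
    timepoint: str = "",
) -> RepertoireTable:
    """Read an immunoSEQ-style TSV of (template amino-acid sequence, count).

    Column names are matched case-insensitively against common export schemas.
    Duplicate template rows are summed. Sample/mouse/timepoint identity comes
    from the caller (manifest or filename convention), not the file.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty repertoire file: {path}") from exc
    if df.empty:
        raise FormatError(f"repertoire file has no rows: {path}")
    lower = {c.lower(): c for c in df.columns}
    tcol = next((lower[c.lower()] for c in _TEMPLATE_COLS if c.lower() in lower), None)
    ccol = next((lower[c.lower()] for c in _COUNT_COLS if c.lower() in lower), None)
    if tcol is None or ccol is None:
        raise FormatError(f"cannot locate template/count columns in {list(df.columns)}")
    counts = pd.to_numeric(df[ccol], errors="coerce")
    if counts.isna().any():
        raise FormatError("non-numeric count value in repertoire table")
    if (counts < 0).any():
        raise FormatError("negative count in repertoire table")
    merged = counts.groupby(df[tcol].astype(str)).sum()
    return RepertoireTable(
        sample_id=sample_id or Path(path).stem,
        mouse_id=mouse_id,
        timepoint=timepoint,
        templates=merged.index.to_numpy(dtype=object),
        counts=merged.to_numpy(dtype=float),
    )


def write_repertoire_tsv(table: RepertoireTable, path) -> None:
    pd.DataFrame({"template": table.templates, "count": table.counts.astype(int)}).to_csv(
        path, sep="\t", index=False
    )


def read_bulk_tsv(counts_path, lengths_path=None, conditions_path=None) -> BulkCounts:
    """Read a gene x sample TSV of integer counts, with optional gene lengths
    (TSV: gene, length in bases) and sample conditions (TSV: sample, condition)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = None
    if lengths_path is not None:
        ldf = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = ldf.iloc[:, 0].astype(float)
    conditions = None
    if conditions_path is not None:
        cdf = pd.read_csv(conditions_path, sep="\t", index_col=0)
        conditions = cdf.iloc[:, 0]
    return BulkCounts(counts=counts, gene_lengths=lengths, sample_conditions=conditions)


def write_results(obj, path, format: str = "csv") -> None:
    """Write a tabular result (DataFrame) or an MST trajectory to csv/json.

    Tabular CSV output round-trips through :func:`read_results`.
    """
    path = Path(path)
    if isinstance(obj, MstTrajectory):
        if format != "json":
            raise ValueError("MST trajectories are written as JSON")
        path.write_text(json.dumps(obj.to_dict(), indent=2))
        return
    if isinstance(obj, dict):
        path.write_text(json.dumps(obj, indent=2, default=float))
        return
    df = pd.DataFrame(obj)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        df.to_json(path, orient="records", indent=2)
    else:
        raise ValueError(f"unsupported format: {format}")


def read_results(path, format: str = "csv") -> pd.DataFrame:
    path = Path(path)
    if format == "csv":
        return pd.read_csv(path)
    if format == "json":
        return pd.read_json(path, orient="records")
    raise ValueError(f"unsupported format: {format}")


def read_manifest(path) -> pd.DataFrame:
    """Read a repertoire manifest TSV with columns: path, mouse_id, timepoint."""
    mf = pd.read_csv(path, sep="\t")
    required = {"path", "mouse_id", "timepoint"}
    if not required.issubset(mf.columns):
        raise FormatError(f"manifest must contain columns {sorted(required)}")
    return mf
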