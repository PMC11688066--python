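"""Readers and writers for the package's plain-text formats.

* count/TPM matrix: TSV, first column gene id, header row of sample ids;
  or MatrixMarket coordinate (``.mtx``) with two sidecar id lists
  (``<stem>_genes.txt`` and ``<stem>_samples.txt``, one id per line).
* gene lengths: TSV with columns ``gene_id``, ``length_bp``.
* sample metadata: TSV with columns ``sample_id``, ``tissue``,
  ``condition`` and optional ``time``, ``event``.
* gene sets: one gene id per line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .expression import validate_counts, validate_metadata


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}_genes.txt"), Path(f"{stem}_samples.txt")


def read_count_matrix(path, format: str = "tsv") -> pd.DataFrame:
    """Read a gene x sample count matrix (``tsv`` or ``mtx_triplet``)."""
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return validate_counts(df)
    if format == "mtx_triplet":
        genes_path, samples_path = _sidecar_paths(path)
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = genes_path.read_text().split()
        samples = samples_path.read_text().split()
        df = pd.DataFrame(np.asarray(mat), index=genes, columns=samples)
        return validate_counts(df)
    raise ValueError(f"unknown count matrix format {format!r}")


def write_count_matrix(counts: pd.DataFrame, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        counts.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "mtx_triplet":
        genes_path, samples_path = _sidecar_paths(path)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(counts.to_numpy()))
        genes_path.write_text("\n".join(map(str, counts.index)) + "\n")
        samples_path.write_text("\n".join(map(str, counts.columns)) + "\n")
    else:
        raise ValueError(f"unknown count matrix format {format!r}")


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a real-valued gene x sample matrix (e.g. TPM) from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in length table: {dup!r}")
    lengths = df.set_index("gene_id")["length_bp"].astype(int)
    if (lengths < 1).any():
        bad = lengths.index[lengths < 1][0]
        raise ValueError(f"gene length < 1 bp for {bad!r}")
    return lengths


def write_gene_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("length_bp").to_csv(path, sep="\t", index_label="gene_id")


def read_sample_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    return validate_metadata(df)


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_set(path) -> set[str]:
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


def write_gene_set(genes, path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + ("\n" if genes else ""))


def read_deg_table(path) -> pd.DataFrame:
    """Read a differential-expression result table.

    Expected columns: ``gene_id``, ``log2_fc``, ``p_value``, ``p_adj``,
    ``base_mean`` — the same format :func:`write_deg_table` emits, so
    externally computed screens (e.g. DESeq2 exports) can be plugged in.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    required = {"log2_fc", "p_value", "p_adj", "base_mean"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DEG table missing column(s): {sorted(missing)}")
    return df


def write_deg_table(deg: pd.DataFrame, path) -> None:
    deg.to_csv(path, sep="\t", index_label="gene_id")


def read_truth_table(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return df.set_index("gene_id")["class"]


def write_truth_table(truth: pd.Series, path) -> None:
    truth.rename("class").to_csv(path, sep="\t", index_label="gene_id")
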