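"""Count-matrix containers, TPM conversion and tumor/normal splitting.

Expression matrices are plain :class:`pandas.DataFrame` objects with genes
as rows (the index) and samples as columns. Sample metadata is a DataFrame
indexed by sample id with columns ``tissue`` (``"A"``/``"B"``),
``condition`` (``"tumor"``/``"normal"``) and optional ``time``/``event``
survival columns. Gene lengths are a :class:`pandas.Series` of base pairs
indexed by gene id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TISSUES = ("A", "B")
CONDITIONS = ("tumor", "normal")

#: numeric label coding used throughout: tissue A -> +1, tissue B -> -1
TISSUE_LABELS = {"A": 1.0, "B": -1.0}


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene x sample count matrix.

    Checks identifier uniqueness, non-negativity and integer-valued cells.
    Returns the matrix with an integer dtype.
    """
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate gene identifier: {dup!r}")
    if counts.columns.has_duplicates:
        dup = counts.columns[counts.columns.duplicated()][0]
        raise ValueError(f"duplicate sample identifier: {dup!r}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = np.argwhere(~np.vectorize(np.isreal)(values))
        r, c = bad[0]
        raise ValueError(
            f"non-numeric count at gene {counts.index[r]!r}, "
            f"sample {counts.columns[c]!r}"
        )
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at gene {counts.index[r]!r}, "
            f"sample {counts.columns[c]!r}"
        )
    if not np.allclose(values, np.round(values)):
        r, c = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise ValueError(
            f"non-integer count at gene {counts.index[r]!r}, "
            f"sample {counts.columns[c]!r}"
        )
    return counts.astype(np.int64)


def validate_metadata(meta: pd.DataFrame, sample_ids=None) -> pd.DataFrame:
    """Validate a sample metadata table (tissue/condition, optional survival)."""
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise ValueError(f"duplicate sample_id in metadata: {dup!r}")
    for col in ("tissue", "condition"):
        if col not in meta.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    bad_tissue = set(meta["tissue"]) - set(TISSUES)
    if bad_tissue:
        raise ValueError(f"unknown tissue value(s): {sorted(bad_tissue)}")
    bad_cond = set(meta["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown condition value(s): {sorted(bad_cond)}")
    has_time = "time" in meta.columns
    has_event = "event" in meta.columns
    if has_time != has_event:
        raise ValueError("survival columns 'time' and 'event' must appear together")
    if has_time:
        present = meta["time"].notna()
        if (present != meta["event"].notna()).any():
            raise ValueError("'time' and 'event' must be present for the same samples")
        if (meta.loc[present, "time"] < 0).any():
            raise ValueError("negative survival time")
    if sample_ids is not None:
        missing = set(sample_ids) - set(meta.index)
        if missing:
            raise ValueError(f"metadata missing sample(s): {sorted(missing)[:5]}")
    return meta


def counts_to_tpm(counts: pd.DataFrame, lengths_bp: pd.Series) -> pd.DataFrame:
    """Convert raw counts to transcripts-per-million.

    Per sample: ``rate_g = count_g / length_kb_g`` and
    ``tpm_g = rate_g / sum(rate) * 1e6``, so every column sums to 10^6.

    Parameters
    ----------
    counts : DataFrame, genes x samples, non-negative integers.
    lengths_bp : Series of gene lengths in base pairs, covering every gene.

    Raises
    ------
    ValueError
        If a gene has no length entry or a sample column is all zero
        (the normalization is undefined).
    """
    counts = validate_counts(counts)
    missing = counts.index.difference(lengths_bp.index)
    if len(missing):
        raise ValueError(f"missing gene length for {missing[0]!r}")
    lengths_kb = lengths_bp.reindex(counts.index).astype(float) / 1000.0
    if (lengths_kb <= 0).any():
        bad = lengths_kb.index[lengths_kb <= 0][0]
        raise ValueError(f"non-positive gene length for {bad!r}")
    rate = counts.div(lengths_kb, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts; TPM undefined")
    return rate.div(totals, axis=1) * 1e6


@dataclass
class LabeledSplit:
    """Tumor/normal expression submatrices with numeric tissue labels.

    ``X_tumor``/``X_normal`` are genes x samples DataFrames; ``y_tumor`` /
    ``y_normal`` are aligned vectors coded tissue A -> +1, tissue B -> -1
    (mean-centering happens downstream in the selectors).
    """

    X_tumor: pd.DataFrame
    y_tumor: pd.Series
    X_normal: pd.DataFrame
    y_normal: pd.Series


def split_and_label(tpm: pd.DataFrame, meta: pd.DataFrame) -> LabeledSplit:
    """Partition samples into tumor and normal splits with +/-1 tissue labels.

    Every sample of ``tpm`` must have a metadata record, and each condition
    must contain both tissues (otherwise tissue discrimination is undefined).
    """
    meta = validate_metadata(meta, sample_ids=tpm.columns)
    meta = meta.loc[tpm.columns]
    parts = {}
    for condition in CONDITIONS:
        cols = meta.index[meta["condition"] == condition]
        tissues = set(meta.loc[cols, "tissue"])
        if tissues != set(TISSUES):
            raise ValueError(
                f"condition {condition!r} does not contain both tissues "
                f"(found {sorted(tissues)})"
            )
        y = meta.loc[cols, "tissue"].map(TISSUE_LABELS).astype(float)
        parts[condition] = (tpm[cols], y)
    return LabeledSplit(
        X_tumor=parts["tumor"][0],
        y_tumor=parts["tumor"][1],
        X_normal=parts["normal"][0],
        y_normal=parts["normal"][1],
    )


def log_transform(tpm: pd.DataFrame) -> pd.DataFrame:
    """Optional log2(TPM + 1) transform (off by default in the pipeline)."""
    return np.log2(tpm + 1.0)
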