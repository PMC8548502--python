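"""Count-matrix handling, library-size normalization, and group log-fold
changes.

Counts live in a pandas DataFrame with genes as rows and samples as
columns. Normalization is log2 counts-per-million with a prior count added
after CPM scaling:

    log2(count / library_size * 1e6 + prior_count)

All downstream correlation and log-fold-change work operates on this
normalized view. Log-fold changes are differences of group means of
log2-CPM; no dispersion shrinkage is applied.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "validate_counts",
    "normalize_counts",
    "drop_zero_genes",
    "select_samples",
    "group_log_fold_change",
    "read_counts_tsv",
    "write_matrix_tsv",
]


def validate_counts(counts: pd.DataFrame) -> None:
    """Check ExpressionMatrix invariants: nonnegative integers, unique ids,
    positive library sizes."""
    if counts.index.has_duplicates:
        raise ValidationError("duplicate gene ids in count matrix")
    if counts.columns.has_duplicates:
        raise ValidationError("duplicate sample ids in count matrix")
    values = counts.to_numpy()
    if (values < 0).any():
        raise ValidationError("negative entries in count matrix")
    libsize = values.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise ValidationError(
            f"zero library size for sample(s): {list(counts.columns[zero])}"
        )


def normalize_counts(counts: pd.DataFrame, prior_count: float = 1.0) -> pd.DataFrame:
    """log2-CPM normalization: ``log2(count / libsize * 1e6 + prior)``.

    Deterministic; strictly increasing in counts within a sample.
    """
    validate_counts(counts)
    values = counts.to_numpy(dtype=float)
    libsize = values.sum(axis=0)
    cpm = values / libsize * 1e6
    return pd.DataFrame(np.log2(cpm + prior_count),
                        index=counts.index, columns=counts.columns)


def drop_zero_genes(counts: pd.DataFrame) -> pd.DataFrame:
    """Remove genes with zero counts in every sample (zero-variance rows
    break correlation-network construction). Logs how many were dropped."""
    keep = counts.to_numpy().sum(axis=1) > 0
    n_drop = int((~keep).sum())
    if n_drop:
        log.warning("dropping %d genes with all-zero counts", n_drop)
    return counts.loc[keep]


def select_samples(samples: pd.DataFrame, **clauses) -> pd.Index:
    """Return sample ids matching all metadata equality clauses.

    ``select_samples(meta, rearing="common_garden", habitat="forest")``
    """
    mask = pd.Series(True, index=samples.index)
    for col, val in clauses.items():
        if col not in samples.columns:
            raise ValidationError(f"unknown metadata column: {col}")
        mask &= samples[col] == val
    return samples.index[mask]


def group_log_fold_change(norm: pd.DataFrame, samples: pd.DataFrame,
                          group_a: dict, group_b: dict) -> pd.Series:
    """Per-gene log2 fold change: mean(group_b) - mean(group_a).

    ``group_a``/``group_b`` are metadata equality clauses (see
    :func:`select_samples`). Positive values mean higher expression in
    group_b. Groups must be disjoint and non-empty.
    """
    ids_a = select_samples(samples, **group_a)
    ids_b = select_samples(samples, **group_b)
    if len(ids_a) == 0:
        raise ValidationError(f"group_a selects no samples: {group_a}")
    if len(ids_b) == 0:
        raise ValidationError(f"group_b selects no samples: {group_b}")
    overlap = ids_a.intersection(ids_b)
    if len(overlap):
        raise ValidationError(
            f"groups overlap on {len(overlap)} sample(s), e.g. {overlap[0]}"
        )
    missing = [s for s in list(ids_a) + list(ids_b) if s not in norm.columns]
    if missing:
        raise ValidationError(f"samples absent from expression matrix: {missing[:5]}")
    lfc = norm[list(ids_b)].mean(axis=1) - norm[list(ids_a)].mean(axis=1)
    lfc.name = "lfc"
    return lfc


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a genes x samples count matrix (first column = gene id)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    validate_counts(counts)
    return counts


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")
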