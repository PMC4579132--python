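"""Expression-matrix conditioning for microarray inputs.

Three steps, applied in this order when all are needed: clamp raw
intensities into a box (removing low-end noise and high-end saturation),
drop uninformative genes by max/min ratio and max−min variation across
samples, and fill missing entries by k-nearest-neighbour averaging along
the gene axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.impute import KNNImputer

from .data import DomainError, ExpressionMatrix

__all__ = ["GeneFilterReport", "bound_expression", "filter_genes", "knn_impute"]


@dataclass
class GeneFilterReport:
    """Per-gene statistics and the outcome of :func:`filter_genes`."""

    kept_gene_ids: list[str]
    n_before: int
    n_after: int
    gene_max: np.ndarray
    gene_min: np.ndarray
    ratio: np.ndarray
    variation: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n_before": self.n_before,
            "n_after": self.n_after,
            "kept_gene_ids": list(self.kept_gene_ids),
        }


def bound_expression(
    data: ExpressionMatrix, lo: float = 20.0, hi: float = 16000.0
) -> ExpressionMatrix:
    """Clamp every value into [lo, hi]; identifiers and shape are unchanged.

    The defaults are the conventional microarray floor/ceiling of 20 and
    16,000 intensity units.  Idempotent.
    """
    if lo >= hi:
        raise ValueError("lo must be strictly below hi")
    return ExpressionMatrix(
        values=np.clip(data.values, lo, hi),
        sample_ids=list(data.sample_ids),
        gene_ids=list(data.gene_ids),
        allow_missing=data.allow_missing,
    )


def filter_genes(
    data: ExpressionMatrix, ratio_min: float = 5.0, variation_min: float = 500.0
) -> tuple[ExpressionMatrix, GeneFilterReport]:
    """Keep genes whose across-sample max/min ≥ ratio_min AND max−min ≥ variation_min.

    Boundary genes (ratio or variation exactly at the threshold) are kept.
    The matrix must be bounded first so every per-gene minimum is positive
    and the ratio is well defined.  Column order of surviving genes is
    preserved and their values are untouched.
    """
    g_max = data.values.max(axis=0)
    g_min = data.values.min(axis=0)
    if (g_min <= 0).any():
        raise DomainError(
            "a gene has a non-positive minimum; apply bound_expression first"
        )
    ratio = g_max / g_min
    variation = g_max - g_min
    keep = (ratio >= ratio_min) & (variation >= variation_min)
    kept_ids = [g for g, k in zip(data.gene_ids, keep) if k]
    filtered = ExpressionMatrix(
        values=data.values[:, keep],
        sample_ids=list(data.sample_ids),
        gene_ids=kept_ids,
    )
    report = GeneFilterReport(
        kept_gene_ids=kept_ids,
        n_before=data.n_genes,
        n_after=len(kept_ids),
        gene_max=g_max,
        gene_min=g_min,
        ratio=ratio,
        variation=variation,
    )
    return filtered, report


def knn_impute(data: ExpressionMatrix, k: int = 5) -> ExpressionMatrix:
    """Fill missing entries with the mean of the k nearest genes' values.

    Neighbours are found along the gene axis: the distance between two
    genes is the Euclidean distance over their co-observed samples, scaled
    by the number of co-observed entries so partially observed pairs are
    comparable.  A missing entry (sample i, gene g) becomes the mean of
    the k nearest genes' values at sample i (among neighbours observed
    there).  Observed entries are returned bit-identical.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if not data.has_missing:
        return data
    values = data.values
    if np.isnan(values).all(axis=0).any():
        raise DomainError("a gene has no observed value; it cannot be imputed")
    # genes as rows: KNNImputer then averages over gene-axis neighbours
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(values.T).T
    if np.isnan(filled).any():
        raise DomainError("imputation failed: no co-observed gene pairs")
    out = values.copy()
    miss = np.isnan(values)
    out[miss] = filled[miss]
    return ExpressionMatrix(
        values=out, sample_ids=list(data.sample_ids), gene_ids=list(data.gene_ids)
    )
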