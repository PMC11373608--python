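"""UMI-count normalization and highly-expressed-gene selection.

Raw counts are normalized per spot: a pseudocount of one is added to every
gene, each spot is scaled to sum to one, and values are moved to natural-log
scale.  The predicted gene panel is then the ``n_genes`` genes with the
highest mean normalized (pre-log) expression across all spots of all
sections, which makes the ranking invariant to section size.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .data import CountMatrix, ExpressionMatrix

__all__ = ["normalize_counts", "filter_top_genes", "subset_genes"]


def normalize_counts(counts: CountMatrix) -> ExpressionMatrix:
    """Pseudocount, per-spot sum-to-one normalization, natural log."""
    v = counts.values
    if v.shape[0] < 1 or v.shape[1] < 1:
        raise ValueError("need at least one spot and one gene")
    shifted = v.astype(float) + 1.0
    frac = shifted / shifted.sum(axis=1, keepdims=True)
    return ExpressionMatrix(np.log(frac), counts.gene_ids, counts.section_id)


def _normalized_fraction(section: CountMatrix | ExpressionMatrix) -> np.ndarray:
    """Pre-log normalized expression of one section (rows sum to one)."""
    if isinstance(section, CountMatrix):
        shifted = section.values.astype(float) + 1.0
        return shifted / shifted.sum(axis=1, keepdims=True)
    return np.exp(section.values)


def filter_top_genes(
    sections: Sequence[CountMatrix | ExpressionMatrix],
    n_genes: int = 250,
    statistic: str = "mean_normalized",
) -> np.ndarray:
    """Indices of the top ``n_genes`` genes by aggregate expression.

    ``statistic`` selects the ranking: ``"mean_normalized"`` (default) ranks
    by mean normalized pre-log expression pooled over all spots of all
    sections; ``"total_counts"`` ranks by raw UMI totals (counts input only).
    Ties break deterministically toward the lower gene index.  The returned
    index array is ordered by decreasing rank statistic.
    """
    if not sections:
        raise ValueError("need at least one section")
    gene_ids = sections[0].gene_ids
    for s in sections:
        if s.gene_ids != gene_ids:
            raise ValueError("sections must share an identical gene axis")
    total_genes = len(gene_ids)
    if not 1 <= n_genes <= total_genes:
        raise ValueError(
            f"n_genes must be in [1, {total_genes}], got {n_genes}"
        )
    if statistic == "mean_normalized":
        sums = np.zeros(total_genes)
        n_spots = 0
        for s in sections:
            frac = _normalized_fraction(s)
            sums += frac.sum(axis=0)
            n_spots += frac.shape[0]
        score = sums / n_spots
    elif statistic == "total_counts":
        score = np.zeros(total_genes)
        for s in sections:
            if not isinstance(s, CountMatrix):
                raise ValueError("total_counts ranking requires raw counts")
            score += s.values.sum(axis=0)
    else:
        raise ValueError(f"unknown ranking statistic {statistic!r}")
    # stable sort on -score keeps the lower gene index first among ties
    return np.argsort(-score, kind="stable")[:n_genes]


def subset_genes(
    matrix: CountMatrix | ExpressionMatrix, gene_index: np.ndarray
) -> CountMatrix | ExpressionMatrix:
    """Column-subset a matrix to a gene panel, preserving panel order."""
    gene_index = np.asarray(gene_index, dtype=int)
    ids = tuple(np.asarray(matrix.gene_ids, dtype=object)[gene_index])
    cls = type(matrix)
    return cls(matrix.values[:, gene_index], ids, matrix.section_id)
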