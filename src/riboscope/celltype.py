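"""Cell-type enrichment scoring from sorted-population expression.

The enrichment score for gene i in cell type j is its FPKM share across
cell types minus one half:  E_ij = FPKM_ij / sum_k FPKM_ik - 1/2, bounded
in [-0.5, 0.5].  Scores above 0.2 (strict) define cell-type-specific genes;
pairwise ratios of scores (Es) feed comparison GSEA rank lists.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

SPECIFICITY_CUTOFF = 0.2


def enrichment_scores(
    fpkm: pd.DataFrame, exclude_cell_types: tuple[str, ...] = ()
) -> pd.DataFrame:
    """E_ij over retained cell types; genes with zero total FPKM are dropped.

    ``exclude_cell_types`` removes columns before the share is computed
    (at least two cell types must remain).
    """
    missing = set(exclude_cell_types) - set(fpkm.columns)
    if missing:
        raise ValueError(f"unknown cell types to exclude: {sorted(missing)}")
    kept = fpkm.drop(columns=list(exclude_cell_types))
    if kept.shape[1] < 2:
        raise ValueError("need at least 2 cell types after exclusion")
    if (kept.to_numpy() < 0).any():
        raise ValueError("FPKM values must be non-negative")
    totals = kept.sum(axis=1)
    positive = totals > 0
    if not positive.any():
        raise ValueError("all gene rows have zero total FPKM")
    n_dropped = int((~positive).sum())
    if n_dropped:
        logger.info("enrichment_scores: dropped %d genes with zero total FPKM", n_dropped)
    sub = kept[positive]
    return sub.div(totals[positive], axis=0) - 0.5


def specific_gene_list(
    scores: pd.DataFrame, cell_type: str, cutoff: float = SPECIFICITY_CUTOFF
) -> list[str]:
    """Genes whose enrichment score in ``cell_type`` strictly exceeds the
    cutoff."""
    if cell_type not in scores.columns:
        raise ValueError(f"unknown cell type {cell_type!r}")
    col = scores[cell_type]
    return list(col.index[col > cutoff])


def comparison_scores(
    scores: pd.DataFrame, cell_type_k: str, cell_type_j: str
) -> pd.DataFrame:
    """Per-gene comparison score Es = E_ik / E_ij.

    Genes with a zero denominator are excluded (logged).  Rows where both
    enrichment scores are negative yield a positive Es of ambiguous meaning;
    they are computed exactly as written and flagged ``both_negative``.
    """
    if cell_type_k == cell_type_j:
        raise ValueError("cell types must differ")
    for ct in (cell_type_k, cell_type_j):
        if ct not in scores.columns:
            raise ValueError(f"unknown cell type {ct!r}")
    num = scores[cell_type_k]
    den = scores[cell_type_j]
    defined = den != 0
    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.info("comparison_scores: excluded %d genes with zero denominator", n_dropped)
    es = (num[defined] / den[defined]).rename("score")
    flags = ((num[defined] < 0) & (den[defined] < 0)).rename("both_negative")
    return pd.concat([es, flags], axis=1)


def rank_list(scores: pd.Series) -> pd.Series:
    """Descending rank list with deterministic lexicographic tie-breaking on
    gene identifier."""
    import numpy as np

    genes = scores.index.astype(str).to_numpy()
    values = scores.to_numpy(dtype=float)
    order = np.lexsort((genes, -values))
    return pd.Series(values[order], index=scores.index[order], name=scores.name)
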