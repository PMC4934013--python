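"""Treated-vs-untreated differential translation efficiency.

Fold changes of group TE and of normalized RNA means, a label-permutation
significance substitute (NOT RiboDiff: outputs are labelled
``permutation_test``), and the three-way TOP-motif / ribosomal-protein
overlap summary.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .quantify import normalize

logger = logging.getLogger(__name__)

FC_CUTOFF_LOG2 = 1.0
FDR_ALPHA = 0.05
STATISTIC_NAME = "permutation_test"  # substitute statistic, not RiboDiff


def te_fold_changes(
    te_treated: pd.Series,
    te_untreated: pd.Series,
    rna_treated: pd.DataFrame | None = None,
    rna_untreated: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """log2 fold changes (treated - untreated) of group TE and RNA level.

    ``te_*`` are gene -> log2 group TE series (genes failing the group
    threshold in a condition are absent there, hence absent from the
    output).  RNA fold changes come from jointly size-factor-normalized
    count frames, mean per condition.
    """
    genes = te_treated.index.intersection(te_untreated.index)
    out = pd.DataFrame(index=genes)
    out["log2_te_fc"] = te_treated.loc[genes] - te_untreated.loc[genes]
    if rna_treated is not None and rna_untreated is not None:
        joint = pd.concat(
            [rna_treated.add_prefix("trt::"), rna_untreated.add_prefix("unt::")], axis=1
        )
        norm = normalize(joint)
        trt = norm[[c for c in norm.columns if c.startswith("trt::")]].mean(axis=1)
        unt = norm[[c for c in norm.columns if c.startswith("unt::")]].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.log2(trt / unt)
        out["log2_rna_fc"] = fc.reindex(genes)
    else:
        out["log2_rna_fc"] = np.nan
    out.index.name = "gene"
    return out


def _label_permutations(n1: int, n2: int, n_perm: int, rng: np.random.Generator):
    """Index sets (into the pooled sample axis) assigned to condition 1.

    Enumerates all distinct assignments when feasible, else samples
    ``n_perm`` random ones.  The observed labeling is excluded from the
    enumeration path's count (it is compared separately with add-one
    smoothing).
    """
    total = n1 + n2
    all_combos = None
    from math import comb

    if comb(total, n1) <= n_perm:
        all_combos = [np.array(c) for c in combinations(range(total), n1)]
        return all_combos
    out = []
    for _ in range(n_perm):
        out.append(rng.permutation(total)[:n1])
    return out


def significance_flags(
    records: pd.DataFrame,
    te_treated_samples: pd.DataFrame,
    te_untreated_samples: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    fc_cutoff: float = FC_CUTOFF_LOG2,
    alpha: float = FDR_ALPHA,
) -> pd.DataFrame:
    """Flag genes with both BH FDR < alpha (condition-label permutation test
    on per-sample log2 TEs) and |log2 TE fold change| >= fc_cutoff.

    ``te_*_samples`` are genes x samples log2 TE matrices.  With fewer than
    two samples in either condition the permutation test is impossible; a
    prominent warning is raised and flags fall back to the fold-change
    criterion alone.
    """
    genes = records.index
    trt = te_treated_samples.reindex(genes)
    unt = te_untreated_samples.reindex(genes)
    n1, n2 = trt.shape[1], unt.shape[1]
    out = records.copy()
    if n1 < 2 or n2 < 2:
        warnings.warn(
            "fewer than 2 samples per condition: permutation test impossible; "
            "flagging on |log2 TE fold change| alone",
            stacklevel=2,
        )
        out["p_value"] = np.nan
        out["fdr_q"] = np.nan
        out["significant"] = out["log2_te_fc"].abs() >= fc_cutoff
        out["statistic"] = STATISTIC_NAME + "_unavailable"
        return out

    pooled = np.concatenate([trt.to_numpy(dtype=float), unt.to_numpy(dtype=float)], axis=1)
    complete = ~np.isnan(pooled).any(axis=1)
    obs = np.nanmean(pooled[:, :n1], axis=1) - np.nanmean(pooled[:, n1:], axis=1)
    rng = np.random.default_rng(seed)
    combos = _label_permutations(n1, n2, n_perm, rng)
    total = n1 + n2
    exceed = np.zeros(len(genes))
    for combo in combos:
        mask = np.zeros(total, dtype=bool)
        mask[combo] = True
        diff = pooled[:, mask].mean(axis=1) - pooled[:, ~mask].mean(axis=1)
        exceed += np.abs(diff) >= np.abs(obs) - 1e-12
    p = (1.0 + exceed) / (1.0 + len(combos))
    p = np.where(complete, p, np.nan)

    q = benjamini_hochberg(p)
    out["p_value"] = p
    out["fdr_q"] = q
    out["significant"] = (out["fdr_q"] < alpha) & (out["log2_te_fc"].abs() >= fc_cutoff)
    out["significant"] = out["significant"].fillna(False)
    out["statistic"] = STATISTIC_NAME
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q values; NaNs propagate."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    ps = p[mask]
    m = ps.size
    if m == 0:
        return q
    order = np.argsort(ps)
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[mask] = adj
    return q


def top_overlap(
    flagged_down_genes,
    top_gene_list,
    ribosomal_protein_list,
) -> dict[str, int]:
    """Three-way Venn counts between significantly down-regulated genes, TOP
    motif-containing genes, and ribosomal proteins."""
    a, b, c = set(flagged_down_genes), set(top_gene_list), set(ribosomal_protein_list)
    return {
        "flagged_only": len(a - b - c),
        "top_only": len(b - a - c),
        "ribosomal_only": len(c - a - b),
        "flagged_and_top": len((a & b) - c),
        "flagged_and_ribosomal": len((a & c) - b),
        "top_and_ribosomal": len((b & c) - a),
        "all_three": len(a & b & c),
        "n_flagged": len(a),
        "n_top": len(b),
        "n_ribosomal": len(c),
    }
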