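"""Pre-ranked classic (unweighted) GSEA with gene-set-permutation NES/FDR,
TE-binned gene-set construction, and margin-based GO cell-type assignment.

The running statistic increments 1/N_hit at set members and decrements
1/(N - N_hit) elsewhere; the enrichment score (ES) is the signed maximum
deviation from zero.  The null is built from random same-size gene sets
drawn from the rank list (fixed seed); NES divides ES by the mean of
matching-sign null scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_TE_BIN_WIDTH = 0.75
GO_ASSIGNMENT_MARGIN = 3.0


@dataclass
class GeneSetCollection:
    """Named gene sets; for TE bins, per-set centers (log2 TE units) are kept."""

    sets: dict[str, set[str]]
    bin_centers: dict[str, float] = field(default_factory=dict)
    bin_width: float | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


def te_bins(log2_te: pd.Series, width: float = DEFAULT_TE_BIN_WIDTH) -> GeneSetCollection:
    """Bin genes by log2 TE into half-open bins of fixed width anchored at
    the median.

    Bin edges sit at ``median + m * width`` for integer m; each gene falls in
    exactly one bin ``[edge, edge + width)`` and empty bins are dropped.  The
    number of bins is emergent from the data range.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if len(log2_te) == 0:
        raise ValueError("empty TE table")
    med = float(log2_te.median())
    idx = np.floor((log2_te.to_numpy(dtype=float) - med) / width).astype(int)
    sets: dict[str, set[str]] = {}
    centers: dict[str, float] = {}
    for m in sorted(set(idx)):
        name = f"te_bin_{m:+d}"
        members = set(log2_te.index[idx == m])
        sets[name] = members
        centers[name] = med + (m + 0.5) * width
    return GeneSetCollection(sets=sets, bin_centers=centers, bin_width=width)


def _es_from_hits(hit_ranks: np.ndarray, n_total: int) -> np.ndarray:
    """Signed-max-deviation ES for one or many sets of sorted 0-based hit ranks.

    ``hit_ranks`` has shape (..., k); peaks occur at hit positions and
    troughs immediately before them, which suffices to locate the extremum
    of the running sum.
    """
    ranks = np.asarray(hit_ranks)
    k = ranks.shape[-1]
    n_miss = n_total - k
    if n_miss <= 0:
        raise ValueError("gene set equals the entire rank list")
    j = np.arange(1, k + 1, dtype=float)
    hit_inc = 1.0 / k
    miss_dec = 1.0 / n_miss
    peak = j * hit_inc - (ranks + 1 - j) * miss_dec
    trough = (j - 1) * hit_inc - (ranks - (j - 1)) * miss_dec
    mx = peak.max(axis=-1)
    mn = trough.min(axis=-1)
    # equal-magnitude deviations resolve to the positive one; the small
    # tolerance keeps that rule stable under float rounding
    return np.where(mx >= -mn - 1e-12, mx, mn)


def enrichment_score(rank_list, gene_set) -> float:
    """Classic ES of one gene set against an ordered rank list."""
    genes = list(rank_list.index) if isinstance(rank_list, pd.Series) else list(rank_list)
    positions = np.array(sorted(i for i, g in enumerate(genes) if g in gene_set))
    if positions.size == 0:
        raise ValueError("gene set does not intersect the rank list")
    return float(_es_from_hits(positions, len(genes)))


def _null_es(rng: np.random.Generator, n_total: int, k: int, n_perm: int) -> np.ndarray:
    """ES of random same-size sets drawn from the list."""
    draws = np.argsort(rng.random((n_perm, n_total)), axis=1)[:, :k]
    draws.sort(axis=1)
    return _es_from_hits(draws, n_total)


def _normalize_against(null: np.ndarray, es: np.ndarray) -> np.ndarray:
    """NES = ES / |mean same-sign null|, sign-preserving; NaN when the
    matching-sign null is empty."""
    pos = null[null > 0]
    neg = null[null < 0]
    pos_mean = pos.mean() if pos.size else np.nan
    neg_mean = abs(neg.mean()) if neg.size else np.nan
    es = np.asarray(es, dtype=float)
    return np.where(es >= 0, es / pos_mean, es / neg_mean)


def preranked_gsea(
    rank_list: pd.Series,
    gene_sets,
    n_perm: int = 1000,
    seed: int = 0,
    shared_null: bool = True,
) -> pd.DataFrame:
    """Classic pre-ranked GSEA over a collection of gene sets.

    ``rank_list`` must be ordered descending (apply
    :func:`riboscope.celltype.rank_list` first to break ties);
    ``gene_sets`` is a :class:`GeneSetCollection` or a name -> set mapping.

    Returns a frame indexed by set name with columns ``es``, ``nes``,
    ``p``, ``fdr_q``, ``size``, ``n_perm``, ``seed``.  Nominal p is
    one-sided against the matching-sign null; FDR q follows the GSEA
    ratio-of-tail-fractions procedure on normalized null scores, clipped
    at 1.

    With ``shared_null`` (the default, and the reference implementation's
    behavior) all sets of the same size reuse one permutation null, which
    is efficient but makes p values across sets statistically dependent;
    set it to False for calibration studies that require independent nulls.
    """
    sets = gene_sets.sets if isinstance(gene_sets, GeneSetCollection) else dict(gene_sets)
    genes = list(rank_list.index)
    n_total = len(genes)
    if n_total != len(set(genes)):
        raise ValueError("rank list contains duplicate genes")
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    set_ranks: dict[str, np.ndarray] = {}
    for name, members in sets.items():
        ranks = np.array(sorted(gene_pos[g] for g in members if g in gene_pos))
        if ranks.size == 0:
            raise ValueError(f"gene set {name!r} does not intersect the rank list")
        if ranks.size == n_total:
            raise ValueError(f"gene set {name!r} equals the entire rank list")
        set_ranks[name] = ranks

    nulls: dict[int | str, np.ndarray] = {}
    if shared_null:
        for ranks in set_ranks.values():
            k = ranks.size
            if k not in nulls:
                nulls[k] = _null_es(rng, n_total, k, n_perm)
    else:
        for name, ranks in set_ranks.items():
            nulls[name] = _null_es(rng, n_total, ranks.size, n_perm)

    rows = []
    all_null_nes = []
    for name, ranks in set_ranks.items():
        k = ranks.size
        es = float(_es_from_hits(ranks, n_total))
        null = nulls[k if shared_null else name]
        nes = float(_normalize_against(null, np.array([es]))[0])
        pos = null[null > 0]
        neg = null[null < 0]
        if es >= 0:
            p = (1 + int((pos >= es).sum())) / (1 + pos.size) if pos.size else 1.0
        else:
            p = (1 + int((neg <= es).sum())) / (1 + neg.size) if neg.size else 1.0
        rows.append({"es": es, "nes": nes, "p": p, "size": k})
        all_null_nes.append(_normalize_against(null, null))
    result = pd.DataFrame(rows, index=pd.Index(list(set_ranks), name="gene_set"))

    null_nes = np.concatenate(all_null_nes)
    null_nes = null_nes[np.isfinite(null_nes)]
    obs = result["nes"].to_numpy()
    q = np.ones(len(result))
    n_null_pos = max((null_nes >= 0).sum(), 1)
    n_null_neg = max((null_nes < 0).sum(), 1)
    n_obs_pos = max((obs >= 0).sum(), 1)
    n_obs_neg = max((obs < 0).sum(), 1)
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            q[i] = np.nan
            continue
        if nes >= 0:
            num = (null_nes >= nes).sum() / n_null_pos
            den = (obs >= nes).sum() / n_obs_pos
        else:
            num = (null_nes <= nes).sum() / n_null_neg
            den = (obs <= nes).sum() / n_obs_neg
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    result["fdr_q"] = q
    result["n_perm"] = n_perm
    result["seed"] = seed
    return result


def nes_heatmap(
    te_bin_sets: GeneSetCollection,
    rank_lists: dict[str, pd.Series],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Matrix of NES: one pre-ranked GSEA per (cell-type rank list, TE bin).

    Rows are cell types, columns TE bins ordered by bin center.
    """
    order = sorted(te_bin_sets.names(), key=lambda n: te_bin_sets.bin_centers.get(n, 0.0))
    rows = {}
    for ct, rl in rank_lists.items():
        res = preranked_gsea(rl, te_bin_sets, n_perm=n_perm, seed=seed)
        rows[ct] = res["nes"].reindex(order)
    return pd.DataFrame(rows).T[order]


def go_cell_type_assignment(
    nes_matrix: pd.DataFrame,
    margin: float = GO_ASSIGNMENT_MARGIN,
    gene_sets: dict[str, set[str]] | None = None,
    log2_te: pd.Series | None = None,
) -> pd.DataFrame:
    """Assign each GO (row) to its argmax cell type iff the top NES beats the
    runner-up by at least ``margin``; otherwise leave unassigned.

    When ``gene_sets`` and ``log2_te`` are provided, assigned GOs also report
    the median log2 TE of member genes.
    """
    if nes_matrix.shape[1] < 2:
        raise ValueError("need at least two cell types")
    rows = []
    for go, row in nes_matrix.iterrows():
        vals = row.to_numpy(dtype=float)
        order = np.argsort(vals)[::-1]
        top, runner = vals[order[0]], vals[order[1]]
        assigned = (top - runner) >= margin
        cell_type = nes_matrix.columns[order[0]] if assigned else None
        median_te = np.nan
        if assigned and gene_sets is not None and log2_te is not None:
            members = [g for g in gene_sets.get(go, ()) if g in log2_te.index]
            if members:
                median_te = float(log2_te.loc[members].median())
        rows.append(
            {
                "cell_type": cell_type,
                "assigned": bool(assigned),
                "margin": float(top - runner),
                "median_log2_te": median_te,
            }
        )
    return pd.DataFrame(rows, index=nes_matrix.index)
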