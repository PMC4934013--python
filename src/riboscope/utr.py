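"""5'UTR feature analysis.

Ribosomal-density flags, upstream AUG scanning, abundance-weighted UTR
length and GC content, binned median TE, and Mann-Whitney comparisons.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .models import TranscriptModel

logger = logging.getLogger(__name__)

#: total sample size at or below which the exact Mann-Whitney null is used
EXACT_MW_LIMIT = 12

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def utr5_density_flags(
    count_table, models: list[TranscriptModel] | None = None
) -> pd.Series:
    """True for genes with at least one ribosome footprint in the 5'UTR.

    ``count_table`` is a :class:`~riboscope.quantify.RegionCountTable` (its
    ribo samples are summed) or a genes x samples UTR5 count frame.  Genes
    without an annotated 5'UTR (when ``models`` is given) are excluded.
    """
    from .quantify import RegionCountTable

    if isinstance(count_table, RegionCountTable):
        ribo = count_table.select(assay="ribo")
        utr5 = ribo.region("utr5")
    else:
        utr5 = count_table
    totals = utr5.sum(axis=1)
    flags = (totals >= 1).rename("has_utr5_density")
    if models is not None:
        with_utr5 = {m.gene_id for m in models if m.cds_start > 0}
        flags = flags[flags.index.isin(with_utr5)]
    return flags


def uaug_scan(utr5_sequence: str) -> tuple[bool, int]:
    """Scan a 5'UTR for AUG/ATG in any frame, counting overlapping starts."""
    s = utr5_sequence.upper().replace("U", "T")
    count = sum(1 for i in range(len(s) - 2) if s[i : i + 3] == "ATG")
    return count > 0, count


def weighted_utr5_stats(models: list[TranscriptModel]) -> pd.DataFrame:
    """Abundance-weighted 5'UTR length and GC content per gene.

    length = sum_t a_t * len_t / sum_t a_t and likewise for per-isoform GC
    fraction.  Genes whose isoform abundances sum to zero, or with no
    annotated 5'UTR on any isoform, are excluded (logged).
    """
    per_gene: dict[str, list[tuple[float, int, float]]] = {}
    for m in models:
        ulen = m.cds_start
        if ulen == 0:
            continue
        seq = m.utr5_sequence.upper()
        gc = (seq.count("G") + seq.count("C")) / ulen
        per_gene.setdefault(m.gene_id, []).append((m.isoform_abundance, ulen, gc))
    rows = {}
    n_zero = 0
    for gene, items in per_gene.items():
        total = sum(a for a, _, _ in items)
        if total <= 0:
            n_zero += 1
            continue
        length = sum(a * l for a, l, _ in items) / total
        gc = sum(a * g for a, _, g in items) / total
        rows[gene] = {"utr5_length_weighted": length, "utr5_gc_weighted": gc}
    if n_zero:
        logger.info("weighted_utr5_stats: excluded %d genes with zero total abundance", n_zero)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_id"
    return out


def build_feature_table(
    models: list[TranscriptModel],
    count_table,
    log2_te: pd.Series,
) -> pd.DataFrame:
    """Assemble the per-gene UTR feature record.

    ``has_uaug`` is evaluated (abundance-weighted majority is not needed:
    any isoform's UTR5 containing an AUG flags the gene) only for genes with
    5'UTR ribosomal density, mirroring the density/uAUG pairing.
    """
    flags = utr5_density_flags(count_table, models)
    stats_df = weighted_utr5_stats(models)
    uaug: dict[str, bool] = {}
    for m in models:
        if m.cds_start == 0:
            continue
        found, _ = uaug_scan(m.utr5_sequence)
        uaug[m.gene_id] = uaug.get(m.gene_id, False) or found
    out = stats_df.copy()
    out["has_utr5_density"] = flags.reindex(out.index).fillna(False)
    out["has_uaug"] = pd.Series(uaug).reindex(out.index).astype("boolean")
    out.loc[~out["has_utr5_density"], "has_uaug"] = pd.NA
    out["cds_log2_te"] = log2_te.reindex(out.index)
    return out


def binned_median_te(
    records: pd.DataFrame,
    gc_bins,
    length_bins,
) -> dict[str, pd.Series | pd.DataFrame]:
    """Median log2 TE per GC bin, per length bin, and per (gc, length) cell.

    ``records`` needs columns ``utr5_gc_weighted``, ``utr5_length_weighted``,
    ``cds_log2_te``.  Empty bins are NaN.
    """
    df = records.dropna(subset=["cds_log2_te"]).copy()
    df["gc_bin"] = pd.cut(df["utr5_gc_weighted"], bins=gc_bins)
    df["len_bin"] = pd.cut(df["utr5_length_weighted"], bins=length_bins)
    by_gc = df.groupby("gc_bin", observed=False)["cds_log2_te"].median()
    by_len = df.groupby("len_bin", observed=False)["cds_log2_te"].median()
    matrix = df.pivot_table(
        index="gc_bin",
        columns="len_bin",
        values="cds_log2_te",
        aggfunc="median",
        observed=False,
    )
    return {"by_gc": by_gc, "by_length": by_len, "matrix": matrix}


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p <= threshold:
            return stars
    return ""


def mann_whitney_u(group_a, group_b) -> tuple[float, float, str]:
    """Mann-Whitney U (midrank ties) with a two-sided p value.

    The exact null is enumerated when n_a + n_b <= 12 and there are no ties;
    otherwise the normal approximation with tie and continuity corrections
    is used.  Returns (U, p, star annotation).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size + b.size <= EXACT_MW_LIMIT and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    u = float(res.statistic)
    p = float(min(res.pvalue, 1.0))
    return u, p, significance_stars(p)


def uaug_te_comparison(
    records: pd.DataFrame,
    cell_type_gene_lists: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Median CDS TE of (density + uAUG) vs (density, no uAUG) genes, per
    cell-type stratum and for all genes, with Mann-Whitney p values.

    Strata where either group is empty are skipped (logged).
    """
    strata: dict[str, pd.DataFrame] = {"all": records}
    if cell_type_gene_lists:
        for ct, genes in cell_type_gene_lists.items():
            strata[ct] = records[records.index.isin(genes)]
    rows = []
    for name, sub in strata.items():
        sub = sub[sub["has_utr5_density"].astype(bool) & sub["cds_log2_te"].notna()]
        with_uaug = sub[sub["has_uaug"].astype(bool)]["cds_log2_te"]
        without = sub[~sub["has_uaug"].astype(bool)]["cds_log2_te"]
        if len(with_uaug) == 0 or len(without) == 0:
            logger.info("uaug_te_comparison: skipping stratum %r (empty group)", name)
            continue
        u, p, star = mann_whitney_u(with_uaug, without)
        rows.append(
            {
                "stratum": name,
                "n_uaug": len(with_uaug),
                "n_no_uaug": len(without),
                "median_te_uaug": float(with_uaug.median()),
                "median_te_no_uaug": float(without.median()),
                "u_statistic": u,
                "p_value": p,
                "stars": star,
            }
        )
    return pd.DataFrame(rows).set_index("stratum") if rows else pd.DataFrame()
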