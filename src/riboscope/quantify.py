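"""Region counting, size-factor normalization, translation efficiency,
RiboTag enrichment, and the qPCR abundance conversion.

Translation efficiency (TE) is the ratio of size-factor-normalized ribosome
footprint CDS counts to normalized RNA-seq CDS counts.  Count thresholds
(37 per sample, 75 when both samples in a group are combined) are applied to
raw counts and guarantee positive denominators, so no pseudocounts are used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import REGIONS, TranscriptModel, genes_of, index_by_transcript

logger = logging.getLogger(__name__)

#: raw-count threshold for per-sample TE
PER_SAMPLE_MIN_COUNT = 37
#: raw-count threshold when the TE of both samples in a group is used
GROUP_MIN_COUNT = 75

ASSAYS = ("ribo", "rna", "ip", "homogenate")


@dataclass
class RegionCountTable:
    """gene x sample x region non-negative integer counts plus sample metadata.

    ``counts`` is indexed by gene with MultiIndex columns (sample, region);
    ``samples`` is indexed by sample with columns ``assay`` and ``condition``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.counts.columns, pd.MultiIndex):
            raise ValueError("counts must have MultiIndex columns (sample, region)")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns.get_level_values(0)) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")

    @property
    def sample_names(self) -> list[str]:
        return list(self.samples.index)

    def region(self, region: str) -> pd.DataFrame:
        """genes x samples counts for one region."""
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        sub = self.counts.xs(region, axis=1, level=1)
        return sub

    def gene_totals(self) -> pd.DataFrame:
        """genes x samples counts summed over regions."""
        return self.counts.T.groupby(level=0).sum().T

    def select(self, assay: str | None = None, condition: str | None = None) -> "RegionCountTable":
        meta = self.samples
        if assay is not None:
            meta = meta[meta["assay"] == assay]
        if condition is not None:
            meta = meta[meta["condition"] == condition]
        keep = list(meta.index)
        cols = [c for c in self.counts.columns if c[0] in keep]
        return RegionCountTable(self.counts[cols], meta)

    @staticmethod
    def from_region_frames(
        frames: dict[str, pd.DataFrame], samples: pd.DataFrame
    ) -> "RegionCountTable":
        """Build from per-region genes x samples frames sharing an index."""
        pieces = {}
        for region, df in frames.items():
            for s in df.columns:
                pieces[(s, region)] = df[s]
        counts = pd.DataFrame(pieces)
        counts.columns = pd.MultiIndex.from_tuples(counts.columns)
        # stable sample order from metadata
        counts = counts.reindex(
            columns=pd.MultiIndex.from_product([list(samples.index), list(frames)]),
        ).fillna(0).astype(np.int64)
        return RegionCountTable(counts, samples)

    @staticmethod
    def concat(tables: list["RegionCountTable"]) -> "RegionCountTable":
        counts = pd.concat([t.counts for t in tables], axis=1).fillna(0).astype(np.int64)
        samples = pd.concat([t.samples for t in tables], axis=0)
        if samples.index.duplicated().any():
            raise ValueError("duplicate sample names across tables")
        return RegionCountTable(counts, samples)


def count_regions(
    alignments: pd.DataFrame,
    models: list[TranscriptModel],
    sample: str = "s1",
    assay: str = "ribo",
    condition: str = "untreated",
) -> RegionCountTable:
    """Count uniquely mapped footprints per gene and region (by 5' position).

    Every alignment (duplicate-flagged or not) is counted once; alignments
    straddling a region boundary are assigned by the region of their 5' end.
    """
    by_tid = index_by_transcript(models)
    genes = genes_of(models)
    frames = {r: pd.DataFrame(0, index=genes, columns=[sample], dtype=np.int64) for r in REGIONS}
    if len(alignments):
        tids = alignments["transcript_id"].to_numpy()
        pos = alignments["five_prime_pos"].to_numpy(dtype=np.int64)
        gene_arr = np.array([by_tid[t].gene_id for t in tids], dtype=object)
        starts = np.array([by_tid[t].cds_start for t in tids], dtype=np.int64)
        ends = np.array([by_tid[t].cds_end for t in tids], dtype=np.int64)
        region_arr = np.where(pos < starts, "utr5", np.where(pos < ends, "cds", "utr3"))
        tally = pd.DataFrame({"gene": gene_arr, "region": region_arr}).value_counts()
        for (g, r), c in tally.items():
            frames[r].loc[g, sample] = int(c)
    meta = pd.DataFrame({"assay": [assay], "condition": [condition]}, index=[sample])
    meta.index.name = "sample"
    return RegionCountTable.from_region_frames(frames, meta)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq formula, re-implemented).

    For each gene, form the geometric mean of its counts across samples
    (genes with any zero count are excluded); each sample's factor is the
    median over included genes of count / geometric mean.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.ndim != 2 or mat.shape[1] == 0:
        raise ValueError("counts must be a genes x samples table")
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has nonzero counts in all samples")
    sub = mat[positive]
    log_geomean = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def _as_cds_frame(table) -> pd.DataFrame:
    if isinstance(table, RegionCountTable):
        return table.region("cds")
    return table


def translation_efficiency(
    ribo_counts,
    rna_counts,
    mode: str = "per_sample",
    min_count: int | None = None,
) -> pd.DataFrame:
    """Per-gene translation efficiency from CDS counts.

    Parameters
    ----------
    ribo_counts, rna_counts:
        genes x samples CDS count frames (or :class:`RegionCountTable`, from
        which the CDS region is taken).  Samples are paired positionally
        between the two assays.
    mode:
        ``"per_sample"`` computes one TE per matched sample pair, keeping a
        (gene, sample) entry only when both raw counts are at least 37.
        ``"group"`` averages the per-sample TEs over all pairs, keeping a gene
        only when every raw count (both assays, all samples) is at least 75.
    min_count:
        Override the mode's default raw-count threshold.

    Returns
    -------
    Tidy frame with columns ``gene``, ``sample``, ``te``, ``log2_te``.  In
    group mode ``sample`` is the constant ``"group"``.
    """
    ribo = _as_cds_frame(ribo_counts)
    rna = _as_cds_frame(rna_counts)
    if mode not in ("per_sample", "group"):
        raise ValueError(f"unknown mode {mode!r}")
    genes = ribo.index.intersection(rna.index)
    ribo = ribo.loc[genes]
    rna = rna.loc[genes]
    if ribo.shape[1] != rna.shape[1]:
        raise ValueError("ribo and rna tables must have matched sample counts")
    threshold = min_count if min_count is not None else (
        PER_SAMPLE_MIN_COUNT if mode == "per_sample" else GROUP_MIN_COUNT
    )
    ribo_norm = normalize(ribo)
    rna_norm = normalize(rna)

    records = []
    n_samples = ribo.shape[1]
    per_sample_te = np.full((len(genes), n_samples), np.nan)
    for i in range(n_samples):
        rcol, ncol = ribo.columns[i], rna.columns[i]
        ok = (ribo[rcol] >= threshold) & (rna[ncol] >= threshold)
        te = ribo_norm[rcol] / rna_norm[ncol]
        per_sample_te[:, i] = te.to_numpy()
        if mode == "per_sample":
            for gene in genes[ok]:
                t = float(te.loc[gene])
                records.append((gene, str(rcol), t, np.log2(t)))
    if mode == "group":
        raw_ok = (ribo >= threshold).all(axis=1) & (rna >= threshold).all(axis=1)
        mean_te = per_sample_te.mean(axis=1)
        for gene, t in zip(genes[raw_ok], mean_te[raw_ok.to_numpy()]):
            records.append((gene, "group", float(t), float(np.log2(t))))
    return pd.DataFrame(records, columns=["gene", "sample", "te", "log2_te"])


def group_te_series(te_table: pd.DataFrame) -> pd.Series:
    """Extract a gene -> log2 TE series from a group-mode TE table."""
    sub = te_table[te_table["sample"] == "group"]
    return sub.set_index("gene")["log2_te"]


def ribotag_enrichment_score(
    ip_counts, homogenate_counts
) -> pd.Series:
    """Per-gene RiboTag enrichment: normalized IP over normalized homogenate.

    Both tables are size-factor normalized jointly; the score is the mean
    normalized IP count divided by the mean normalized homogenate count.
    Genes with zero mean homogenate signal are excluded (logged).
    """
    ip = _as_cds_frame(ip_counts)
    hom = _as_cds_frame(homogenate_counts)
    genes = ip.index.intersection(hom.index)
    ip = ip.loc[genes]
    hom = hom.loc[genes]
    joint = pd.concat(
        [ip.add_prefix("ip::"), hom.add_prefix("hom::")], axis=1
    )
    norm = normalize(joint)
    ip_mean = norm[[c for c in norm.columns if c.startswith("ip::")]].mean(axis=1)
    hom_mean = norm[[c for c in norm.columns if c.startswith("hom::")]].mean(axis=1)
    defined = hom_mean > 0
    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.info("ribotag_enrichment_score: dropped %d genes with zero homogenate signal", n_dropped)
    score = (ip_mean[defined] / hom_mean[defined]).rename("ribotag_enrichment")
    return score


def cq_to_abundance(cq_values) -> np.ndarray:
    """Convert qPCR CQ values to max-normalized abundances.

    abundance = 2 ** (1 - CQ) per fraction, then divided by the maximum so
    the most abundant fraction is exactly 1.
    """
    cq = np.asarray(cq_values, dtype=float)
    if cq.size == 0:
        raise ValueError("empty CQ vector")
    abundance = 2.0 ** (1.0 - cq)
    return abundance / abundance.max()
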