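"""Synthetic data with the statistical structure the analysis assumes.

Generates transcript annotations with AUG-controlled 5'UTRs, cell-type
expression with a bimodal neuronal TE mixture, ligation-free-structured
footprint reads (G-rich prefix + footprint + poly(A) tail), RNA-seq count
tables, and RiboTag IP/homogenate pairs — all pure functions of
(config, seed) so every downstream stage is testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .models import REGIONS, TranscriptModel
from .quantify import RegionCountTable

CELL_TYPES = (
    "astrocyte",
    "neuron",
    "opc",
    "newly_formed_oligodendrocyte",
    "myelinating_oligodendrocyte",
    "microglia",
    "endothelial",
)

#: default mixture of log2 TE components per cell type: (weight, mean, sd).
#: Neurons are bimodal (very high or very low translation); microglia and
#: myelinating oligodendrocytes sit low, OPC > newly formed > myelinating.
DEFAULT_TE_MIXTURE: dict[str, tuple[tuple[float, float, float], ...]] = {
    "astrocyte": ((1.0, 0.0, 0.6),),
    "neuron": ((0.5, -1.5, 0.5), (0.5, 1.5, 0.5)),
    "opc": ((1.0, 0.8, 0.5),),
    "newly_formed_oligodendrocyte": ((1.0, 0.0, 0.5),),
    "myelinating_oligodendrocyte": ((1.0, -0.8, 0.5),),
    "microglia": ((1.0, -1.0, 0.5),),
    "endothelial": ((1.0, 0.0, 0.6),),
}

#: G-rich 5' prefix composition from terminal-transferase activity
PREFIX_COMPOSITION = {"G": 0.7, "C": 0.1, "A": 0.1, "T": 0.1}
PREFIX_LENGTH = 5
MIN_POLYA = 8


def cell_type_labels(n: int) -> list[str]:
    if n <= len(CELL_TYPES):
        return list(CELL_TYPES[:n])
    return list(CELL_TYPES) + [f"cell_type_{i}" for i in range(len(CELL_TYPES), n)]


class FastqRead(NamedTuple):
    read_id: str
    sequence: str
    quality: str


def _check_interval(name: str, iv, integer: bool = True) -> None:
    lo, hi = iv
    if lo > hi:
        raise ValueError(f"{name}: degenerate range {iv} (min > max)")
    if integer and (lo < 0 or int(lo) != lo or int(hi) != hi):
        raise ValueError(f"{name}: must be a non-negative integer interval, got {iv}")


def _check_proportion(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass
class SimulationConfig:
    """Generative parameters; validated eagerly."""

    n_genes: int
    n_cell_types: int = 7
    cds_length_range: tuple[int, int] = (300, 900)
    utr5_length_range: tuple[int, int] = (60, 240)
    utr3_length_range: tuple[int, int] = (60, 180)
    utr5_gc_range: tuple[float, float] = (0.35, 0.75)
    frac_uaug_genes: float = 0.4
    te_log2_distribution: Mapping[str, Sequence[tuple[float, float, float]]] | None = None
    cds_read_fraction: tuple[float, float, float] = (0.10, 0.85, 0.05)  # (utr5, cds, utr3)
    periodicity_strength: float = 0.9
    top_gene_fraction: float = 0.05
    top_repression_log2: float = -2.0
    ribotag_target_cell_type: int = 1
    footprint_length_dist: Mapping[int, float] = field(
        default_factory=lambda: {28: 0.2, 29: 0.3, 30: 0.3, 31: 0.2}
    )
    read_length: int = 75
    noise: str = "poisson"  # or "nb"
    nb_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_cell_types < 2:
            raise ValueError("n_cell_types must be >= 2")
        _check_interval("cds_length_range", self.cds_length_range)
        _check_interval("utr5_length_range", self.utr5_length_range)
        _check_interval("utr3_length_range", self.utr3_length_range)
        _check_interval("utr5_gc_range", self.utr5_gc_range, integer=False)
        for name in ("frac_uaug_genes", "periodicity_strength", "top_gene_fraction"):
            _check_proportion(name, getattr(self, name))
        for p in self.utr5_gc_range:
            _check_proportion("utr5_gc_range", p)
        if self.cds_length_range[0] < 6:
            raise ValueError("cds_length_range minimum must be >= 6")
        split = self.cds_read_fraction
        if len(split) != 3 or any(f < 0 for f in split) or abs(sum(split) - 1.0) > 1e-9:
            raise ValueError("cds_read_fraction must be 3 non-negative fractions summing to 1")
        if not 0 <= self.ribotag_target_cell_type < self.n_cell_types:
            raise ValueError("ribotag_target_cell_type out of range")
        w = sum(self.footprint_length_dist.values())
        if abs(w - 1.0) > 1e-9 or any(v < 0 for v in self.footprint_length_dist.values()):
            raise ValueError("footprint_length_dist weights must be >= 0 and sum to 1")
        if self.read_length < PREFIX_LENGTH + max(self.footprint_length_dist) + MIN_POLYA:
            raise ValueError("read_length too short for prefix + footprint + poly(A)")
        if self.noise not in ("poisson", "nb"):
            raise ValueError("noise must be 'poisson' or 'nb'")
        mixture = self.te_mixture()
        for ct, comps in mixture.items():
            total = sum(c[0] for c in comps)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"TE mixture weights for {ct} must sum to 1")

    def te_mixture(self) -> dict[str, Sequence[tuple[float, float, float]]]:
        labels = cell_type_labels(self.n_cell_types)
        if self.te_log2_distribution is not None:
            missing = [ct for ct in labels if ct not in self.te_log2_distribution]
            if missing:
                raise ValueError(f"te_log2_distribution missing cell types: {missing}")
            return {ct: self.te_log2_distribution[ct] for ct in labels}
        return {ct: DEFAULT_TE_MIXTURE.get(ct, ((1.0, 0.0, 0.6),)) for ct in labels}

    @property
    def cell_types(self) -> list[str]:
        return cell_type_labels(self.n_cell_types)


@dataclass
class SyntheticTruth:
    """Ground truth keyed identically to the emitted annotation.

    ``genes`` is indexed by gene_id with columns ``cell_type``, ``is_top``,
    ``has_uaug``, ``log2_te_untreated``, ``log2_te_treated``;
    ``fpkm`` is gene x cell-type expected FPKM.
    """

    genes: pd.DataFrame
    fpkm: pd.DataFrame

    def bulk_fpkm(self) -> pd.Series:
        """Tissue-level expression: mean FPKM over cell types."""
        return self.fpkm.mean(axis=1)

    def log2_te(self, condition: str) -> pd.Series:
        col = f"log2_te_{condition}"
        if col not in self.genes:
            raise ValueError(f"unknown condition {condition!r}")
        return self.genes[col]


BASES = np.array(list("ACGT"))


def _random_sequence(rng: np.random.Generator, length: int, gc: float,
                     gc_range: tuple[float, float]) -> str:
    """Sequence of fixed composition: GC count from target, clamped in range."""
    lo = int(np.ceil(gc_range[0] * length - 1e-9))
    hi = int(np.floor(gc_range[1] * length + 1e-9))
    gc_count = int(round(gc * length))
    if lo <= hi:
        gc_count = min(max(gc_count, lo), hi)
    chars = np.empty(length, dtype="<U1")
    gc_bases = rng.choice(["G", "C"], size=gc_count)
    at_bases = rng.choice(["A", "T"], size=length - gc_count)
    chars[:gc_count] = gc_bases
    chars[gc_count:] = at_bases
    return "".join(chars[rng.permutation(length)])


def _strip_aug(seq: str) -> str:
    """Remove every ATG occurrence; T->A swaps preserve GC content."""
    s = list(seq)
    i = "".join(s).find("ATG")
    while i >= 0:
        s[i + 1] = "A"
        i = "".join(s).find("ATG")
    return "".join(s)


def _utr5_with_uaug(rng: np.random.Generator, length: int, gc: float,
                    gc_range: tuple[float, float]) -> str:
    """UTR5 guaranteed to contain >= 1 ATG; composition-aware insertion."""
    if length < 3:
        raise ValueError("UTR5 too short to hold an AUG")
    lo = int(np.ceil(gc_range[0] * length - 1e-9))
    hi = int(np.floor(gc_range[1] * length + 1e-9))
    gc_count = int(round(gc * length))
    if lo <= hi:
        gc_count = min(max(gc_count, lo), hi)
    # ATG contributes one G and two A/T; remaining length-3 bases make up the rest
    rest_gc = gc_count - 1
    if rest_gc < 0 or rest_gc > length - 3:
        raise ValueError(
            f"utr5_gc_range {gc_range} infeasible with an inserted AUG at length {length}"
        )
    rest = _random_sequence(rng, length - 3, rest_gc / max(length - 3, 1), (0.0, 1.0))
    pos = int(rng.integers(0, length - 2))
    return rest[:pos] + "ATG" + rest[pos:]


def simulate_annotation(config: SimulationConfig):
    """Generate transcripts plus ground truth; deterministic for fixed seed.

    Returns ``(models, truth)`` where flagged genes contain >= 1 AUG in their
    5'UTR and unflagged genes contain none.
    """
    rng = np.random.default_rng(config.seed)
    labels = config.cell_types
    mixture = config.te_mixture()

    n = config.n_genes
    uaug_flags = np.zeros(n, dtype=bool)
    uaug_flags[: int(round(config.frac_uaug_genes * n))] = True
    uaug_flags = uaug_flags[rng.permutation(n)]
    top_flags = np.zeros(n, dtype=bool)
    top_flags[: int(round(config.top_gene_fraction * n))] = True
    top_flags = top_flags[rng.permutation(n)]
    cell_type_idx = rng.integers(0, config.n_cell_types, size=n)

    models: list[TranscriptModel] = []
    gene_rows = []
    fpkm_rows = []
    for i in range(n):
        gene_id = f"G{i:05d}"
        tid = f"T{i:05d}.1"
        utr5_len = int(rng.integers(config.utr5_length_range[0], config.utr5_length_range[1] + 1))
        utr3_len = int(rng.integers(config.utr3_length_range[0], config.utr3_length_range[1] + 1))
        cds_len = int(rng.integers(config.cds_length_range[0], config.cds_length_range[1] + 1))
        cds_len -= cds_len % 3
        gc = float(rng.uniform(*config.utr5_gc_range))
        if uaug_flags[i]:
            utr5 = _utr5_with_uaug(rng, utr5_len, gc, config.utr5_gc_range)
        else:
            utr5 = _strip_aug(_random_sequence(rng, utr5_len, gc, config.utr5_gc_range))
        cds = "ATG" + _random_sequence(rng, cds_len - 3, 0.5, (0.0, 1.0))
        utr3 = _random_sequence(rng, utr3_len, 0.5, (0.0, 1.0))
        seq = utr5 + cds + utr3
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=tid,
                sequence=seq,
                cds_start=utr5_len,
                cds_end=utr5_len + cds_len,
                isoform_abundance=1.0,
            )
        )

        ct = labels[cell_type_idx[i]]
        comps = mixture[ct]
        weights = np.array([c[0] for c in comps])
        k = rng.choice(len(comps), p=weights / weights.sum())
        te = float(rng.normal(comps[k][1], comps[k][2]))
        te_treated = te + (config.top_repression_log2 if top_flags[i] else 0.0)
        base = float(rng.lognormal(mean=1.0, sigma=0.7))
        row = base * rng.uniform(0.1, 0.6, size=config.n_cell_types)
        row[cell_type_idx[i]] = base * 8.0
        fpkm_rows.append(row)
        gene_rows.append(
            {
                "cell_type": ct,
                "is_top": bool(top_flags[i]),
                "has_uaug": bool(uaug_flags[i]),
                "log2_te_untreated": te,
                "log2_te_treated": te_treated,
            }
        )

    gene_ids = [m.gene_id for m in models]
    genes = pd.DataFrame(gene_rows, index=pd.Index(gene_ids, name="gene_id"))
    fpkm = pd.DataFrame(fpkm_rows, index=genes.index, columns=labels)
    return models, SyntheticTruth(genes=genes, fpkm=fpkm)


def _gene_read_counts(
    rng: np.random.Generator, mean_weights: np.ndarray, depth: int, noise: str, dispersion: float
) -> np.ndarray:
    lam = depth * mean_weights / mean_weights.sum()
    if noise == "poisson":
        return rng.poisson(lam)
    shape = 1.0 / dispersion
    lam_nb = rng.gamma(shape, lam * dispersion)
    return rng.poisson(lam_nb)


def _sample_footprint_lengths(rng, dist: Mapping[int, float], n: int) -> np.ndarray:
    lengths = np.array(sorted(dist))
    probs = np.array([dist[int(l)] for l in lengths], dtype=float)
    return rng.choice(lengths, size=n, p=probs / probs.sum())


def simulate_footprints(
    models: list[TranscriptModel],
    truth: SyntheticTruth,
    config: SimulationConfig,
    condition: str = "untreated",
    depth: int = 100_000,
    with_reads: bool = True,
    rng: np.random.Generator | None = None,
):
    """Simulate ribosome footprints and their ligation-free raw reads.

    Per-gene read counts follow Poisson (or NB) noise around means
    proportional to bulk FPKM x 2**log2_te(condition); within the CDS, 5'
    ends prefer frame 0 with probability ``periodicity_strength``.  Raw
    reads carry the G-rich prefix + footprint + poly(A) fill to
    ``read_length``.

    Returns ``(reads, alignments)``: a list of :class:`FastqRead` (or ``None``
    when ``with_reads`` is false) and a truth DataFrame with columns
    gene_id, transcript_id, five_prime_pos, length.
    """
    if not models:
        raise ValueError("empty model collection")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    te = truth.log2_te(condition)
    bulk = truth.bulk_fpkm()
    gene_ids = [m.gene_id for m in models]
    weights = (bulk.loc[gene_ids] * np.exp2(te.loc[gene_ids])).to_numpy()
    counts = _gene_read_counts(rng, weights, depth, config.noise, config.nb_dispersion)

    p_strength = config.periodicity_strength
    split = np.array(config.cds_read_fraction, dtype=float)

    all_gene, all_tid, all_pos, all_len = [], [], [], []
    for m, n_reads in zip(models, counts):
        if n_reads == 0:
            continue
        lengths = _sample_footprint_lengths(rng, config.footprint_length_dist, n_reads)
        region_p = split.copy()
        if m.cds_start == 0:
            region_p[0] = 0
        if m.cds_end == m.length:
            region_p[2] = 0
        region_p = region_p / region_p.sum()
        regions = rng.choice(3, size=n_reads, p=region_p)
        pos = np.empty(n_reads, dtype=np.int64)

        cds_mask = regions == 1
        n_cds = int(cds_mask.sum())
        if n_cds:
            n_codons = (m.cds_end - m.cds_start) // 3
            codons = rng.integers(0, n_codons, size=n_cds)
            frames = np.where(
                rng.random(n_cds) < p_strength, 0, rng.integers(0, 3, size=n_cds)
            )
            pos[cds_mask] = m.cds_start + 3 * codons + frames
        u5_mask = regions == 0
        if u5_mask.any():
            pos[u5_mask] = rng.integers(0, m.cds_start, size=int(u5_mask.sum()))
        u3_mask = regions == 2
        if u3_mask.any():
            pos[u3_mask] = rng.integers(m.cds_end, m.length, size=int(u3_mask.sum()))
        lengths = np.minimum(lengths, m.length - pos)

        all_gene.append(np.full(n_reads, m.gene_id, dtype=object))
        all_tid.append(np.full(n_reads, m.transcript_id, dtype=object))
        all_pos.append(pos)
        all_len.append(lengths)

    if all_pos:
        alignments = pd.DataFrame(
            {
                "gene_id": np.concatenate(all_gene),
                "transcript_id": np.concatenate(all_tid),
                "five_prime_pos": np.concatenate(all_pos),
                "length": np.concatenate(all_len),
            }
        )
    else:
        alignments = pd.DataFrame(
            columns=["gene_id", "transcript_id", "five_prime_pos", "length"]
        )

    reads = None
    if with_reads:
        by_tid = {m.transcript_id: m for m in models}
        prefix_bases = list(PREFIX_COMPOSITION)
        prefix_probs = np.array([PREFIX_COMPOSITION[b] for b in prefix_bases])
        n_total = len(alignments)
        prefix_chars = rng.choice(prefix_bases, size=(n_total, PREFIX_LENGTH), p=prefix_probs)
        reads = []
        for i, row in enumerate(alignments.itertuples(index=False)):
            m = by_tid[row.transcript_id]
            footprint = m.sequence[row.five_prime_pos : row.five_prime_pos + row.length]
            prefix = "".join(prefix_chars[i])
            tail = "A" * (config.read_length - PREFIX_LENGTH - len(footprint))
            seq = prefix + footprint + tail
            reads.append(FastqRead(f"r{i:07d}", seq, "I" * len(seq)))
    return reads, alignments


def _region_length_split(m: TranscriptModel) -> np.ndarray:
    lens = np.array([m.cds_start, m.cds_end - m.cds_start, m.length - m.cds_end], dtype=float)
    return lens / lens.sum()


def _split_by_region(
    rng: np.random.Generator, totals: np.ndarray, splits: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorized per-gene multinomial split of totals into the 3 regions.

    ``splits`` is (n_genes, 3) of region probabilities per gene.
    """
    totals = np.asarray(totals, dtype=np.int64)
    p_u5 = splits[:, 0]
    u5 = rng.binomial(totals, p_u5)
    rest = totals - u5
    with np.errstate(divide="ignore", invalid="ignore"):
        p_cds = np.where(p_u5 < 1.0, splits[:, 1] / (1.0 - p_u5), 0.0)
    cds = rng.binomial(rest, np.clip(p_cds, 0.0, 1.0))
    u3 = rest - cds
    return {"utr5": u5, "cds": cds, "utr3": u3}


def simulate_rnaseq_counts(
    models: list[TranscriptModel],
    truth: SyntheticTruth,
    config: SimulationConfig,
    condition: str = "untreated",
    depth: int = 1_000_000,
    n_samples: int = 2,
    lib_scales: Sequence[float] | None = None,
    sample_prefix: str = "rna",
    assay: str = "rna",
    rng: np.random.Generator | None = None,
) -> RegionCountTable:
    """RNA-seq counts with FPKM-proportional means split across regions
    by region length; per-sample library scaling factors are configurable."""
    if not models:
        raise ValueError("empty model collection")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if lib_scales is None:
        lib_scales = [1.0] * n_samples
    if len(lib_scales) != n_samples:
        raise ValueError("lib_scales length must equal n_samples")
    bulk = truth.bulk_fpkm()
    gene_ids = [m.gene_id for m in models]
    w = bulk.loc[gene_ids].to_numpy()
    p = w / w.sum()
    sample_names = [f"{sample_prefix}_{condition}_{i+1}" for i in range(n_samples)]
    splits = np.array([_region_length_split(m) for m in models])
    frames = {r: pd.DataFrame(0, index=gene_ids, columns=sample_names, dtype=np.int64) for r in REGIONS}
    for s, scale in zip(sample_names, lib_scales):
        lam = depth * scale * p
        if config.noise == "poisson":
            totals = rng.poisson(lam)
        else:
            shape = 1.0 / config.nb_dispersion
            totals = rng.poisson(rng.gamma(shape, lam * config.nb_dispersion))
        parts = _split_by_region(rng, totals, splits)
        for r in REGIONS:
            frames[r][s] = parts[r]
    meta = pd.DataFrame(
        {"assay": assay, "condition": condition}, index=pd.Index(sample_names, name="sample")
    )
    return RegionCountTable.from_region_frames(frames, meta)


def simulate_ribotag(
    models: list[TranscriptModel],
    truth: SyntheticTruth,
    config: SimulationConfig,
    enrichment: float = 4.0,
    depletion: float = 1.0,
    depth: int = 1_000_000,
    n_reps: int = 2,
    rng: np.random.Generator | None = None,
) -> tuple[RegionCountTable, RegionCountTable]:
    """Paired IP / homogenate tables: IP means equal homogenate means times
    ``enrichment`` for genes of the target cell type and ``depletion``
    otherwise."""
    if not models:
        raise ValueError("empty model collection")
    target = config.cell_types[config.ribotag_target_cell_type]
    is_target = truth.genes["cell_type"] == target
    if not is_target.any():
        raise ValueError(f"target cell type {target!r} absent from truth")
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    bulk = truth.bulk_fpkm()
    gene_ids = [m.gene_id for m in models]
    w = bulk.loc[gene_ids].to_numpy()
    p = w / w.sum()
    factor = np.where(is_target.loc[gene_ids].to_numpy(), enrichment, depletion)

    splits = np.array([_region_length_split(m) for m in models])

    def _make(lam_per_gene, prefix, assay):
        names = [f"{prefix}_{i+1}" for i in range(n_reps)]
        frames = {r: pd.DataFrame(0, index=gene_ids, columns=names, dtype=np.int64) for r in REGIONS}
        for s in names:
            totals = rng.poisson(lam_per_gene)
            parts = _split_by_region(rng, totals, splits)
            for r in REGIONS:
                frames[r][s] = parts[r]
        meta = pd.DataFrame(
            {"assay": assay, "condition": "untreated"},
            index=pd.Index(names, name="sample"),
        )
        return RegionCountTable.from_region_frames(frames, meta)

    hom_lam = depth * p
    ip_lam = hom_lam * factor
    return _make(ip_lam, "ip", "ip"), _make(hom_lam, "homogenate", "homogenate")
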