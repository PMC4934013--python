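"""Readers and writers for the plain-text formats used across the toolkit.

FASTA/FASTQ go through Biopython; annotations, count tables, rank lists
(RNK) and gene sets (GMT) are tab-separated text in the usual dialects.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import REGIONS, TranscriptModel
from .quantify import RegionCountTable
from .synthetic import FastqRead


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fastq(path) -> list[FastqRead]:
    with _open_text(path) as fh:
        return [
            FastqRead(
                rec.id,
                str(rec.seq),
                "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
            )
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(reads, path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


# ---------------------------------------------------------------- annotation

ANNOTATION_COLUMNS = ["transcript_id", "gene_id", "cds_start", "cds_end", "isoform_abundance"]


def write_annotation(models: list[TranscriptModel], tsv_path, fasta_path=None) -> None:
    rows = [
        {
            "transcript_id": m.transcript_id,
            "gene_id": m.gene_id,
            "cds_start": m.cds_start,
            "cds_end": m.cds_end,
            "isoform_abundance": m.isoform_abundance,
        }
        for m in models
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(tsv_path, sep="\t", index=False)
    if fasta_path is not None:
        write_fasta({m.transcript_id: m.sequence for m in models}, fasta_path)


def read_annotation(tsv_path, fasta_path) -> list[TranscriptModel]:
    table = pd.read_csv(tsv_path, sep="\t")
    seqs = read_fasta(fasta_path)
    models = []
    for row in table.itertuples(index=False):
        seq = seqs.get(row.transcript_id)
        if seq is None:
            raise ValueError(f"transcript {row.transcript_id} missing from FASTA")
        models.append(
            TranscriptModel(
                gene_id=row.gene_id,
                transcript_id=row.transcript_id,
                sequence=seq,
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
                isoform_abundance=float(getattr(row, "isoform_abundance", 1.0)),
            )
        )
    return models


# ------------------------------------------------------------- count tables

def write_counts(table: RegionCountTable, path) -> None:
    """Self-contained long TSV: gene_id, sample, assay, condition, region, count."""
    rows = []
    for (sample, region), col in table.counts.items():
        meta = table.samples.loc[sample]
        for gene, count in col.items():
            rows.append((gene, sample, meta["assay"], meta["condition"], region, int(count)))
    pd.DataFrame(
        rows, columns=["gene_id", "sample", "assay", "condition", "region", "count"]
    ).to_csv(path, sep="\t", index=False)


def read_counts(path) -> RegionCountTable:
    long = pd.read_csv(path, sep="\t")
    samples = (
        long[["sample", "assay", "condition"]].drop_duplicates().set_index("sample")
    )
    counts = long.pivot_table(
        index="gene_id", columns=["sample", "region"], values="count", fill_value=0
    ).astype(int)
    counts = counts.reindex(
        columns=pd.MultiIndex.from_product([samples.index, REGIONS]), fill_value=0
    )
    return RegionCountTable(counts, samples)


# ---------------------------------------------------------------- alignments

ALIGNMENT_COLUMNS = ["read_id", "gene_id", "transcript_id", "five_prime_pos", "length", "duplicate"]


def write_alignments(alignments: pd.DataFrame, path) -> None:
    cols = [c for c in ALIGNMENT_COLUMNS if c in alignments.columns]
    alignments[cols].to_csv(path, sep="\t", index=False)


def read_alignments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ------------------------------------------------------------------ GMT/RNK

def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with _open_text(path, "wt") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_rnk(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"], comment="#")
    return df.set_index("gene")["score"]


def write_rnk(scores: pd.Series, path) -> None:
    scores.to_csv(path, sep="\t", header=False)
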