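"""Raw-read preprocessing for the ligation-free read structure.

Fixed trimming (first 5 / last 20 bases), 3' poly(A) clipping, a 15-nt
length filter, rRNA subtraction (substring match with at most one
mismatch), a toy exact/near-exact transcriptome mapper with
unique-gene-only semantics, and duplicate marking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import TranscriptModel

TRIM_HEAD = 5
TRIM_TAIL = 20
MIN_LENGTH = 15
POLYA_MIN_RUN = 8

STATUSES = ("kept", "too_short", "rrna", "unmapped", "multimapped")


@dataclass
class ProcessedRead:
    read_id: str
    sequence: str
    status: str


def trim_and_clip(
    sequence: str,
    read_id: str = "read",
    trim_head: int = TRIM_HEAD,
    trim_tail: int = TRIM_TAIL,
) -> ProcessedRead:
    """Trim fixed head/tail, clip a terminal poly(A) run, length-filter.

    Order: (1) drop the first 5 bases, (2) drop the last 20 bases, (3) if the
    sequence now ends in a run of >= 8 consecutive A's, remove the entire
    trailing run, (4) discard if fewer than 15 bases remain.  Reads of 25 or
    fewer raw bases are consumed by trimming and reported ``too_short`` with
    an empty sequence (not an exception).

    ``trim_head``/``trim_tail`` may be set to 0 so that an already-processed,
    A-run-free sequence passes through unchanged (guards against
    double-trimming in pipeline wiring).
    """
    seq = sequence.upper()
    if len(seq) <= trim_head + trim_tail:
        return ProcessedRead(read_id, "", "too_short")
    s = seq[trim_head : len(seq) - trim_tail]
    stripped = s.rstrip("A")
    if len(s) - len(stripped) >= POLYA_MIN_RUN:
        s = stripped
    status = "kept" if len(s) >= MIN_LENGTH else "too_short"
    return ProcessedRead(read_id, s, status)


def _matches_with_mismatches(read: str, ref: str, max_mismatches: int) -> bool:
    n, m = len(read), len(ref)
    if n > m:
        return False
    if max_mismatches <= 0:
        return read in ref
    if read in ref:
        return True
    for off in range(m - n + 1):
        mm = 0
        window = ref[off : off + n]
        for a, b in zip(read, window):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            return True
    return False


def filter_rrna(
    reads: list[ProcessedRead],
    rrna_refs: list[str],
    max_mismatches: int = 1,
) -> list[ProcessedRead]:
    """Label reads matching any rRNA reference substring (Hamming <= 1) as
    ``rrna``; all others pass through unchanged.  Reads are matched as-is
    (they are sense-stranded after the protocol)."""
    refs = [r.upper() for r in rrna_refs]
    if not refs:
        raise ValueError("rrna_refs must be non-empty")
    out = []
    for r in reads:
        if r.status != "kept":
            out.append(r)
            continue
        hit = any(_matches_with_mismatches(r.sequence, ref, max_mismatches) for ref in refs)
        out.append(ProcessedRead(r.read_id, r.sequence, "rrna" if hit else "kept"))
    return out


class TranscriptomeIndex:
    """Seeded substring index over transcript sequences.

    Exact matching verifies seed hits; with ``max_mismatches=1`` two seeds
    (read start and read midpoint) guarantee one mismatch-free seed by
    pigeonhole for reads of length >= 2*k.
    """

    def __init__(self, models: list[TranscriptModel], k: int = 15):
        self.models = list(models)
        self.by_tid = {m.transcript_id: m for m in self.models}
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for m in self.models:
            seq = m.sequence.upper()
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((m.transcript_id, i))

    def candidates(self, read: str) -> set[tuple[str, int]]:
        """Candidate (transcript_id, alignment_start) pairs from seed hits."""
        k = self.k
        out: set[tuple[str, int]] = set()
        offsets = [0]
        if len(read) >= 2 * k:
            offsets.append(len(read) // 2)
        for off in offsets:
            seed = read[off : off + k]
            if len(seed) < k:
                continue
            for tid, pos in self.index.get(seed, ()):
                start = pos - off
                if start >= 0:
                    out.add((tid, start))
        return out

    def align(self, read: str, max_mismatches: int = 0):
        """All (gene_id, transcript_id, pos) placements within the mismatch
        budget."""
        hits = []
        for tid, start in self.candidates(read):
            m = self.by_tid[tid]
            window = m.sequence[start : start + len(read)]
            if len(window) < len(read):
                continue
            mm = sum(a != b for a, b in zip(read, window))
            if mm <= max_mismatches:
                hits.append((m.gene_id, tid, start))
        return hits


def map_to_transcriptome(
    reads: list[ProcessedRead],
    models: list[TranscriptModel],
    max_mismatches: int = 0,
    index: TranscriptomeIndex | None = None,
) -> tuple[pd.DataFrame, list[ProcessedRead]]:
    """Map kept reads to transcripts; reads matching more than one gene are
    ``multimapped`` and discarded (uniquely-mapped semantics).

    Within a single gene, ties resolve to the lowest transcript_id and the
    leftmost position.  Returns ``(alignments, fates)`` where alignments has
    columns read_id, gene_id, transcript_id, five_prime_pos, length.
    """
    if index is None:
        index = TranscriptomeIndex(models)
    rows = []
    fates = []
    for r in reads:
        if r.status != "kept":
            fates.append(r)
            continue
        hits = index.align(r.sequence.upper(), max_mismatches)
        genes = {g for g, _, _ in hits}
        if not hits:
            fates.append(ProcessedRead(r.read_id, r.sequence, "unmapped"))
            continue
        if len(genes) > 1:
            fates.append(ProcessedRead(r.read_id, r.sequence, "multimapped"))
            continue
        gene_id, tid, pos = min(hits, key=lambda h: (h[1], h[2]))
        rows.append((r.read_id, gene_id, tid, pos, len(r.sequence)))
        fates.append(r)
    alignments = pd.DataFrame(
        rows, columns=["read_id", "gene_id", "transcript_id", "five_prime_pos", "length"]
    )
    return alignments, fates


def mark_duplicates(alignments: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Flag fragments identical on (transcript_id, five_prime_pos, length)
    beyond the first; return the alignments plus the unique-fragment count."""
    out = alignments.copy()
    if len(out) == 0:
        out["duplicate"] = pd.Series(dtype=bool)
        return out, 0
    key_cols = ["transcript_id", "five_prime_pos", "length"]
    out["duplicate"] = out.duplicated(subset=key_cols, keep="first")
    n_unique = len(out.drop_duplicates(subset=key_cols))
    return out, n_unique


def read_fate_summary(fates: list[ProcessedRead]) -> pd.Series:
    """Count reads per terminal status (every read has exactly one)."""
    counts = pd.Series(0, index=list(STATUSES), dtype=np.int64)
    for r in fates:
        counts[r.status] += 1
    return counts


def run_preprocess(
    raw_reads,
    models: list[TranscriptModel],
    rrna_refs: list[str] | None = None,
    max_mismatches: int = 0,
):
    """Full pipeline: trim/clip -> rRNA subtraction -> mapping -> duplicates.

    ``raw_reads`` is an iterable of (read_id, sequence) pairs or objects with
    ``read_id``/``sequence`` attributes.  Returns (alignments, fates, summary).
    """
    processed = []
    for r in raw_reads:
        if isinstance(r, tuple):
            rid, seq = r[0], r[1]
        else:
            rid, seq = r.read_id, r.sequence
        processed.append(trim_and_clip(seq, rid))
    if rrna_refs:
        processed = filter_rrna(processed, rrna_refs)
    alignments, fates = map_to_transcriptome(processed, models, max_mismatches)
    alignments, _ = mark_duplicates(alignments)
    return alignments, fates, read_fate_summary(fates)
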