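"""Transcript models: the coordinate substrate shared by all modules.

Transcript coordinates are 0-based, half-open, single-strand (transcripts
are sense-oriented); the three regions tile ``[0, len)`` as
``utr5 = [0, cds_start)``, ``cds = [cds_start, cds_end)``,
``utr3 = [cds_end, len)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

REGIONS = ("utr5", "cds", "utr3")


@dataclass(frozen=True)
class TranscriptModel:
    """A single transcript isoform with UTR5/CDS/UTR3 segmentation."""

    gene_id: str
    transcript_id: str
    sequence: str
    cds_start: int
    cds_end: int
    isoform_abundance: float = 1.0

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (0 <= self.cds_start < self.cds_end <= n):
            raise ValueError(
                f"{self.transcript_id}: invalid CDS [{self.cds_start}, "
                f"{self.cds_end}) for length {n}"
            )
        if self.isoform_abundance < 0:
            raise ValueError(f"{self.transcript_id}: negative isoform abundance")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def utr5(self) -> tuple[int, int]:
        return (0, self.cds_start)

    @property
    def cds(self) -> tuple[int, int]:
        return (self.cds_start, self.cds_end)

    @property
    def utr3(self) -> tuple[int, int]:
        return (self.cds_end, self.length)

    @property
    def utr5_sequence(self) -> str:
        return self.sequence[: self.cds_start]

    @property
    def cds_sequence(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    def region_of(self, position: int) -> str:
        """Region containing a 0-based transcript position."""
        if not 0 <= position < self.length:
            raise ValueError(f"position {position} outside [0, {self.length})")
        if position < self.cds_start:
            return "utr5"
        if position < self.cds_end:
            return "cds"
        return "utr3"


@dataclass(frozen=True)
class AlignedFootprint:
    """A footprint mapped to transcript coordinates by its 5' end."""

    gene_id: str
    transcript_id: str
    five_prime_pos: int
    length: int
    duplicate: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.five_prime_pos < 0 or self.length <= 0:
            raise ValueError("five_prime_pos must be >= 0 and length > 0")


def index_by_transcript(models) -> dict[str, TranscriptModel]:
    out: dict[str, TranscriptModel] = {}
    for m in models:
        if m.transcript_id in out:
            raise ValueError(f"duplicate transcript_id {m.transcript_id}")
        out[m.transcript_id] = m
    return out


def genes_of(models) -> list[str]:
    """Unique gene ids in first-seen order."""
    seen: dict[str, None] = {}
    for m in models:
        seen.setdefault(m.gene_id, None)
    return list(seen)
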