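"""Stranded genomic intervals and the records built from them.

All internal coordinates are 0-based half-open (`[start, end)`), the BED
convention. Interaction summary tables are declared 1-based inclusive and
converted once at the IO boundary. Strand ``'.'`` marks strand-agnostic
spans (BED3 rows, crosslink tracks); such spans are treated as occupying
both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

STRANDS = ("+", "-", ".")

_DNA_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")
_RNA_COMPLEMENT = str.maketrans("ACGUNacgun", "UGCANugcan")


def reverse_complement_rna(seq: str) -> str:
    """Reverse complement of an RNA sequence (N stays N)."""
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def reverse_complement_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """One stranded genomic span, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def same_strand(self, other: "GenomicInterval") -> bool:
        """Strand compatibility; '.' matches either strand."""
        return (
            self.strand == other.strand
            or self.strand == "."
            or other.strand == "."
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom or not self.same_strand(other):
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.intersection_length(other) > 0

    def contains_position(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def as_tuple(self):
        return (self.chrom, self.start, self.end, self.strand)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"


@dataclass(frozen=True)
class RRIRecord:
    """One interactome row: two interacting arms, a reliability score and
    its replicate of origin."""

    arm1: GenomicInterval
    arm2: GenomicInterval
    score: float
    replicate_id: str
    record_id: str

    def __post_init__(self):
        if self.score < 0:
            raise ValueError(f"record {self.record_id}: negative score")

    def sort_key(self):
        return (self.arm1.as_tuple(), self.arm2.as_tuple())


def add_context(
    interval: GenomicInterval, context_len: int, chrom_len: int
) -> tuple[GenomicInterval, int]:
    """Extend an interval by ``context_len`` nt of genomic context on both
    sides, clipped to the chromosome.

    Returns the extended window together with the genomic-left offset of
    the original site inside it.
    """
    if context_len < 0:
        raise ValueError("context_len must be >= 0")
    if interval.end > chrom_len:
        raise ValueError(
            f"interval {interval} exceeds chromosome length {chrom_len}"
        )
    new_start = max(0, interval.start - context_len)
    new_end = min(chrom_len, interval.end + context_len)
    window = replace(interval, start=new_start, end=new_end)
    return window, interval.start - new_start


def positions_identifier(arm1: GenomicInterval, arm2: GenomicInterval) -> str:
    """Positions-based site identifier, 1-based inclusive on output."""
    return (
        f"{arm1.chrom}:{arm1.start + 1}-{arm1.end}:{arm1.strand};"
        f"{arm2.chrom}:{arm2.start + 1}-{arm2.end}:{arm2.strand}"
    )
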