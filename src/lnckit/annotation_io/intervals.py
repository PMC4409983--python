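"""Core coordinate types: genomic intervals and multi-exon transcript models.

All internal coordinates are 0-based half-open; conversions to the 1-based
inclusive GTF convention happen only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

PLUS = "+"
MINUS = "-"
UNKNOWN = "."

_VALID_STRANDS = {PLUS, MINUS, UNKNOWN}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = UNKNOWN

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def strands_compatible(a: str, b: str) -> bool:
    """Same strand, or either unknown."""
    return a == UNKNOWN or b == UNKNOWN or a == b


# Locus class codes relative to a reference annotation.
CLASS_I = "I"  # fully intronic
CLASS_U = "U"  # intergenic
CLASS_X = "X"  # exonic overlap, opposite strand
CLASS_OTHER = "OTHER"
CLASS_REFERENCE = "REFERENCE"


@dataclass
class Transcript:
    """A stranded, multi-exon gene model.

    Exons must be sorted, pairwise disjoint and share one chrom/strand.
    """

    id: str
    exons: Sequence[GenomicInterval]
    class_code: str = CLASS_OTHER
    source: str = ""
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id}: needs at least one exon")
        exons = sorted(self.exons, key=lambda e: e.start)
        chrom = exons[0].chrom
        strand = exons[0].strand
        for e in exons:
            if e.chrom != chrom or e.strand != strand:
                raise ValueError(
                    f"transcript {self.id}: exons on mixed chrom/strand"
                )
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(f"transcript {self.id}: overlapping exons")
        object.__setattr__(self, "exons", tuple(exons))

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def exonic_overlap(self, other: "Transcript") -> int:
        """Total exon-vs-exon overlap in nucleotides (any strand)."""
        total = 0
        for e in self.exons:
            for f in other.exons:
                total += e.overlap_length(f)
        return total


def total_exonic_length(exons: Iterable[GenomicInterval]) -> int:
    return sum(len(e) for e in exons)
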