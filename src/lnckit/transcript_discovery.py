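"""Transcript-filtering front end: dual-assembler support, locus class codes,
length filter, complementary-strand duplicate detection, gene-set overlap and
exon/expression summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .annotation_io.intervals import (
    CLASS_I,
    CLASS_OTHER,
    CLASS_U,
    CLASS_X,
    Transcript,
    strands_compatible,
)


@dataclass
class ExpressionRecord:
    """FPKM bookkeeping for one transcript."""

    transcript_id: str
    fragment_count: float
    exonic_length: int
    total_mapped_fragments: float

    @property
    def fpkm(self) -> float:
        return compute_fpkm(self.fragment_count, self.exonic_length, self.total_mapped_fragments)


@dataclass
class DiscoverySet:
    """Transcripts surviving a cascade stage, with per-stage counts."""

    transcripts: list[Transcript]
    stage_counts: dict[str, int] = field(default_factory=dict)
    flags: dict[str, dict] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.transcripts)

    def record_stage(self, name: str) -> None:
        self.stage_counts[name] = len(self.transcripts)


def _group_by_chrom(transcripts: Iterable[Transcript]) -> dict[str, list[Transcript]]:
    out: dict[str, list[Transcript]] = {}
    for t in transcripts:
        out.setdefault(t.chrom, []).append(t)
    for v in out.values():
        v.sort(key=lambda t: t.start)
    return out


def intersect_assemblies(
    set_a: list[Transcript],
    set_b: list[Transcript],
    min_overlap: int = 1,
    reciprocal_fraction: float | None = None,
) -> DiscoverySet:
    """Retain transcripts of ``set_a`` with exonic support in ``set_b``.

    Support means >= ``min_overlap`` nt of exon-vs-exon overlap on a
    compatible strand (same strand, or either unknown).  When
    ``reciprocal_fraction`` is given, both transcripts must additionally be
    covered over at least that fraction of their exonic length.
    """
    by_chrom = _group_by_chrom(set_b)
    kept: list[Transcript] = []
    flags: dict[str, dict] = {}
    for t in set_a:
        supported = False
        for other in by_chrom.get(t.chrom, []):
            if other.start >= t.end:
                break
            if other.end <= t.start:
                continue
            if not strands_compatible(t.strand, other.strand):
                continue
            ov = t.exonic_overlap(other)
            if ov >= min_overlap:
                if reciprocal_fraction is not None:
                    if (
                        ov / t.spliced_length < reciprocal_fraction
                        or ov / other.spliced_length < reciprocal_fraction
                    ):
                        continue
                supported = True
                break
        if supported:
            kept.append(t)
            flags[t.id] = {"supported_by_both": True}
    ds = DiscoverySet(kept, flags=flags)
    ds.record_stage("supported_by_both")
    return ds


def assign_class_code(transcript: Transcript, reference: list[Transcript]) -> str:
    """Locus class relative to a reference annotation.

    Precedence: same-strand exonic overlap -> OTHER; opposite-strand exonic
    overlap -> X; fully inside a single reference intron -> I; no span
    overlap with any reference transcript -> U; any remaining span overlap
    -> OTHER.
    """
    span = transcript.span
    span_overlaps = []
    for r in reference:
        if not span.overlaps(r.span):
            continue
        span_overlaps.append(r)
        if transcript.exonic_overlap(r) > 0:
            if (
                transcript.strand != "."
                and r.strand != "."
                and transcript.strand != r.strand
            ):
                continue  # keep scanning: same-strand overlap dominates
            return CLASS_OTHER
    for r in span_overlaps:
        if transcript.exonic_overlap(r) > 0:
            return CLASS_X
    for r in span_overlaps:
        for intron in r.introns():
            if intron.contains(span):
                return CLASS_I
    if not span_overlaps:
        return CLASS_U
    return CLASS_OTHER


def classify_all(
    transcripts: list[Transcript],
    reference: list[Transcript],
    keep_codes: tuple[str, ...] = (CLASS_I, CLASS_U, CLASS_X),
) -> DiscoverySet:
    kept = []
    for t in transcripts:
        code = assign_class_code(t, reference)
        t.class_code = code
        if code in keep_codes:
            kept.append(t)
    ds = DiscoverySet(kept)
    ds.record_stage("class_IUX")
    return ds


def length_filter(transcripts: list[Transcript], min_len: int = 200) -> DiscoverySet:
    """Retain transcripts with spliced length >= ``min_len`` (inclusive)."""
    kept = [t for t in transcripts if t.spliced_length >= min_len]
    ds = DiscoverySet(kept)
    ds.record_stage(f"length_ge_{min_len}")
    return ds


def find_duplicate_complements(
    transcripts: list[Transcript],
    min_fraction: float = 0.5,
) -> set[tuple[str, str]]:
    """Single-exon pairs on opposite strands with overlap/union-span >= 0.5.

    Returns unordered id pairs (sorted tuples).
    """
    singles = [t for t in transcripts if t.n_exons == 1 and t.strand in "+-"]
    by_chrom = _group_by_chrom(singles)
    pairs: set[tuple[str, str]] = set()
    for chrom, items in by_chrom.items():
        for i, a in enumerate(items):
            for b in items[i + 1 :]:
                if b.start >= a.end:
                    break
                if a.strand == b.strand:
                    continue
                overlap = min(a.end, b.end) - max(a.start, b.start)
                union = max(a.end, b.end) - min(a.start, b.start)
                if union > 0 and overlap / union >= min_fraction:
                    pairs.add(tuple(sorted((a.id, b.id))))
    return pairs


def compare_gene_sets(
    set_a: list[Transcript],
    set_b: list[Transcript],
    min_frac: float = 0.5,
) -> set[str]:
    """Ids of ``set_a`` genes whose exonic length is covered >= ``min_frac``
    by some single gene of ``set_b`` (one-directional)."""
    by_chrom = _group_by_chrom(set_b)
    matched: set[str] = set()
    for t in set_a:
        need = min_frac * t.spliced_length
        for other in by_chrom.get(t.chrom, []):
            if other.start >= t.end:
                break
            if other.end <= t.start:
                continue
            if t.exonic_overlap(other) >= need:
                matched.add(t.id)
                break
    return matched


def compute_fpkm(fragment_count: float, exonic_length: int, total_mapped: float) -> float:
    """fragments x 10^9 / (exonic length x library size)."""
    if exonic_length <= 0:
        raise ValueError("exonic_length must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if fragment_count < 0:
        raise ValueError("fragment_count must be non-negative")
    return fragment_count * 1e9 / (exonic_length * total_mapped)


def exon_count_summary(transcripts: list[Transcript]) -> pd.DataFrame:
    """Per-class mean exons/gene and exon-count histogram.

    Classes with no members are simply absent (missing, not zero).
    """
    rows = []
    by_class: dict[str, list[int]] = {}
    for t in transcripts:
        by_class.setdefault(t.class_code, []).append(t.n_exons)
    for cls, counts in sorted(by_class.items()):
        hist: dict[int, int] = {}
        for c in counts:
            hist[c] = hist.get(c, 0) + 1
        rows.append(
            {
                "class": cls,
                "n": len(counts),
                "mean_exons": sum(counts) / len(counts),
                "histogram": ";".join(f"{k}:{v}" for k, v in sorted(hist.items())),
            }
        )
    return pd.DataFrame(rows, columns=["class", "n", "mean_exons", "histogram"])
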