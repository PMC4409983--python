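"""GTF reading and writing.

GTF is 1-based inclusive on disk; in memory everything is 0-based half-open.
Only ``exon`` and ``CDS`` features are interpreted; exons are grouped by
``transcript_id``.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

from .intervals import GenomicInterval, Transcript, UNKNOWN

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    pass


def _parse_attributes(field: str) -> dict:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: str | Path, feature_types: tuple[str, ...] = ("exon",)) -> list[Transcript]:
    """Parse a GTF file into a list of :class:`Transcript`.

    ``CDS`` features, when present, are attached to the owning transcript as
    ``attributes["cds"]`` (a list of 0-based half-open ``(start, end, frame)``
    tuples in genomic order) so that codon positions can be recovered.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[tuple[int, int, int]]] = {}
    meta: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, source, ftype, start_s, end_s, _score, strand, frame_s, attr_s = fields
            if ftype not in feature_types and ftype != "CDS":
                continue
            try:
                start = int(start_s) - 1  # to 0-based half-open
                end = int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: bad coordinates") from exc
            if start < 0 or end <= start:
                raise GtfParseError(f"{path}:{lineno}: invalid interval {start_s}..{end_s}")
            attrs = _parse_attributes(attr_s)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise GtfParseError(f"{path}:{lineno}: missing transcript_id attribute")
            if strand not in "+-":
                strand = UNKNOWN
            if ftype == "CDS":
                frame = int(frame_s) if frame_s in "012" else 0
                cds.setdefault(tid, []).append((start, end, frame))
                meta.setdefault(tid, {}).setdefault("_chrom_strand", (chrom, strand))
                continue
            exons.setdefault(tid, []).append(GenomicInterval(chrom, start, end, strand))
            m = meta.setdefault(tid, {})
            m["gene_id"] = attrs.get("gene_id", tid)
            m["source"] = source
    transcripts = []
    for tid, ex in exons.items():
        attrs = {"gene_id": meta[tid].get("gene_id", tid)}
        if tid in cds:
            attrs["cds"] = sorted(cds[tid])
        try:
            transcripts.append(
                Transcript(id=tid, exons=ex, source=meta[tid].get("source", ""), attributes=attrs)
            )
        except ValueError as exc:
            raise GtfParseError(f"{path}: transcript {tid}: {exc}") from exc
    transcripts.sort(key=lambda t: (t.chrom, t.start, t.id))
    return transcripts


def write_gtf(transcripts: Iterable[Transcript], path: str | Path, source: str = "lnckit") -> None:
    """Write transcripts as GTF (1-based inclusive), deterministically ordered."""
    records = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.id))
    with open(path, "w") as fh:
        fh.write("##gtf produced by lnckit\n")
        for t in records:
            gene_id = t.attributes.get("gene_id", t.id)
            for e in t.exons:
                strand = e.strand if e.strand in "+-" else "."
                attrs = f'gene_id "{gene_id}"; transcript_id "{t.id}";'
                fh.write(
                    f"{e.chrom}\t{t.source or source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{strand}\t.\t{attrs}\n"
                )
            for cds_rec in t.attributes.get("cds", []):
                start, end, frame = cds_rec
                strand = t.strand if t.strand in "+-" else "."
                attrs = f'gene_id "{gene_id}"; transcript_id "{t.id}";'
                fh.write(
                    f"{t.chrom}\t{t.source or source}\tCDS\t{start + 1}\t{end}\t.\t"
                    f"{strand}\t{frame}\t{attrs}\n"
                )
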