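"""Indexed access to multiple whole-genome alignments in MAF format.

Blocks are indexed by reference-species coordinates.  Extraction projects a
genomic interval of the reference into a rectangular, reference-anchored
:class:`RegionAlignment`: columns that are insertions relative to the
reference (gap in the reference row) are dropped and counted, and species
absent from all overlapping blocks appear as all-gap rows.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO

from .genome import reverse_complement
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

GAP = "-"


class MafParseError(ValueError):
    pass


@dataclass
class MafBlock:
    """One alignment block, keyed by reference coordinates."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    # species -> (gapped text, own-genome start, ungapped size, strand, srcSize)
    rows: dict[str, tuple[str, int, int, str, int]]

    def species(self) -> list[str]:
        return list(self.rows)


def _split_src(src: str) -> tuple[str, str]:
    """MAF source names are ``species.chrom``; chrom may contain dots."""
    if "." in src:
        sp, chrom = src.split(".", 1)
        return sp, chrom
    return src, src


@dataclass
class RegionAlignment:
    """Rectangular alignment over a reference interval, one row per species.

    The reference row is ungapped and exactly ``len(interval)`` columns wide.
    """

    reference_species: str
    interval: GenomicInterval
    species: list[str]
    rows: dict[str, str]
    dropped_insertion_columns: int = 0

    def __post_init__(self) -> None:
        n = len(self.interval)
        for sp, row in self.rows.items():
            if len(row) != n:
                raise ValueError(f"row {sp} has {len(row)} columns, expected {n}")
        ref = self.rows[self.reference_species]
        if GAP in ref:
            raise ValueError("reference row must be ungapped")

    @property
    def n_columns(self) -> int:
        return len(self.interval)

    def row(self, species: str) -> str:
        return self.rows[species]

    def subset_columns(self, start: int, end: int) -> "RegionAlignment":
        """Columns [start, end) relative to the region (reference positions)."""
        iv = GenomicInterval(
            self.interval.chrom,
            self.interval.start + start,
            self.interval.start + end,
            self.interval.strand,
        )
        return RegionAlignment(
            reference_species=self.reference_species,
            interval=iv,
            species=list(self.species),
            rows={sp: row[start:end] for sp, row in self.rows.items()},
            dropped_insertion_columns=self.dropped_insertion_columns,
        )

    def reverse_complemented(self) -> "RegionAlignment":
        return RegionAlignment(
            reference_species=self.reference_species,
            interval=self.interval,
            species=list(self.species),
            rows={sp: reverse_complement(row) for sp, row in self.rows.items()},
            dropped_insertion_columns=self.dropped_insertion_columns,
        )

    def coverage(self, species: str) -> float:
        """Fraction of reference positions where ``species`` has a nucleotide."""
        row = self.rows.get(species)
        if row is None:
            return 0.0
        n = len(row)
        if n == 0:
            return 0.0
        return sum(1 for c in row if c not in (GAP, ".")) / n


def concatenate_regions(regions: list[RegionAlignment]) -> RegionAlignment:
    """Column-wise concatenation (e.g. exon sub-alignments of one transcript).

    The resulting interval spans from the first region's start to the last
    region's end; only its column content is meaningful.
    """
    if not regions:
        raise ValueError("nothing to concatenate")
    first = regions[0]
    species = list(first.species)
    rows = {
        sp: "".join(r.rows.get(sp, GAP * r.n_columns) for r in regions)
        for sp in species
    }
    iv = GenomicInterval(
        first.interval.chrom,
        min(r.interval.start for r in regions),
        max(r.interval.end for r in regions),
        first.interval.strand,
    )
    total = sum(r.n_columns for r in regions)
    # Fabricate a covering interval of the right width for validation.
    iv = GenomicInterval(iv.chrom, iv.start, iv.start + total, iv.strand)
    return RegionAlignment(
        reference_species=first.reference_species,
        interval=iv,
        species=species,
        rows=rows,
        dropped_insertion_columns=sum(r.dropped_insertion_columns for r in regions),
    )


class MafStore:
    """All blocks of a MAF file, indexed by reference chromosome/coordinates."""

    def __init__(self, reference_species: str):
        self.reference_species = reference_species
        self._blocks: dict[str, list[MafBlock]] = {}
        self._starts: dict[str, list[int]] = {}
        self.species: list[str] = []
        self.skipped_blocks = 0

    def add_block(self, block: MafBlock) -> None:
        self._blocks.setdefault(block.ref_chrom, []).append(block)
        for sp in block.rows:
            if sp not in self.species:
                self.species.append(sp)

    def finalize(self) -> None:
        for chrom, blocks in self._blocks.items():
            blocks.sort(key=lambda b: b.ref_start)
            prev_end = -1
            for b in blocks:
                if b.ref_start < prev_end:
                    raise MafParseError(
                        f"overlapping/unsorted reference blocks on {chrom} at {b.ref_start}"
                    )
                prev_end = b.ref_end
            self._starts[chrom] = [b.ref_start for b in blocks]

    def query(self, chrom: str, start: int, end: int) -> list[MafBlock]:
        """All blocks whose reference interval overlaps [start, end)."""
        blocks = self._blocks.get(chrom, [])
        if not blocks:
            return []
        starts = self._starts[chrom]
        i = bisect_left(starts, start)
        # step back one: the previous block may extend into the interval
        if i > 0 and blocks[i - 1].ref_end > start:
            i -= 1
        out = []
        while i < len(blocks) and blocks[i].ref_start < end:
            if blocks[i].ref_end > start:
                out.append(blocks[i])
            i += 1
        return out


def read_maf(path: str | Path, reference_species: str) -> MafStore:
    """Parse a MAF file into a :class:`MafStore`.

    Blocks lacking the reference species are skipped with a logged warning
    and counted in ``store.skipped_blocks``.
    """
    store = MafStore(reference_species)
    with open(path) as fh:
        for aln in AlignIO.parse(fh, "maf"):
            rows: dict[str, tuple[str, int, int, str, int]] = {}
            ref_key = None
            lengths = {len(rec.seq) for rec in aln}
            if len(lengths) > 1:
                raise MafParseError(f"{path}: inconsistent row lengths in a block")
            for rec in aln:
                sp, _chrom = _split_src(rec.id)
                strand = "+" if rec.annotations.get("strand", 1) == 1 else "-"
                rows[sp] = (
                    str(rec.seq).upper(),
                    int(rec.annotations["start"]),
                    int(rec.annotations["size"]),
                    strand,
                    int(rec.annotations.get("srcSize", 0)),
                )
                if sp == reference_species:
                    ref_key = rec.id
            if ref_key is None:
                store.skipped_blocks += 1
                logger.warning("MAF block without reference species %s skipped", reference_species)
                continue
            _sp, ref_chrom = _split_src(ref_key)
            text, start, size, strand, _src_size = rows[reference_species]
            if strand != "+":
                raise MafParseError("reference rows must be on the + strand")
            store.add_block(
                MafBlock(ref_chrom=ref_chrom, ref_start=start, ref_end=start + size, rows=rows)
            )
    store.finalize()
    return store


def extract_region_alignment(
    store: MafStore,
    interval: GenomicInterval,
    species_list: list[str] | None = None,
    chrom_length: int | None = None,
) -> RegionAlignment:
    """Project MAF blocks onto a reference interval.

    Insertion columns (gap in the reference row) are dropped and counted.
    Reference positions covered by no block are filled with ``N`` in the
    reference row and gaps elsewhere.
    """
    if chrom_length is not None and interval.end > chrom_length:
        raise IndexError(
            f"interval end {interval.end} beyond chromosome length {chrom_length}"
        )
    ref = store.reference_species
    if species_list is None:
        species_list = list(store.species)
    if ref not in species_list:
        species_list = [ref] + list(species_list)
    n = len(interval)
    cols = {sp: [GAP] * n for sp in species_list}
    cols[ref] = ["N"] * n
    dropped = 0
    for block in store.query(interval.chrom, interval.start, interval.end):
        ref_text = block.rows[ref][0]
        pos = block.ref_start
        for c, ref_char in enumerate(ref_text):
            if ref_char == GAP:
                if interval.start <= pos < interval.end:
                    dropped += 1
                continue
            if interval.start <= pos < interval.end:
                j = pos - interval.start
                cols[ref][j] = ref_char
                for sp in species_list:
                    if sp == ref or sp not in block.rows:
                        continue
                    cols[sp][j] = block.rows[sp][0][c]
            pos += 1
    return RegionAlignment(
        reference_species=ref,
        interval=interval,
        species=list(species_list),
        rows={sp: "".join(v) for sp, v in cols.items()},
        dropped_insertion_columns=dropped,
    )


def write_maf(store_blocks: list[MafBlock], species_order: list[str], path: str | Path,
              ref_species: str) -> None:
    """Serialize blocks to MAF (UCSC dialect)."""
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        for block in store_blocks:
            fh.write("\na score=0.0\n")
            ordered = [sp for sp in species_order if sp in block.rows]
            width = max(len(f"{sp}.{block.ref_chrom}") for sp in ordered)
            for sp in ordered:
                text, start, size, strand, src_size = block.rows[sp]
                src = f"{sp}.{block.ref_chrom}"
                fh.write(
                    f"s {src:<{width}} {start:>10d} {size:>8d} {strand} {src_size:>10d} {text}\n"
                )
        fh.write("\n")
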