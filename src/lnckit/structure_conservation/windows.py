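"""Sliding-window structure screening of genes and per-species retention."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ..annotation_io.intervals import GenomicInterval, Transcript
from ..annotation_io.maf import MafStore, RegionAlignment, extract_region_alignment
from .scores import StructureScore, StructureScoreParams, structure_score

logger = logging.getLogger(__name__)


@dataclass
class StructureLocus:
    """A merged run of high-confidence windows within one gene.

    ``best_window`` is the interval of the highest-scoring window inside the
    locus; per-species retention is evaluated on it (bounded width keeps the
    dynamic program cheap).
    """

    gene_id: str
    interval: GenomicInterval
    best_score: StructureScore
    best_window: GenomicInterval | None = None
    flagged: list[str] = field(default_factory=list)

    @property
    def high_confidence(self) -> bool:
        return self.best_score.combined > 0.5


def scan_windows(
    gene: Transcript,
    store: MafStore,
    window: int = 120,
    step: int = 40,
    params: StructureScoreParams = StructureScoreParams(),
    seed: int | None = None,
    species: list[str] | None = None,
) -> list[StructureLocus]:
    """Slide windows over the gene span, score each, and merge overlapping
    high-confidence windows into maximal non-overlapping loci."""
    span = gene.span
    aln = extract_region_alignment(
        store, GenomicInterval(span.chrom, span.start, span.end), species
    )
    n = aln.n_columns
    flagged: list[str] = []
    if n < window:
        starts = [0]
        width = n
        flagged.append("gene_shorter_than_window")
    else:
        starts = list(range(0, n - window + 1, step))
        if starts[-1] + window < n:
            starts.append(n - window)
        width = window
    confident: list[tuple[int, int, StructureScore]] = []
    for idx, s in enumerate(starts):
        sub = aln.subset_columns(s, s + width)
        wid = f"{gene.id}:w{idx}"
        w_seed = None if seed is None else seed + 977 * idx
        score = structure_score(sub, params, seed=w_seed, window_id=wid)
        if score.combined > params.threshold:
            confident.append((s, s + width, score))
    loci: list[StructureLocus] = []
    for s, e, score in sorted(confident, key=lambda x: x[0]):
        win_iv = GenomicInterval(span.chrom, span.start + s, span.start + e)
        if loci and s < loci[-1].interval.end - span.start:
            prev = loci[-1]
            new_end = max(prev.interval.end, span.start + e)
            if score.combined > prev.best_score.combined:
                best, best_win = score, win_iv
            else:
                best, best_win = prev.best_score, prev.best_window
            loci[-1] = StructureLocus(
                gene.id,
                GenomicInterval(span.chrom, prev.interval.start, new_end),
                best,
                best_win,
                prev.flagged,
            )
        else:
            loci.append(StructureLocus(gene.id, win_iv, score, win_iv, list(flagged)))
    return loci


def species_structure_presence(
    locus: StructureLocus,
    store: MafStore,
    species: str,
    threshold: float = 0.5,
    seed: int | None = None,
    params: StructureScoreParams = StructureScoreParams(),
    min_cov: float = 0.10,
) -> bool:
    """Present iff the species aligns over the locus and the two-row
    (reference + species) sub-alignment of the locus's best window still
    scores above threshold."""
    iv = locus.best_window or locus.interval
    aln = extract_region_alignment(store, GenomicInterval(iv.chrom, iv.start, iv.end))
    cov = aln.coverage(species)
    if cov < min_cov:
        return False
    ref = aln.reference_species
    if species == ref:
        return True
    pair = RegionAlignment(
        reference_species=ref,
        interval=aln.interval,
        species=[ref, species],
        rows={ref: aln.rows[ref], species: aln.rows.get(species, "-" * aln.n_columns)},
        dropped_insertion_columns=aln.dropped_insertion_columns,
    )
    score = structure_score(pair, params, seed=seed, window_id=f"{locus.gene_id}:{species}")
    return score.combined > threshold
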