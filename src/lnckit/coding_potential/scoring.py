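"""Phylogenetic coding-potential scoring.

The score is a likelihood ratio, in decibans, of a codon model (MG94xHKY)
against a nucleotide neutral model (HKY85) fitted on four-fold degenerate
sites, evaluated on a reference-anchored alignment.  Positive scores favour
protein-coding evolution; +/-10 decibans are the classification thresholds.

Three scanning modes mirror per-codon, per-exon and per-gene use: a 6-frame
profile over a transcript span plus flanks, the best frame per exon, and the
best-scoring ATG-to-stop ORF on the spliced transcript.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ..annotation_io.genome import spliced_sequence as _spliced_seq  # noqa: F401
from ..annotation_io.intervals import GenomicInterval, MINUS, Transcript
from ..annotation_io.maf import (
    MafStore,
    RegionAlignment,
    concatenate_regions,
    extract_region_alignment,
)
from ..annotation_io.trees import SpeciesTree
from .models import (
    CODON_INDEX,
    NT_INDEX,
    STOP_CODONS,
    SubstitutionModel,
    codon_partials,
    compress_columns,
    hky_model,
    mg94_model,
    nucleotide_partials,
    site_log_likelihoods,
)
from .orf import OpenReadingFrame, scan_orfs

logger = logging.getLogger(__name__)

_DB = 10.0 / math.log(10.0)

# third-position columns of these codon prefixes never change the amino acid
FOURFOLD_PREFIXES = {"TC", "CT", "GT", "CC", "CG", "AC", "GC", "GG"}


@dataclass
class NeutralModel:
    """HKY85 fitted on four-fold degenerate sites, plus a tree scale factor."""

    pi: np.ndarray
    kappa: float
    scale: float
    tree: SpeciesTree
    n_sites: int = 0

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if not np.all(self.pi > 0) or abs(self.pi.sum() - 1.0) > 1e-6:
            raise ValueError("pi must be positive and sum to 1")
        if self.kappa <= 0 or self.scale <= 0:
            raise ValueError("kappa and scale must be positive")
        self.model: SubstitutionModel = hky_model(self.pi, self.kappa)


@dataclass
class CodingModel:
    """MG94xHKY sharing pi/kappa with the neutral model; omega fixed or refit."""

    neutral: NeutralModel
    omega: float = 0.2

    def __post_init__(self) -> None:
        self.model: SubstitutionModel = mg94_model(self.neutral.pi, self.neutral.kappa, self.omega)


@dataclass
class CodingScore:
    total_decibans: float
    per_codon: np.ndarray
    best_frame: int
    mode: str
    n_codons: int = 0
    warnings: list[str] = field(default_factory=list)


class NeutralFitError(RuntimeError):
    pass


def collect_fourfold_columns(
    store: MafStore,
    reference_transcripts: list[Transcript],
    species: list[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Alignment columns at four-fold degenerate third codon positions.

    Transcripts must carry CDS records in ``attributes["cds"]`` (genomic
    0-based half-open ``(start, end, frame)`` tuples).  Returns the columns
    and the species order of their characters.
    """
    ref = store.reference_species
    columns: list[str] = []
    sp_order: list[str] = []
    for t in reference_transcripts:
        cds = t.attributes.get("cds")
        if not cds:
            continue
        regions = [
            extract_region_alignment(store, GenomicInterval(t.chrom, s, e, t.strand), species)
            for s, e, _f in cds
        ]
        aln = concatenate_regions(regions)
        if t.strand == MINUS:
            aln = aln.reverse_complemented()
        if not sp_order:
            sp_order = list(aln.species)
        rows = [aln.rows[sp] for sp in sp_order]
        ref_row = aln.rows[ref]
        n_cod = len(ref_row) // 3
        for i in range(n_cod):
            codon = ref_row[3 * i : 3 * i + 3]
            if codon[:2] in FOURFOLD_PREFIXES and codon in CODON_INDEX:
                columns.append("".join(r[3 * i + 2] for r in rows))
    return columns, sp_order


def fit_neutral_model(
    store: MafStore,
    reference_transcripts: list[Transcript],
    tree: SpeciesTree,
    min_columns: int = 100,
    species: list[str] | None = None,
) -> NeutralModel:
    """Maximize the HKY likelihood over (kappa, tree scale) on 4-fold sites.

    Base frequencies are fixed at the empirical frequencies of the columns;
    branch-length proportions of the input tree are preserved.
    """
    if species is None:
        species = [sp for sp in store.species if sp in tree.leaf_names]
    columns, sp_order = collect_fourfold_columns(store, reference_transcripts, species)
    if len(columns) < min_columns:
        raise NeutralFitError(
            f"only {len(columns)} four-fold degenerate columns available "
            f"(need >= {min_columns})"
        )
    counts = np.zeros(4)
    for col in columns:
        for c in col:
            j = NT_INDEX.get(c)
            if j is not None:
                counts[j] += 1
    if np.any(counts == 0):
        counts += 1.0  # pseudocount to keep frequencies positive
    pi = counts / counts.sum()
    patterns, weights = compress_columns(columns)
    leaf_partials = {
        sp: np.vstack([nucleotide_partials(p[i])[0:1] for p in patterns])
        for i, sp in enumerate(sp_order)
        if sp in tree.leaf_names
    }

    def neg_ll(x):
        # clamp keeps kappa/scale in (e^-14, e^14); flat directions (e.g. an
        # invariant alignment leaves kappa unidentified) stay finite
        kappa = math.exp(min(max(x[0], -14.0), 14.0))
        scale = math.exp(min(max(x[1], -14.0), 14.0))
        model = hky_model(pi, kappa)
        ll = site_log_likelihoods(tree, model, leaf_partials, rate_scale=scale)
        return -float(np.dot(ll, weights))

    res = minimize(neg_ll, x0=[math.log(2.0), 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    kappa = math.exp(min(max(res.x[0], -14.0), 14.0))
    scale = max(math.exp(min(max(res.x[1], -14.0), 14.0)), 1e-6)
    return NeutralModel(pi=pi, kappa=kappa, scale=scale, tree=tree, n_sites=len(columns))


# ---------------------------------------------------------------------------
# Region scoring
# ---------------------------------------------------------------------------

def _tree_rows(aln: RegionAlignment, tree: SpeciesTree) -> dict[str, str]:
    rows = {}
    for sp in aln.species:
        if sp in tree.leaf_names:
            rows[sp] = aln.rows[sp]
        else:
            logger.warning("alignment row %s not in tree; dropped", sp)
    return rows


def coding_score(
    region_alignment: RegionAlignment,
    frame: int,
    neutral_model: NeutralModel,
    coding_model: CodingModel,
    mode: str = "per_codon",
) -> CodingScore:
    """Deciban log-likelihood ratio of coding vs neutral evolution.

    Codons whose reference codon is a stop are scored under the neutral model
    only and contribute 0 decibans.
    """
    aln = region_alignment.reverse_complemented() if frame >= 3 else region_alignment
    offset = frame % 3
    tree = neutral_model.tree
    rows = _tree_rows(aln, tree)
    ref = aln.reference_species
    if ref not in rows:
        raise ValueError("reference species missing from tree")
    n = aln.n_columns
    n_codons = (n - offset) // 3
    warnings: list[str] = []
    if n_codons < 1:
        raise ValueError("region shorter than one codon in this frame")
    informative = any(
        any(c in NT_INDEX for c in row)
        for sp, row in rows.items()
        if sp != ref
    )
    if not informative:
        warnings.append("no informative species")
        return CodingScore(0.0, np.zeros(n_codons), frame, mode, n_codons, warnings)
    start, end = offset, offset + 3 * n_codons
    segs = {sp: row[start:end] for sp, row in rows.items()}
    ref_seg = segs[ref]
    stop_mask = np.array(
        [ref_seg[3 * i : 3 * i + 3] in STOP_CODONS for i in range(n_codons)]
    )
    scale = neutral_model.scale
    cod_parts = {sp: codon_partials(s) for sp, s in segs.items()}
    ln_c = site_log_likelihoods(tree, coding_model.model, cod_parts, rate_scale=scale)
    nuc_parts = {sp: nucleotide_partials(s) for sp, s in segs.items()}
    ln_n_site = site_log_likelihoods(tree, neutral_model.model, nuc_parts, rate_scale=scale)
    ln_n = ln_n_site.reshape(n_codons, 3).sum(axis=1)
    per_codon = _DB * (ln_c - ln_n)
    per_codon[stop_mask] = 0.0
    return CodingScore(
        total_decibans=float(per_codon.sum()),
        per_codon=per_codon,
        best_frame=frame,
        mode=mode,
        n_codons=n_codons,
        warnings=warnings,
    )


def write_bedgraph_track(
    path,
    chrom: str,
    region_start: int,
    profiles: dict[int, CodingScore],
    track_name: str = "coding_potential",
) -> None:
    """Browser-track export of per-codon deciban profiles.

    Each codon is written as a 3-nt bedGraph interval; where frames overlap
    a position, the maximum across frames is reported.
    """
    per_pos: dict[int, float] = {}
    for frame, score in profiles.items():
        offset = frame % 3
        for k, value in enumerate(score.per_codon):
            pos = region_start + offset + 3 * k
            for p in range(pos, pos + 3):
                per_pos[p] = max(per_pos.get(p, float("-inf")), float(value))
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        run_start = None
        run_val = None
        last = None
        for p in sorted(per_pos):
            v = round(per_pos[p], 3)
            if run_start is not None and (p != last + 1 or v != run_val):
                fh.write(f"{chrom}\t{run_start}\t{last + 1}\t{run_val}\n")
                run_start = None
            if run_start is None:
                run_start, run_val = p, v
            last = p
        if run_start is not None:
            fh.write(f"{chrom}\t{run_start}\t{last + 1}\t{run_val}\n")


def score_per_codon(
    transcript: Transcript,
    store: MafStore,
    neutral_model: NeutralModel,
    coding_model: CodingModel,
    flank: int = 50,
    chrom_length: int | None = None,
    species: list[str] | None = None,
) -> dict[int, CodingScore]:
    """Six-frame per-codon deciban profiles over the transcript span +/- flank."""
    start = max(0, transcript.start - flank)
    end = transcript.end + flank
    if chrom_length is not None and end > chrom_length:
        logger.warning("flank clipped to chromosome end for %s", transcript.id)
        end = chrom_length
    iv = GenomicInterval(transcript.chrom, start, end)
    aln = extract_region_alignment(store, iv, species)
    return {
        frame: coding_score(aln, frame, neutral_model, coding_model, mode="per_codon")
        for frame in range(6)
    }


def score_per_exon(
    transcript: Transcript,
    store: MafStore,
    neutral_model: NeutralModel,
    coding_model: CodingModel,
    species: list[str] | None = None,
) -> list[tuple[GenomicInterval, CodingScore]]:
    """Best frame and score for each exon interval."""
    out = []
    for exon in transcript.exons:
        if len(exon) < 3:
            score = CodingScore(0.0, np.zeros(0), 0, "per_exon", 0, ["exon shorter than 3 nt"])
            out.append((exon, score))
            continue
        aln = extract_region_alignment(store, exon, species)
        best = None
        for frame in range(6):
            if (aln.n_columns - frame % 3) < 3:
                continue
            s = coding_score(aln, frame, neutral_model, coding_model, mode="per_exon")
            if best is None or s.total_decibans > best.total_decibans:
                best = s
        out.append((exon, best))
    return out


def spliced_alignment(
    transcript: Transcript,
    store: MafStore,
    species: list[str] | None = None,
) -> RegionAlignment:
    """Exon sub-alignments concatenated in transcript orientation."""
    regions = [extract_region_alignment(store, e, species) for e in transcript.exons]
    aln = concatenate_regions(regions)
    if transcript.strand == MINUS:
        aln = aln.reverse_complemented()
    return aln


def score_per_gene(
    transcript: Transcript,
    store: MafStore,
    neutral_model: NeutralModel,
    coding_model: CodingModel,
    species: list[str] | None = None,
) -> tuple[OpenReadingFrame | None, CodingScore]:
    """Best-scoring ATG-to-stop ORF on the spliced transcript.

    If no ATG-anchored ORF exists, the best-scoring maximal stop-free
    stretch is scored instead and flagged ``no_start_codon``.
    """
    aln = spliced_alignment(transcript, store, species)
    ref_seq = aln.rows[aln.reference_species]
    orfs = scan_orfs(ref_seq)
    anchored = [o for o in orfs if o.requires_start and o.has_stop]
    candidates = anchored if anchored else [o for o in orfs if o.nt_length >= 3]
    flag = None if anchored else "no_start_codon"
    rc_aln = aln.reverse_complemented()
    best: tuple[OpenReadingFrame, CodingScore] | None = None
    for orf in candidates:
        sub = (rc_aln if orf.frame >= 3 else aln).subset_columns(orf.start, orf.end)
        score = coding_score(sub, 0, neutral_model, coding_model, mode="per_gene")
        score = CodingScore(
            score.total_decibans, score.per_codon, orf.frame, "per_gene",
            score.n_codons, score.warnings,
        )
        if best is None or score.total_decibans > best[1].total_decibans:
            best = (orf, score)
    if best is None:
        return None, CodingScore(0.0, np.zeros(0), 0, "per_gene", 0, ["no scorable frame"])
    if flag:
        best[1].warnings.append(flag)
    return best


def score_longest_orf(
    transcript: Transcript,
    store: MafStore,
    neutral_model: NeutralModel,
    coding_model: CodingModel,
    species: list[str] | None = None,
) -> tuple[OpenReadingFrame | None, CodingScore]:
    """Score of the longest ATG-to-stop ORF (the one the peptide-length
    thresholds refer to).

    Unlike the best-scoring-ORF argmax of :func:`score_per_gene`, this avoids
    the upward selection bias of maximizing over many short ORFs and is the
    evidence used for classification.  Falls back to the best-scoring maximal
    stop-free stretch when no ATG-anchored ORF exists.
    """
    aln = spliced_alignment(transcript, store, species)
    ref_seq = aln.rows[aln.reference_species]
    orfs = scan_orfs(ref_seq)
    anchored = [o for o in orfs if o.requires_start and o.has_stop]
    if not anchored:
        return score_per_gene(transcript, store, neutral_model, coding_model, species)
    orf = max(anchored, key=lambda o: (o.peptide_length, -o.frame, o.start))
    sub = (aln.reverse_complemented() if orf.frame >= 3 else aln).subset_columns(
        orf.start, orf.end
    )
    score = coding_score(sub, 0, neutral_model, coding_model, mode="per_gene")
    return orf, CodingScore(
        score.total_decibans, score.per_codon, orf.frame, "per_gene",
        score.n_codons, score.warnings,
    )
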