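"""End-to-end synthetic study generation.

One call produces every input the pipeline consumes — genome FASTA,
reference GTF, two pseudo-assembler GTFs, a multi-species MAF, a Newick
tree, a root-age table and a domain table — together with a serializable
ground-truth record (generating class per gene, per-species ablation,
planted structures, duplicate pairs).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..annotation_io.genome import reverse_complement, write_fasta
from ..annotation_io.gtf import write_gtf
from ..annotation_io.intervals import GenomicInterval, MINUS, PLUS, Transcript
from ..annotation_io.maf import MafBlock, write_maf
from ..annotation_io.trees import SpeciesTree
from ..coding_potential.orf import max_peptide_length, scan_orfs
from .evolve import (
    CodingSpec,
    NeutralSpec,
    StructuredSpec,
    hairpin_pairs,
    ladder_tree,
    simulate_coding,
    simulate_frozen,
    simulate_neutral,
    simulate_structured,
)

SENSE_NO_ATG = None  # filled lazily


@dataclass
class StudyConfig:
    chrom: str = "chr1"
    reference: str = "ref"
    tree_newick: str | None = None
    n_ref_genes: int = 8
    n_coding: int = 15
    n_lnc_structured: int = 15
    n_lnc_unstructured: int = 5
    n_lnc_intronic: int = 5
    n_lnc_antisense: int = 5
    n_ambiguous: int = 15
    n_duplicate_pairs: int = 3
    n_spurious_per_assembler: int = 4
    kappa: float = 2.5
    scale: float = 1.0
    omega_coding: float = 0.1
    gc: float = 0.5
    drop_prob: float = 0.0
    jitter_sd: float = 0.0
    decay_rate: float = 0.3
    compensatory_prob: float = 0.9
    pair_sub_rate: float = 1.5
    ablation_rates: dict = field(
        default_factory=lambda: {"coding": 0.10, "lncRNA": 0.35, "ambiguous": 0.25}
    )
    spacer: int = 400
    maf_block: int = 1000
    max_lnc_peptide: int = 45  # rejection bound for planted non-coding genes
    age_per_distance: float = 40.0  # Mya per substitution/site of ref-leaf distance

    @property
    def pi(self) -> tuple:
        at = (1.0 - self.gc) / 2
        gc = self.gc / 2
        return (at, gc, gc, at)

    def n_lncrna(self) -> int:
        return (
            self.n_lnc_structured
            + self.n_lnc_unstructured
            + self.n_lnc_intronic
            + self.n_lnc_antisense
        )


@dataclass
class PlantedStructure:
    gene_id: str
    start: int  # genomic
    end: int
    retained: dict[str, bool]


@dataclass
class StudyTruth:
    classes: dict[str, str] = field(default_factory=dict)        # gene -> generating class
    class_codes: dict[str, str] = field(default_factory=dict)    # gene -> expected I/U/X
    ablation: dict[str, list[str]] = field(default_factory=dict)  # gene -> species lost
    structures: list[PlantedStructure] = field(default_factory=list)
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    spurious: dict[str, list[str]] = field(default_factory=dict)  # assembler -> ids
    dropped: dict[str, list[str]] = field(default_factory=dict)   # assembler -> ids
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["structures"] = [dataclasses.asdict(s) for s in self.structures]
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyTruth":
        payload = json.loads(Path(path).read_text())
        payload["structures"] = [PlantedStructure(**s) for s in payload["structures"]]
        payload["duplicate_pairs"] = [tuple(p) for p in payload["duplicate_pairs"]]
        return cls(**payload)


class _ChromBuilder:
    """Accumulates per-species sequence pieces along one chromosome."""

    def __init__(self, species: list[str]):
        self.species = species
        self.pieces: dict[str, list[str]] = {sp: [] for sp in species}
        self.cursor = 0

    def append(self, rows: dict[str, str]) -> tuple[int, int]:
        n = len(next(iter(rows.values())))
        for sp in self.species:
            self.pieces[sp].append(rows[sp])
        start = self.cursor
        self.cursor += n
        return start, self.cursor

    def sequences(self) -> dict[str, str]:
        return {sp: "".join(self.pieces[sp]) for sp in self.species}


def _concat_rows(parts: list[dict[str, str]], species: list[str]) -> dict[str, str]:
    return {sp: "".join(p[sp] for p in parts) for sp in species}


def _cut_rows(rows: dict[str, str], lengths: list[int], species: list[str]) -> list[dict[str, str]]:
    out = []
    pos = 0
    for n in lengths:
        out.append({sp: rows[sp][pos : pos + n] for sp in species})
        pos += n
    return out


def _rc_rows(rows: dict[str, str], species: list[str]) -> dict[str, str]:
    return {sp: reverse_complement(rows[sp]) for sp in species}


def _genomic_layout(
    spliced: dict[str, str],
    exon_lengths: list[int],
    intron_rows: list[dict[str, str]],
    strand: str,
    species: list[str],
) -> tuple[list[dict[str, str]], list[tuple[int, int]]]:
    """Arrange spliced pieces + introns into genomic order.

    Returns (ordered row pieces, exon offsets relative to the feature start).
    """
    exon_pieces = _cut_rows(spliced, exon_lengths, species)
    if strand == MINUS:
        exon_pieces = [_rc_rows(p, species) for p in reversed(exon_pieces)]
        exon_lengths = list(reversed(exon_lengths))
    ordered: list[dict[str, str]] = []
    offsets: list[tuple[int, int]] = []
    pos = 0
    for k, piece in enumerate(exon_pieces):
        ordered.append(piece)
        offsets.append((pos, pos + exon_lengths[k]))
        pos += exon_lengths[k]
        if k < len(intron_rows):
            n = len(next(iter(intron_rows[k].values())))
            ordered.append(intron_rows[k])
            pos += n
    return ordered, offsets


def patristic_distances(tree: SpeciesTree, reference: str) -> dict[str, float]:
    """Path length from the reference leaf to every other leaf."""
    parent = {}
    for node in tree.nodes:
        for ci in node.children:
            parent[ci] = node.index

    def path_to_root(idx: int) -> dict[int, float]:
        depth = {}
        d = 0.0
        while idx in parent:
            d += tree.nodes[idx].branch_length
            idx = parent[idx]
            depth[idx] = d
        return depth

    ref_depths = path_to_root(tree.leaf_index(reference))
    out = {}
    for name in tree.leaf_names:
        if name == reference:
            out[name] = 0.0
            continue
        depths = path_to_root(tree.leaf_index(name))
        shared = set(ref_depths) & set(depths)
        out[name] = min(ref_depths[a] + depths[a] for a in shared)
    return out


def _random_sense_codons(n: int, rng: np.random.Generator, forbid_atg: bool = True) -> str:
    from ..coding_potential.models import SENSE_CODONS

    codons = [c for c in SENSE_CODONS if not (forbid_atg and c == "ATG")]
    return "".join(codons[rng.integers(len(codons))] for _ in range(n))


@dataclass
class _Feature:
    transcript: Transcript
    truth_class: str | None = None  # coding / lncRNA / ambiguous / duplicate / reference
    class_code: str | None = None
    ablatable: bool = False
    structures: list[tuple[int, int, dict[str, bool]]] = field(default_factory=list)


def generate_genome(
    n_chrom: int, length: int, gc: float, seed: int, genes_per_chrom: int = 4
) -> tuple[dict[str, str], list[Transcript]]:
    """IID genome with planted, non-overlapping multi-exon reference genes."""
    if length < 10_000:
        raise ValueError("length must be >= 10 kb per chromosome")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1 - gc) / 2
    p = np.array([at, gc / 2, gc / 2, at])
    genome: dict[str, str] = {}
    genes: list[Transcript] = []
    bases = np.array(list("ACGT"))
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        seq = "".join(bases[rng.choice(4, size=length, p=p)])
        genome[chrom] = seq
        slot = length // (genes_per_chrom + 1)
        for g in range(genes_per_chrom):
            start = slot * (g + 1)
            strand = PLUS if g % 2 == 0 else MINUS
            e1 = GenomicInterval(chrom, start, start + 300, strand)
            e2 = GenomicInterval(chrom, start + 500, start + 800, strand)
            cds = [(e1.start, e1.end, 0), (e2.start, e2.end, 0)]
            genes.append(
                Transcript(
                    id=f"{chrom}_gene{g}",
                    exons=[e1, e2],
                    class_code="REFERENCE",
                    source="reference",
                    attributes={"gene_id": f"{chrom}_gene{g}", "cds": cds},
                )
            )
    return genome, genes


def generate_assembler_calls(
    planted: list[Transcript],
    rng: np.random.Generator,
    drop_prob: float = 0.0,
    jitter_sd: float = 0.0,
    chrom_length: int | None = None,
) -> tuple[list[Transcript], list[Transcript], dict[str, list[str]]]:
    """Two noisy transcript-call sets from the planted novel set.

    Returns (set_a, set_b, dropped ids per assembler).  Spurious calls are
    added by the caller (they need genomic territory of their own).
    """

    def jitter(t: Transcript, prefix: str) -> Transcript:
        exons = list(t.exons)
        if jitter_sd > 0:
            first, last = exons[0], exons[-1]
            ds = int(round(rng.normal(0, jitter_sd)))
            de = int(round(rng.normal(0, jitter_sd)))
            new_start = max(0, min(first.start + ds, first.end - 20))
            new_end = max(last.start + 20, last.end + de)
            if chrom_length is not None:
                new_end = min(new_end, chrom_length)
            exons[0] = GenomicInterval(first.chrom, new_start, first.end, first.strand)
            exons[-1] = GenomicInterval(last.chrom, last.start, new_end, last.strand)
        return Transcript(
            id=prefix + t.id,
            exons=exons,
            source=prefix.rstrip("_") or "cufflinks",
            attributes={"gene_id": prefix + t.attributes.get("gene_id", t.id)},
        )

    set_a, set_b = [], []
    dropped: dict[str, list[str]] = {"a": [], "b": []}
    for t in planted:
        if rng.random() < drop_prob:
            dropped["a"].append(t.id)
        else:
            set_a.append(jitter(t, ""))
        if rng.random() < drop_prob:
            dropped["b"].append(t.id)
        else:
            set_b.append(jitter(t, "scr_"))
    return set_a, set_b, dropped


@dataclass
class StudyBundle:
    outdir: Path
    genome_path: Path
    reference_gtf: Path
    cufflinks_gtf: Path
    scripture_gtf: Path
    maf_path: Path
    tree_path: Path
    root_age_path: Path
    domain_path: Path
    truth_path: Path
    truth: StudyTruth
    tree: SpeciesTree
    config: StudyConfig


def generate_study(outdir: str | Path, config: StudyConfig | None = None,
                   seed: int = 0) -> StudyBundle:
    """Generate a complete, internally consistent desk-scale study."""
    cfg = config or StudyConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    tree = ladder_tree(cfg.tree_newick)
    species = tree.leaf_names
    ref = cfg.reference
    if ref not in species:
        raise ValueError(f"reference {ref} not among tree leaves {species}")
    neutral = NeutralSpec(kappa=cfg.kappa, scale=cfg.scale, pi=cfg.pi)
    coding = CodingSpec(omega=cfg.omega_coding, kappa=cfg.kappa, scale=cfg.scale, pi=cfg.pi)
    builder = _ChromBuilder(species)
    features: list[_Feature] = []

    def sim_neutral(length: int) -> dict[str, str]:
        return simulate_neutral(tree, neutral, length, rng)

    def sim_neutral_rejected(length: int, window: tuple[int, int],
                             max_pep: int, tries: int = 400) -> dict[str, str]:
        for _ in range(tries):
            rows = sim_neutral(length)
            seg = rows[ref][window[0] : window[1]]
            if max_peptide_length(scan_orfs(seg)) < max_pep:
                return rows
        raise RuntimeError("rejection sampling failed; relax the ORF bound")

    def add_spacer(length: int | None = None) -> None:
        builder.append(sim_neutral(length or cfg.spacer))

    def add_feature(
        fid: str,
        spliced_parts: list[dict[str, str]],
        exon_lengths: list[int],
        intron_rows: list[dict[str, str]],
        strand: str,
        truth_class: str | None,
        class_code: str | None,
        ablatable: bool,
        cds_exons: list[int] | None = None,
        source: str = "planted",
        structures_spliced: list[tuple[int, int, dict[str, bool]]] = (),
    ) -> _Feature:
        spliced = _concat_rows(spliced_parts, species)
        ordered, offsets = _genomic_layout(spliced, exon_lengths, intron_rows, strand, species)
        start0 = builder.cursor
        for piece in ordered:
            builder.append(piece)
        exons = [
            GenomicInterval(cfg.chrom, start0 + a, start0 + b, strand) for a, b in offsets
        ]
        attrs: dict = {"gene_id": fid}
        if cds_exons is not None:
            attrs["cds"] = [(exons[k].start, exons[k].end, 0) for k in cds_exons]
        t = Transcript(id=fid, exons=exons, source=source, attributes=attrs)
        # map spliced structure offsets to genomic coordinates
        structs = []
        for s, e, kept in structures_spliced:
            if strand == MINUS:
                total = sum(exon_lengths)
                gs, ge = total - e, total - s
            else:
                gs, ge = s, e
            structs.append((start0 + gs, start0 + ge, kept))
        feat = _Feature(t, truth_class, class_code, ablatable, structs)
        features.append(feat)
        return feat

    # --- reference genes -------------------------------------------------
    n_hosts = max(cfg.n_lnc_intronic, cfg.n_lnc_antisense)
    if cfg.n_ref_genes < n_hosts:
        raise ValueError("need at least as many reference genes as hosted lncRNAs")
    intronic_ids, antisense_ids = [], []
    for g in range(cfg.n_ref_genes):
        host_i = g < cfg.n_lnc_intronic
        host_x = g < cfg.n_lnc_antisense
        strand = PLUS if (host_i or host_x or g % 2 == 0) else MINUS
        add_spacer()
        parts = [
            simulate_frozen(tree, "ATG"),
            simulate_coding(tree, coding, 149, rng),
            simulate_coding(tree, coding, 149, rng),
            simulate_frozen(tree, "TAA"),
        ]
        intron1_len = 600 if host_i else 120
        if host_i:
            intron1 = sim_neutral_rejected(intron1_len, (100, 500), cfg.max_lnc_peptide)
        else:
            intron1 = sim_neutral(intron1_len)
        if host_x:
            tail = sim_neutral_rejected(550, (30, 450), cfg.max_lnc_peptide)
            utr = {sp: tail[sp][:150] for sp in species}
            tail_rest = {sp: tail[sp][150:] for sp in species}
        else:
            utr = sim_neutral(150)
            tail_rest = None
        parts.append(utr)
        feat = add_feature(
            f"ref_{g}",
            parts,
            exon_lengths=[450, 450, 150],
            intron_rows=[intron1, sim_neutral(100)],
            strand=strand,
            truth_class="reference",
            class_code="REFERENCE",
            ablatable=False,
            cds_exons=[0, 1],
            source="reference",
        )
        gene_start = feat.transcript.start
        if host_i:
            # single-exon lncRNA inside intron 1 (between exon offsets 450..1050)
            iv = GenomicInterval(cfg.chrom, gene_start + 450 + 100, gene_start + 450 + 500, PLUS)
            tid = f"lnc_i_{len(intronic_ids)}"
            features.append(
                _Feature(
                    Transcript(id=tid, exons=[iv], source="planted",
                               attributes={"gene_id": tid}),
                    "lncRNA", "I", False,
                )
            )
            intronic_ids.append(tid)
        if tail_rest is not None:
            utr_start = feat.transcript.exons[-1].start
            builder.append(tail_rest)
            iv = GenomicInterval(cfg.chrom, utr_start + 30, utr_start + 450, MINUS)
            tid = f"lnc_x_{len(antisense_ids)}"
            features.append(
                _Feature(
                    Transcript(id=tid, exons=[iv], source="planted",
                               attributes={"gene_id": tid}),
                    "lncRNA", "X", False,
                )
            )
            antisense_ids.append(tid)

    # --- novel coding genes ----------------------------------------------
    for k in range(cfg.n_coding):
        add_spacer()
        strand = PLUS if k % 2 == 0 else MINUS
        parts = [
            sim_neutral(60),
            simulate_frozen(tree, "ATG"),
            simulate_coding(tree, coding, 130, rng),
            simulate_frozen(tree, "TAA"),
            sim_neutral(80),
        ]
        two_exon = k % 3 != 0
        exon_lengths = [250, 286] if two_exon else [536]
        introns = [sim_neutral(150)] if two_exon else []
        add_feature(
            f"nov_c_{k}", parts, exon_lengths, introns, strand,
            "coding", "U", ablatable=True,
        )

    # --- lncRNAs (structured + unstructured intergenic) -------------------
    struct_spec = StructuredSpec(
        pairs=tuple(
            p for off in (0, 30, 60) for p in hairpin_pairs(off, stem=10, loop=5)
        ),
        compensatory_prob=cfg.compensatory_prob,
        decay_rate=cfg.decay_rate,
        pair_sub_rate=cfg.pair_sub_rate,
        kappa=cfg.kappa,
        scale=cfg.scale,
        pi=cfg.pi,
    )

    def structured_segment() -> tuple[dict[str, str], dict[str, bool]]:
        return simulate_structured(tree, struct_spec, 90, rng)

    for k in range(cfg.n_lnc_structured):
        add_spacer()
        for _try in range(200):
            seg1, kept1 = structured_segment()
            seg2, kept2 = structured_segment()
            mids = [sim_neutral(60), sim_neutral(90), sim_neutral(150)]
            parts = [mids[0], seg1, mids[1], seg2, mids[2]]
            ref_seq = "".join(p[ref] for p in parts)
            if max_peptide_length(scan_orfs(ref_seq)) < cfg.max_lnc_peptide:
                break
        add_feature(
            f"lnc_s_{k}", parts, [480], [], PLUS if k % 2 else MINUS,
            "lncRNA", "U", ablatable=True,
            structures_spliced=[(60, 150, kept1), (240, 330, kept2)],
        )

    for k in range(cfg.n_lnc_unstructured):
        add_spacer()
        rows = sim_neutral_rejected(480, (0, 480), cfg.max_lnc_peptide)
        two_exon = k % 5 == 4
        exon_lengths = [240, 160] if two_exon else [480]
        introns = [sim_neutral(120)] if two_exon else []
        if two_exon:
            rows = {sp: rows[sp][:400] for sp in species}
            exon_lengths = [240, 160]
        add_feature(
            f"lnc_u_{k}", [rows], exon_lengths, introns, PLUS if k % 2 else MINUS,
            "lncRNA", "U", ablatable=True,
        )

    # --- ambiguous genes (mid-size frozen ORF, neutral elsewhere) ---------
    for k in range(cfg.n_ambiguous):
        add_spacer()
        orf = "ATG" + _random_sense_codons(70, rng) + "TAA"
        frozen = simulate_frozen(tree, orf)
        for _try in range(400):
            head = sim_neutral(120)
            tail = sim_neutral(164)
            parts = [head, frozen, tail]
            pep = max_peptide_length(
                scan_orfs("".join(p[ref] for p in parts))
            )
            # keep the planted mid-size ORF the dominant one (50 < pep <= 95)
            if 50 < pep <= 95:
                break
        add_feature(
            f"amb_{k}", parts, [500], [], PLUS if k % 2 else MINUS,
            "ambiguous", "U", ablatable=True,
        )

    # --- complementary-strand duplicate pairs -----------------------------
    duplicate_pairs: list[tuple[str, str]] = []
    for k in range(cfg.n_duplicate_pairs):
        add_spacer()
        rows = sim_neutral(350)
        start0 = builder.cursor
        builder.append(rows)
        iv_p = GenomicInterval(cfg.chrom, start0, start0 + 350, PLUS)
        iv_m = GenomicInterval(cfg.chrom, start0, start0 + 350, MINUS)
        ta = Transcript(id=f"dup_{k}a", exons=[iv_p], source="planted",
                        attributes={"gene_id": f"dup_{k}a"})
        tb = Transcript(id=f"dup_{k}b", exons=[iv_m], source="planted",
                        attributes={"gene_id": f"dup_{k}b"})
        features.append(_Feature(ta, "duplicate", "U", False))
        features.append(_Feature(tb, "duplicate", "U", False))
        duplicate_pairs.append((f"dup_{k}a", f"dup_{k}b"))

    # --- spurious-call territory ------------------------------------------
    spurious: dict[str, list[str]] = {"a": [], "b": []}
    spurious_transcripts: dict[str, list[Transcript]] = {"a": [], "b": []}
    for k in range(2 * cfg.n_spurious_per_assembler):
        add_spacer(200)
        start0 = builder.cursor
        builder.append(sim_neutral(250))
        which = "a" if k % 2 == 0 else "b"
        tid = f"spur_{which}_{k // 2}"
        iv = GenomicInterval(cfg.chrom, start0, start0 + 250, PLUS if k % 4 < 2 else MINUS)
        spurious_transcripts[which].append(
            Transcript(id=tid, exons=[iv], source="planted", attributes={"gene_id": tid})
        )
        spurious[which].append(tid)
    add_spacer()

    chrom_seqs = builder.sequences()
    L = builder.cursor

    # --- ablation ----------------------------------------------------------
    dists = patristic_distances(tree, ref)
    truth = StudyTruth(seed=seed, config=dataclasses.asdict(cfg))
    ablation_spans: list[tuple[int, int, list[str]]] = []
    for feat in features:
        t = feat.transcript
        if feat.truth_class in (None, "reference"):
            truth.classes[t.id] = feat.truth_class or "reference"
            truth.class_codes[t.id] = feat.class_code or ""
            continue
        truth.classes[t.id] = feat.truth_class
        truth.class_codes[t.id] = feat.class_code or ""
        lost: list[str] = []
        if feat.ablatable:
            rate = cfg.ablation_rates.get(
                {"coding": "coding", "lncRNA": "lncRNA", "ambiguous": "ambiguous"}.get(
                    feat.truth_class, "ambiguous"
                ),
                0.0,
            )
            for sp in species:
                if sp == ref:
                    continue
                if rng.random() < 1.0 - np.exp(-rate * dists[sp]):
                    lost.append(sp)
        truth.ablation[t.id] = lost
        if lost:
            ablation_spans.append((t.start, t.end, lost))
    truth.duplicate_pairs = duplicate_pairs
    truth.spurious = spurious
    for feat in features:
        for gs, ge, kept in feat.structures:
            truth.structures.append(
                PlantedStructure(feat.transcript.id, gs, ge, dict(kept))
            )

    # --- MAF ----------------------------------------------------------------
    breakpoints = {0, L}
    for s, e, _lost in ablation_spans:
        breakpoints.update((s, e))
    breakpoints.update(range(0, L, cfg.maf_block))
    bounds = sorted(breakpoints)
    blocks: list[MafBlock] = []
    for s, e in zip(bounds, bounds[1:]):
        if e <= s:
            continue
        lost_here: set[str] = set()
        for gs, ge, lost in ablation_spans:
            if gs <= s and e <= ge:
                lost_here.update(lost)
        rows = {
            sp: (chrom_seqs[sp][s:e], s, e - s, "+", L)
            for sp in species
            if sp not in lost_here
        }
        blocks.append(MafBlock(ref_chrom=cfg.chrom, ref_start=s, ref_end=e, rows=rows))

    # --- emit files ---------------------------------------------------------
    genome_path = outdir / "genome.fa"
    write_fasta({cfg.chrom: chrom_seqs[ref]}, genome_path)
    ref_gtf = outdir / "reference.gtf"
    write_gtf([f.transcript for f in features if f.truth_class == "reference"], ref_gtf,
              source="reference")
    planted_novel = [
        f.transcript for f in features if f.truth_class not in (None, "reference")
    ]
    set_a, set_b, dropped = generate_assembler_calls(
        planted_novel, rng, cfg.drop_prob, cfg.jitter_sd, chrom_length=L
    )
    set_a.extend(spurious_transcripts["a"])
    set_b.extend(spurious_transcripts["b"])
    truth.dropped = dropped
    cuff_path = outdir / "cufflinks.gtf"
    scrip_path = outdir / "scripture.gtf"
    write_gtf(set_a, cuff_path, source="cufflinks")
    write_gtf(set_b, scrip_path, source="scripture")
    maf_path = outdir / "alignment.maf"
    write_maf(blocks, species, maf_path, ref)
    tree_path = outdir / "tree.nwk"
    tree.write(tree_path)
    age_path = outdir / "root_age.tsv"
    with open(age_path, "w") as fh:
        fh.write("species\tage_mya\n")
        for sp in species:
            fh.write(f"{sp}\t{dists[sp] / 2.0 * cfg.age_per_distance:.2f}\n")
    domain_path = outdir / "domains.tsv"
    with open(domain_path, "w") as fh:
        fh.write("transcript_id\tdomain_id\te_value\n")
        for k in range(min(3, cfg.n_coding)):
            fh.write(f"nov_c_{k}\tPF{k:05d}\t1e-10\n")
    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    return StudyBundle(
        outdir=outdir,
        genome_path=genome_path,
        reference_gtf=ref_gtf,
        cufflinks_gtf=cuff_path,
        scripture_gtf=scrip_path,
        maf_path=maf_path,
        tree_path=tree_path,
        root_age_path=age_path,
        domain_path=domain_path,
        truth_path=truth_path,
        truth=truth,
        tree=tree,
        config=cfg,
    )
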