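"""Stage runners: discover -> classify -> conserve/structure."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from ..annotation_io import (
    GenomicInterval,
    SpeciesTree,
    Transcript,
    read_fasta,
    read_gtf,
    read_maf,
    spliced_sequence,
    write_gtf,
)
from ..coding_potential import (
    ClassificationThresholds,
    CodingModel,
    Evidence,
    atg_orfs,
    classify_transcript,
    domain_lookup,
    fit_neutral_model,
    max_peptide_length,
    orf_fraction,
    read_domain_table,
    scan_orfs,
)
from ..coding_potential.scoring import (
    score_longest_orf,
    score_per_codon,
    write_bedgraph_track,
)
from ..conservation import (
    class_conservation_compare,
    conservation_test,
    presence_matrix,
)
from ..structure_conservation import (
    DivergencePoint,
    StructureScoreParams,
    divergence_regression,
    scan_windows,
    species_structure_presence,
)
from ..transcript_discovery import (
    classify_all,
    exon_count_summary,
    find_duplicate_complements,
    intersect_assemblies,
    length_filter,
)
from .config import PipelineConfig

logger = logging.getLogger(__name__)


def _write_report(cfg: PipelineConfig, name: str, payload: dict) -> Path:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{name}.json"
    payload = {"provenance": cfg.provenance(), **payload}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def run_discover(cfg: PipelineConfig) -> dict:
    """Dual-assembler intersection -> class codes (keep I/U/X) -> length filter."""
    for key in ("cufflinks_gtf", "scripture_gtf", "reference_gtf"):
        path = getattr(cfg, key)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"missing input: {key}={path!r}")
    set_a = read_gtf(cfg.cufflinks_gtf)
    set_b = read_gtf(cfg.scripture_gtf)
    reference = read_gtf(cfg.reference_gtf)
    stage_counts = {"cufflinks_input": len(set_a), "scripture_input": len(set_b)}
    supported = intersect_assemblies(set_a, set_b, min_overlap=cfg.min_overlap)
    stage_counts.update(supported.stage_counts)
    coded = classify_all(supported.transcripts, reference)
    stage_counts.update(coded.stage_counts)
    final = length_filter(coded.transcripts, min_len=cfg.min_len)
    stage_counts.update(final.stage_counts)
    dup_pairs = find_duplicate_complements(
        final.transcripts, min_fraction=cfg.duplicate_min_fraction
    )
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gtf(final.transcripts, outdir / "candidates.gtf")
    for code in ("I", "U", "X"):
        write_gtf(
            [t for t in final.transcripts if t.class_code == code],
            outdir / f"candidates_{code}.gtf",
        )
    pd.DataFrame(
        [{"stage": k, "count": v} for k, v in stage_counts.items()]
    ).to_csv(outdir / "stage_counts.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(dup_pairs), columns=["id_a", "id_b"]).to_csv(
        outdir / "duplicate_pairs.tsv", sep="\t", index=False
    )
    exon_count_summary(final.transcripts).to_csv(
        outdir / "exon_summary.tsv", sep="\t", index=False
    )
    report = {
        "stage_counts": stage_counts,
        "n_duplicate_pairs": len(dup_pairs),
        "per_class": {
            code: sum(1 for t in final.transcripts if t.class_code == code)
            for code in ("I", "U", "X")
        },
    }
    _write_report(cfg, "discover", report)
    return report


def _load_candidates(cfg: PipelineConfig) -> list[Transcript]:
    path = Path(cfg.outdir) / "candidates.gtf"
    if not path.exists():
        raise FileNotFoundError("discover outputs missing; run discover first")
    candidates = read_gtf(path)
    reference = read_gtf(cfg.reference_gtf)
    # class codes are not persisted in GTF; re-derive them
    from ..transcript_discovery import assign_class_code

    for t in candidates:
        t.class_code = assign_class_code(t, reference)
    return candidates


def run_classify(cfg: PipelineConfig) -> dict:
    """Score every candidate and label CODING / LNCRNA / AMBIGUOUS."""
    candidates = _load_candidates(cfg)
    genome = read_fasta(cfg.genome)
    store = read_maf(cfg.maf, cfg.reference_species)
    tree = SpeciesTree.read(cfg.tree)
    reference = read_gtf(cfg.reference_gtf)
    neutral = fit_neutral_model(
        store, reference, tree, min_columns=cfg.neutral_min_columns
    )
    coding = CodingModel(neutral, omega=cfg.omega)
    thresholds = ClassificationThresholds(
        coding_min_peptide=cfg.coding_min_peptide,
        coding_min_score=cfg.coding_min_score,
        lnc_max_peptide=cfg.lnc_max_peptide,
        lnc_max_orf_fraction=cfg.lnc_max_orf_fraction,
        lnc_max_score=cfg.lnc_max_score,
    )
    domains = read_domain_table(cfg.domains_tsv) if cfg.domains_tsv else None
    rows = []
    for t in candidates:
        seq = spliced_sequence(genome, t)
        orfs = scan_orfs(seq)
        peptide = max_peptide_length(orfs)
        anchored = atg_orfs(orfs)
        longest = max(anchored, key=lambda o: o.peptide_length) if anchored else None
        frac = orf_fraction(longest, len(seq)) if seq else 0.0
        _orf, score = score_longest_orf(t, store, neutral, coding)
        evidence = Evidence(
            peptide_length=peptide,
            orf_fraction=frac,
            score_decibans=score.total_decibans,
            has_domain=domain_lookup(t.id, domains) if domains is not None else False,
        )
        result = classify_transcript(evidence, thresholds)
        if cfg.score_tracks:
            chrom_len = len(genome[t.chrom])
            profiles = score_per_codon(
                t, store, neutral, coding, flank=cfg.flank, chrom_length=chrom_len
            )
            tracks_dir = Path(cfg.outdir) / "tracks"
            tracks_dir.mkdir(parents=True, exist_ok=True)
            write_bedgraph_track(
                tracks_dir / f"{t.id}.bedgraph",
                t.chrom,
                max(0, t.start - cfg.flank),
                profiles,
                track_name=t.id,
            )
        rows.append(
            {
                "transcript_id": t.id,
                "class_code": t.class_code,
                "peptide_length": peptide,
                "orf_fraction": round(frac, 4),
                "score_decibans": round(score.total_decibans, 3),
                "has_domain": evidence.has_domain,
                "label": result.label,
            }
        )
    table = pd.DataFrame(rows)
    outdir = Path(cfg.outdir)
    table.to_csv(outdir / "classification.tsv", sep="\t", index=False)
    label_counts = table["label"].value_counts().to_dict() if len(table) else {}
    report = {
        "n_candidates": len(candidates),
        "labels": {str(k): int(v) for k, v in label_counts.items()},
        "neutral_model": {
            "kappa": neutral.kappa,
            "scale": neutral.scale,
            "n_fourfold_sites": neutral.n_sites,
            "pi": [float(x) for x in neutral.pi],
        },
    }
    _write_report(cfg, "classify", report)
    return report


def run_conserve_structure(cfg: PipelineConfig) -> dict:
    """Presence/absence matrix, per-gene conservation, structure loci and
    the divergence-rate comparison."""
    outdir = Path(cfg.outdir)
    cls_path = outdir / "classification.tsv"
    if not cls_path.exists():
        raise FileNotFoundError("classify outputs missing; run classify first")
    labels = pd.read_csv(cls_path, sep="\t").set_index("transcript_id")["label"].to_dict()
    candidates = _load_candidates(cfg)
    reference = read_gtf(cfg.reference_gtf)
    store = read_maf(cfg.maf, cfg.reference_species)
    tree = SpeciesTree.read(cfg.tree)
    neutral = fit_neutral_model(store, reference, tree, min_columns=cfg.neutral_min_columns)
    species = [sp for sp in store.species if sp != cfg.reference_species]

    genes: list[Transcript] = []
    for t in reference:
        t.class_code = "REFERENCE"
        genes.append(t)
    for t in candidates:
        label = labels.get(t.id, "AMBIGUOUS")
        t.class_code = label
        genes.append(t)

    gene_table, pct_table = presence_matrix(genes, store, species, min_cov=cfg.min_cov)
    gene_table.to_csv(outdir / "presence_matrix.tsv", sep="\t", index=False)
    pct_table.to_csv(outdir / "presence_percent.tsv", sep="\t", index=False)

    results_by_class: dict[str, list] = {}
    cons_rows = []
    for g in genes:
        res = conservation_test(g, store, neutral)
        results_by_class.setdefault(g.class_code, []).append(res)
        cons_rows.append(
            {
                "gene_id": g.id,
                "class": g.class_code,
                "rate_multiplier": round(res.rate_multiplier, 6),
                "statistic": round(res.statistic, 6),
                "p_value": res.p_value,
                "neg_log10_p": round(res.neg_log10_p, 6),
                "testable": res.testable,
            }
        )
    pd.DataFrame(cons_rows).to_csv(outdir / "conservation.tsv", sep="\t", index=False)
    compare = class_conservation_compare(
        {k: v for k, v in results_by_class.items() if len(v) >= 2}
    )
    compare.to_csv(outdir / "conservation_compare.tsv", sep="\t", index=False)

    params = StructureScoreParams(
        weights=tuple(cfg.structure_weights),
        n_shuffles=cfg.n_shuffles,
        threshold=cfg.structure_threshold,
        max_z_rows=cfg.structure_max_z_rows,
    )
    lnc_genes = [t for t in candidates if labels.get(t.id) == "LNCRNA"]
    loci = []
    for i, g in enumerate(lnc_genes):
        loci.extend(
            scan_windows(
                g, store, window=cfg.window, step=cfg.step, params=params,
                seed=cfg.seed + 131 * i,
            )
        )
    with open(outdir / "structure_loci.bed", "w") as fh:
        for locus in loci:
            score1000 = min(1000, int(round(locus.best_score.combined * 1000)))
            fh.write(
                f"{locus.interval.chrom}\t{locus.interval.start}\t{locus.interval.end}\t"
                f"{locus.gene_id}\t{score1000}\t+\n"
            )

    pres_rows = []
    region_counts: dict[str, int] = {}
    struct_counts: dict[str, int] = {}
    for sp in species:
        n_regions = 0
        for g in lnc_genes:
            row = gene_table.loc[gene_table["gene_id"] == g.id]
            if len(row) and bool(row.iloc[0][f"present_{sp}"]):
                n_regions += 1
        n_struct = 0
        for j, locus in enumerate(loci):
            if species_structure_presence(
                locus, store, sp, threshold=cfg.structure_threshold,
                seed=cfg.seed + 7919 * j, params=params, min_cov=cfg.min_cov,
            ):
                n_struct += 1
        region_counts[sp] = n_regions
        struct_counts[sp] = n_struct
        pres_rows.append({"species": sp, "n_regions": n_regions, "n_structures": n_struct})
    pd.DataFrame(pres_rows).to_csv(outdir / "species_counts.tsv", sep="\t", index=False)

    ancova = None
    if cfg.root_age_tsv and Path(cfg.root_age_tsv).exists() and len(species) >= 3:
        ages = pd.read_csv(cfg.root_age_tsv, sep="\t").set_index("species")["age_mya"]
        pts_r = [
            DivergencePoint(sp, float(ages[sp]), region_counts[sp])
            for sp in species if sp in ages.index
        ]
        pts_s = [
            DivergencePoint(sp, float(ages[sp]), struct_counts[sp])
            for sp in species if sp in ages.index
        ]
        if len(pts_r) >= 3:
            rep = divergence_regression(pts_r, pts_s)
            ancova = {
                "slope_regions": rep.regions.slope,
                "slope_structures": rep.structures.slope,
                "intercept_regions": rep.regions.intercept,
                "intercept_structures": rep.structures.intercept,
                "interaction_estimate": rep.interaction_estimate,
                "f_statistic": rep.f_statistic,
                "p_value": rep.p_value,
            }
    elif not cfg.root_age_tsv:
        logger.warning("no root-age table; divergence regression skipped")

    report = {
        "n_genes_tested": len(genes),
        "n_lncrna_genes": len(lnc_genes),
        "n_structure_loci": len(loci),
        "n_distinct_structured_genes": len({l.gene_id for l in loci}),
        "species_counts": pres_rows,
        "ancova": ancova,
    }
    _write_report(cfg, "conserve_structure", report)
    return report


def run_all(cfg: PipelineConfig) -> dict:
    discover = run_discover(cfg)
    classify = run_classify(cfg)
    conserve = run_conserve_structure(cfg)
    report = {"discover": discover, "classify": classify, "conserve_structure": conserve}
    _write_report(cfg, "all", report)
    return report
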