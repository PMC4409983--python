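# lnckit

Discovery and comparative conservation analysis of long non-coding RNAs
(lncRNAs) from dual-assembler transcript calls.

Given transcript models from two independent assemblers, a reference
annotation, a genome, a multi-species whole-genome alignment (MAF) and a
rooted species tree, `lnckit`:

1. **discovers** candidate loci — transcripts supported by both assemblers,
   assigned locus class codes (I = intronic, U = intergenic, X = antisense
   exonic overlap) and filtered at 200 nt, with complementary-strand
   duplicate detection;
2. **classifies** each candidate as CODING / LNCRNA / AMBIGUOUS from
   six-frame ORF structure and a phylogenetic coding-potential score — an
   MG94xHKY (codon) vs HKY85 (nucleotide) likelihood ratio in decibans,
   with the neutral model fitted on four-fold degenerate sites
   (CODING: ORF > 100 aa and score > +10; LNCRNA: max ORF < 50 aa,
   ORF < 35% of transcript, score < −10, no protein domain);
3. **compares conservation** across the species tree — per-species
   presence/absence of alignable regions, a per-gene rate-scaling
   likelihood-ratio test (Felsenstein pruning; one-sided 0.5·χ²₁ boundary
   null) with Mann–Whitney class comparisons, a sliding-window screen for
   conserved RNA secondary structures (fold-energy z-score + structure
   conservation index combined through a logistic score, high-confidence
   at > 0.5), and an ANCOVA comparing the divergence rates of conserved
   regions vs conserved structures.

A fully seeded `synthetic_data` module generates every input the pipeline
consumes (genome, assembler call sets, MAF evolved under neutral / purifying
codon / compensatory structured-RNA models, lineage-specific ablation) with
recorded ground truth, so the whole analysis is testable offline.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalences against brute-force enumeration, statistical calibration and
power checks, label-recovery and end-to-end smoke tests).

## CLI

```bash
# generate a synthetic study bundle with ground truth
lnckit simulate -o study/ --seed 1

# write a config pointing at the bundle (all thresholds have defaults)
cat > config.yaml <<EOF
genome: study/genome.fa
reference_gtf: study/reference.gtf
cufflinks_gtf: study/cufflinks.gtf
scripture_gtf: study/scripture.gtf
maf: study/alignment.maf
tree: study/tree.nwk
reference_species: ref
root_age_tsv: study/root_age.tsv
domains_tsv: study/domains.tsv
outdir: results
seed: 1
EOF

# run the stages (or `lnckit all` for everything)
lnckit discover -c config.yaml
lnckit classify -c config.yaml
lnckit conserve -c config.yaml
lnckit report -c config.yaml
```

Outputs land in `outdir/`: filtered candidate GTF, per-stage count table,
classification TSV, presence/absence matrix and per-class percentages,
per-gene conservation TSV with class comparison, BED of structure loci,
per-species retention counts, and JSON reports that embed the config hash,
seed and package version for provenance.

## Layout

```
src/lnckit/
  annotation_io/          GTF, MAF, FASTA, Newick readers + coordinate algebra
  transcript_discovery.py dual-assembler support, class codes, filters
  coding_potential/       ORF scan, HKY/MG94 models, pruning, classification
  conservation.py         presence/absence + rate-scaling conservation tests
  structure_conservation/ folding DP, z-score/SCI scoring, windows, ANCOVA
  synthetic_data/         seeded generators with ground truth
  pipeline_cli/           config, stage runners, click CLI
```
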