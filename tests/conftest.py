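"""Shared fixtures: tiny trees, in-memory MAF stores, and one session-scoped
synthetic study run end to end through the pipeline."""

from __future__ import annotations

import time

import numpy as np
import pytest

from lnckit.annotation_io import (
    GenomicInterval,
    MafBlock,
    MafStore,
    RegionAlignment,
    SpeciesTree,
)
from lnckit.pipeline_cli import PipelineConfig, run_all
from lnckit.synthetic_data import StudyConfig, generate_study, ladder_tree


@pytest.fixture(scope="session")
def tree8() -> SpeciesTree:
    return ladder_tree()


@pytest.fixture(scope="session")
def tree6() -> SpeciesTree:
    """Six-leaf ingroup ladder used by the calibration/power criteria."""
    return SpeciesTree.from_newick(
        "(((((ref:0.04,sA:0.04):0.05,sB:0.09):0.09,sC:0.18):0.18,sD:0.36):0.18,sE:0.54);"
    )


def make_region(rows: dict[str, str], ref: str = "ref", chrom: str = "c",
                start: int = 0) -> RegionAlignment:
    n = len(rows[ref])
    return RegionAlignment(
        reference_species=ref,
        interval=GenomicInterval(chrom, start, start + n),
        species=list(rows),
        rows=rows,
    )


def make_store(rows: dict[str, str], ref: str = "ref", chrom: str = "chr1",
               start: int = 0) -> MafStore:
    """Single-block in-memory MAF store from ungapped equal-length rows."""
    store = MafStore(ref)
    n = len(rows[ref].replace("-", ""))
    store.add_block(
        MafBlock(
            ref_chrom=chrom,
            ref_start=start,
            ref_end=start + n,
            rows={
                sp: (seq, start, len(seq.replace("-", "")), "+", 10_000_000)
                for sp, seq in rows.items()
            },
        )
    )
    store.finalize()
    return store


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("study")
    return generate_study(outdir, StudyConfig(), seed=7)


@pytest.fixture(scope="session")
def study_config(study, tmp_path_factory) -> PipelineConfig:
    return PipelineConfig(
        genome=str(study.genome_path),
        reference_gtf=str(study.reference_gtf),
        cufflinks_gtf=str(study.cufflinks_gtf),
        scripture_gtf=str(study.scripture_gtf),
        maf=str(study.maf_path),
        tree=str(study.tree_path),
        reference_species="ref",
        root_age_tsv=str(study.root_age_path),
        domains_tsv=str(study.domain_path),
        outdir=str(tmp_path_factory.mktemp("pipeline_out")),
        seed=7,
    )


@pytest.fixture(scope="session")
def pipeline_run(study_config):
    """One full `all` run; returns (report, wall-clock seconds)."""
    t0 = time.time()
    report = run_all(study_config)
    return report, time.time() - t0


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
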