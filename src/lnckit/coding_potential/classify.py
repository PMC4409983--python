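"""Coding / lncRNA / ambiguous classification from scored evidence."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

CODING = "CODING"
LNCRNA = "LNCRNA"
AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class ClassificationThresholds:
    """Defaults follow the printed inclusion/exclusion rules (strict
    inequalities: boundary cases fall to AMBIGUOUS)."""

    coding_min_peptide: int = 100      # aa, exclusive
    coding_min_score: float = 10.0     # decibans, exclusive
    lnc_max_peptide: int = 50          # aa, exclusive upper bound
    lnc_max_orf_fraction: float = 0.35  # exclusive
    lnc_max_score: float = -10.0       # decibans, exclusive upper bound


@dataclass
class Evidence:
    peptide_length: int
    orf_fraction: float
    score_decibans: float
    has_domain: bool = False


@dataclass
class ClassificationResult:
    label: str
    evidence: Evidence
    notes: list[str] = field(default_factory=list)


def classify_transcript(
    evidence: Evidence,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> ClassificationResult:
    """CODING iff long ORF and strongly positive score; LNCRNA iff short ORF,
    low ORF fraction, strongly negative score and no domain; else AMBIGUOUS."""
    t = thresholds
    if evidence.peptide_length > t.coding_min_peptide and \
            evidence.score_decibans > t.coding_min_score:
        return ClassificationResult(CODING, evidence)
    if (
        evidence.peptide_length < t.lnc_max_peptide
        and evidence.orf_fraction < t.lnc_max_orf_fraction
        and evidence.score_decibans < t.lnc_max_score
        and not evidence.has_domain
    ):
        return ClassificationResult(LNCRNA, evidence)
    return ClassificationResult(AMBIGUOUS, evidence)


def read_domain_table(path: str | Path, max_evalue: float = 1e-3) -> dict[str, bool]:
    """TSV with columns transcript_id, domain_id, e_value -> id -> has hit."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    hits: dict[str, bool] = {}
    for _, row in df.iterrows():
        if float(row["e_value"]) <= max_evalue:
            hits[str(row["transcript_id"])] = True
    return hits


def domain_lookup(transcript_id: str, domain_table: dict[str, bool] | None) -> bool:
    """True iff the table records at least one acceptable hit; absent -> False."""
    if domain_table is None:
        logger.warning("no domain table supplied; has_domain defaults to False")
        return False
    return bool(domain_table.get(transcript_id, False))
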