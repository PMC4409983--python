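"""Genus-wide presence/absence profiling and per-gene conservation tests.

Presence of a homologous region is operationalized as non-gap alignment
coverage of a gene's exonic positions.  Conservation is a per-gene
likelihood-ratio test of a rate multiplier r in (0, 1] against the neutral
model (r = 1), with the one-sided boundary mixture 0.5 * chi2(1) null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, mannwhitneyu, t as t_dist

from .annotation_io.intervals import Transcript
from .annotation_io.maf import MafStore, RegionAlignment, concatenate_regions, extract_region_alignment
from .annotation_io.trees import SpeciesTree
from .coding_potential.models import (
    NT_INDEX,
    SubstitutionModel,
    compress_columns,
    nucleotide_partials,
    site_log_likelihoods,
)
from .coding_potential.scoring import NeutralModel


@dataclass
class ConservationResult:
    gene_id: str
    rate_multiplier: float  # r-hat in (0, 1]
    statistic: float        # LRT statistic, >= 0
    p_value: float
    testable: bool = True

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p_value)


def exonic_alignment(gene: Transcript, store: MafStore,
                     species: list[str] | None = None) -> RegionAlignment:
    regions = [extract_region_alignment(store, e, species) for e in gene.exons]
    return concatenate_regions(regions)


def alignable_presence(
    gene: Transcript,
    store: MafStore,
    species: str,
    min_cov: float = 0.10,
) -> tuple[bool, float]:
    """Coverage = fraction of exonic reference positions where ``species``
    aligns a nucleotide; present iff coverage >= min_cov (inclusive)."""
    aln = exonic_alignment(gene, store)
    cov = aln.coverage(species)
    return cov >= min_cov, cov


def presence_matrix(
    genes: list[Transcript],
    store: MafStore,
    species_list: list[str],
    min_cov: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene presence flags and per-class per-species percentages.

    Returns (gene x species boolean/coverage table, class x species
    percentage table).  Empty classes yield missing percentages.
    """
    rows = []
    for gene in genes:
        aln = exonic_alignment(gene, store)
        rec: dict[str, object] = {"gene_id": gene.id, "class": gene.class_code}
        for sp in species_list:
            cov = aln.coverage(sp)
            rec[f"present_{sp}"] = cov >= min_cov
            rec[f"coverage_{sp}"] = cov
        rows.append(rec)
    gene_table = pd.DataFrame(rows)
    pct_rows = []
    for cls, grp in gene_table.groupby("class"):
        rec = {"class": cls, "n_genes": len(grp)}
        for sp in species_list:
            rec[f"pct_{sp}"] = 100.0 * grp[f"present_{sp}"].mean() if len(grp) else float("nan")
        pct_rows.append(rec)
    pct_table = pd.DataFrame(pct_rows)
    return gene_table, pct_table


def _pattern_partials(
    region_alignment: RegionAlignment, tree: SpeciesTree
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Unique-column partial likelihoods and their multiplicities."""
    rows = {
        sp: region_alignment.rows[sp]
        for sp in region_alignment.species
        if sp in tree.leaf_names
    }
    if not rows:
        raise ValueError("no alignment rows match tree leaves")
    sp_names = list(rows)
    row_list = [rows[sp] for sp in sp_names]
    columns = ["".join(r[i] for r in row_list) for i in range(region_alignment.n_columns)]
    usable = [c for c in columns if any(ch in NT_INDEX for ch in c)]
    if not usable:
        raise ValueError("zero usable columns")
    patterns, weights = compress_columns(usable)
    partials = {
        sp: nucleotide_partials("".join(p[i] for p in patterns))
        for i, sp in enumerate(sp_names)
    }
    return partials, weights


def felsenstein_likelihood(
    region_alignment: RegionAlignment,
    tree: SpeciesTree,
    model: SubstitutionModel,
    rate_scale: float,
) -> float:
    """Log-likelihood of the alignment with all branch lengths scaled."""
    partials, weights = _pattern_partials(region_alignment, tree)
    ll = site_log_likelihoods(tree, model, partials, rate_scale=rate_scale)
    return float(np.dot(ll, weights))


def conservation_test(
    gene: Transcript,
    store: MafStore,
    neutral_model: NeutralModel,
    species: list[str] | None = None,
    r_min: float = 1e-6,
    xatol: float = 1e-6,
) -> ConservationResult:
    """LRT of rate multiplier r in (0, 1] vs r = 1 over the gene's exonic
    columns; p = 0.5 * P(chi2_1 >= stat) for stat > 0 else 1."""
    aln = exonic_alignment(gene, store, species)
    ref = aln.reference_species
    informative = any(
        any(c in NT_INDEX for c in aln.rows[sp])
        for sp in aln.species
        if sp != ref
    )
    if not informative:
        return ConservationResult(gene.id, 1.0, 0.0, 1.0, testable=False)
    tree = neutral_model.tree
    model = neutral_model.model
    base = neutral_model.scale
    partials, weights = _pattern_partials(aln, tree)

    def neg_ll(r: float) -> float:
        ll = site_log_likelihoods(tree, model, partials, rate_scale=r * base)
        return -float(np.dot(ll, weights))

    ll0 = -neg_ll(1.0)
    res = minimize_scalar(neg_ll, bounds=(r_min, 1.0), method="bounded",
                          options={"xatol": xatol})
    r_hat = float(res.x)
    ll1 = -float(res.fun)
    if ll1 < ll0:
        r_hat, ll1 = 1.0, ll0
    stat = max(0.0, 2.0 * (ll1 - ll0))
    p = 0.5 * float(chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return ConservationResult(gene.id, r_hat, stat, p)


def mean_ci(values: list[float], level: float = 0.95) -> tuple[float, float, float]:
    """t-based mean and confidence interval."""
    arr = np.asarray(values, dtype=float)
    n = len(arr)
    m = float(arr.mean())
    if n < 2:
        return m, float("nan"), float("nan")
    half = float(t_dist.ppf(0.5 + level / 2, n - 1) * arr.std(ddof=1) / math.sqrt(n))
    return m, m - half, m + half


def class_conservation_compare(
    results_by_class: dict[str, list[ConservationResult]],
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests on -log10 p between classes,
    plus per-class mean and 95% CI."""
    classes = sorted(results_by_class)
    rows = []
    for cls in classes:
        vals = [r.neg_log10_p for r in results_by_class[cls] if r.testable]
        if vals:
            m, lo, hi = mean_ci(vals)
        else:
            m = lo = hi = float("nan")
        rows.append({"kind": "summary", "class_a": cls, "class_b": "", "n": len(vals),
                     "mean_neg_log10_p": m, "ci_low": lo, "ci_high": hi,
                     "statistic": float("nan"), "p_value": float("nan")})
    for i, ca in enumerate(classes):
        for cb in classes[i + 1 :]:
            va = [r.neg_log10_p for r in results_by_class[ca] if r.testable]
            vb = [r.neg_log10_p for r in results_by_class[cb] if r.testable]
            if len(va) < 2 or len(vb) < 2:
                rows.append({"kind": "test", "class_a": ca, "class_b": cb,
                             "n": len(va) + len(vb), "mean_neg_log10_p": float("nan"),
                             "ci_low": float("nan"), "ci_high": float("nan"),
                             "statistic": float("nan"), "p_value": float("nan")})
                continue
            stat, p = mannwhitneyu(va, vb, alternative="two-sided", method="asymptotic")
            rows.append({"kind": "test", "class_a": ca, "class_b": cb,
                         "n": len(va) + len(vb), "mean_neg_log10_p": float("nan"),
                         "ci_low": float("nan"), "ci_high": float("nan"),
                         "statistic": float(stat), "p_value": float(p)})
    return pd.DataFrame(rows)
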