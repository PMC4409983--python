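import itertools
import math

import numpy as np
import pytest

from lnckit.annotation_io import GenomicInterval, SpeciesTree, Transcript, reverse_complement
from lnckit.coding_potential import (
    AMBIGUOUS,
    CODING,
    ClassificationThresholds,
    CodingModel,
    Evidence,
    LNCRNA,
    SENSE_CODONS,
    classify_transcript,
    codon_partials,
    coding_score,
    domain_lookup,
    fit_neutral_model,
    hky_model,
    max_peptide_length,
    mg94_model,
    nucleotide_partials,
    orf_fraction,
    scan_orfs,
    score_per_exon,
    score_per_gene,
    site_log_likelihoods,
)
from lnckit.coding_potential.scoring import NeutralModel
from lnckit.synthetic_data import CodingSpec, simulate_coding

from .conftest import make_region, make_store


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

STOPS = {"TAA", "TAG", "TGA"}


def orf_oracle(seq):
    """Brute-force 6-frame scan: returns {(frame, start, end)} of maximal
    ATG-to-stop ORFs (stop included)."""
    out = set()
    rc = reverse_complement(seq)
    for frame in range(6):
        s = seq if frame < 3 else rc
        off = frame % 3
        codons = [s[i : i + 3] for i in range(off, len(s) - 2, 3)]
        last_stop = -1
        for idx, codon in enumerate(codons):
            if codon in STOPS:
                # find first ATG after previous stop
                for j in range(last_stop + 1, idx):
                    if codons[j] == "ATG":
                        out.add((frame, off + 3 * j, off + 3 * idx + 3))
                        break
                last_stop = idx
    return out


def enumeration_loglik(tree, model, leaf_states):
    """Likelihood of ONE site by explicit summation over all ancestral state
    assignments (independent of the pruning implementation)."""
    S = model.n_states
    internals = [n for n in tree.nodes if not n.is_leaf]
    P = {
        n.index: model.transition_matrix(n.branch_length)
        for n in tree.nodes
        if n.index != tree.root
    }
    parent = {}
    for n in tree.nodes:
        for c in n.children:
            parent[c] = n.index
    total = 0.0
    for assign in itertools.product(range(S), repeat=len(internals)):
        states = {n.index: a for n, a in zip(internals, assign)}
        states.update({tree.leaf_index(sp): st for sp, st in leaf_states.items()})
        prob = model.pi[states[tree.root]]
        for n in tree.nodes:
            if n.index == tree.root:
                continue
            prob *= P[n.index][states[parent[n.index]], states[n.index]]
        total += prob
    return math.log(total)


def random_tree(rng, n_leaves):
    """Random caterpillar topology with uniform branch lengths."""
    names = [f"L{i}" for i in range(n_leaves)]
    cur = (
        f"({names[0]}:{rng.uniform(0.05, 0.5):.3f},"
        f"{names[1]}:{rng.uniform(0.05, 0.5):.3f})"
    )
    for name in names[2:]:
        cur = (
            f"({cur}:{rng.uniform(0.05, 0.3):.3f},"
            f"{name}:{rng.uniform(0.05, 0.5):.3f})"
        )
    return SpeciesTree.from_newick(cur + ";")


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


class TestModels:
    def test_hky_generator_properties(self, rng):
        pi = np.array([0.1, 0.2, 0.3, 0.4])
        m = hky_model(pi, 3.0)
        assert np.allclose(m.Q.sum(axis=1), 0, atol=1e-12)
        assert np.allclose(m.pi @ m.Q, 0, atol=1e-12)  # stationarity
        assert -np.dot(m.pi, np.diag(m.Q)) == pytest.approx(1.0)

    def test_mg94_generator_properties(self):
        m = mg94_model(np.array([0.2, 0.3, 0.3, 0.2]), 2.0, 0.3)
        assert m.n_states == 61
        assert np.allclose(m.Q.sum(axis=1), 0, atol=1e-10)
        assert np.all(m.pi > 0)
        # detailed balance (reversibility)
        F = m.pi[:, None] * m.Q
        assert np.allclose(F, F.T, atol=1e-12)

    def test_transition_matrix_is_stochastic(self):
        m = hky_model([0.25] * 4, 2.0)
        for t in (0.0, 0.1, 2.0):
            P = m.transition_matrix(t)
            assert np.allclose(P.sum(axis=1), 1, atol=1e-10)
            assert np.all(P >= 0)
        assert np.allclose(m.transition_matrix(0.0), np.eye(4), atol=1e-10)

    def test_chapman_kolmogorov(self):
        m = mg94_model([0.25] * 4, 2.0, 0.5)
        P1 = m.transition_matrix(0.3)
        P2 = m.transition_matrix(0.5)
        assert np.allclose(P1 @ P2, m.transition_matrix(0.8), atol=1e-10)

    def test_pruning_equals_enumeration_nucleotide(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 6))
            tree = random_tree(rng, n)
            m = hky_model(rng.dirichlet([5] * 4), float(rng.uniform(0.5, 4)))
            states = {name: int(rng.integers(4)) for name in tree.leaf_names}
            partials = {
                sp: nucleotide_partials("ACGT"[s]) for sp, s in states.items()
            }
            got = site_log_likelihoods(tree, m, partials)[0]
            want = enumeration_loglik(tree, m, states)
            assert got == pytest.approx(want, abs=1e-8)

    def test_pruning_equals_enumeration_codon(self, rng):
        for _ in range(3):
            tree = random_tree(rng, 3)
            m = mg94_model(rng.dirichlet([5] * 4), 2.0, 0.4)
            states = {name: int(rng.integers(61)) for name in tree.leaf_names}
            partials = {sp: codon_partials(SENSE_CODONS[s]) for sp, s in states.items()}
            got = site_log_likelihoods(tree, m, partials)[0]
            want = enumeration_loglik(tree, m, states)
            assert got == pytest.approx(want, abs=1e-8)

    def test_leaf_order_invariance(self, rng):
        tree = random_tree(rng, 4)
        m = hky_model([0.25] * 4, 2.0)
        partials = {sp: nucleotide_partials("ACGT"[i % 4]) for i, sp in enumerate(tree.leaf_names)}
        ll1 = site_log_likelihoods(tree, m, partials)
        shuffled = dict(reversed(list(partials.items())))
        ll2 = site_log_likelihoods(tree, m, shuffled)
        assert ll1[0] == pytest.approx(ll2[0])

    def test_missing_leaf_marginalizes(self, rng):
        """An all-ones partial equals summing that leaf out."""
        tree = random_tree(rng, 3)
        m = hky_model([0.1, 0.4, 0.2, 0.3], 3.0)
        names = tree.leaf_names
        fixed = {names[0]: "A", names[1]: "G"}
        partials = {sp: nucleotide_partials(s) for sp, s in fixed.items()}
        partials[names[2]] = np.ones((1, 4))
        got = site_log_likelihoods(tree, m, partials)[0]
        total = 0.0
        for s in "ACGT":
            all_partials = {sp: nucleotide_partials(x) for sp, x in {**fixed, names[2]: s}.items()}
            total += math.exp(site_log_likelihoods(tree, m, all_partials)[0])
        assert got == pytest.approx(math.log(total), abs=1e-10)


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------


class TestOrfScan:
    def test_simple_orf(self):
        orfs = [o for o in scan_orfs("ATGGCCTAA") if o.requires_start]
        assert len(orfs) == 1
        assert orfs[0].peptide_length == 2
        assert orfs[0].frame == 0

    def test_no_atg(self):
        assert [o for o in scan_orfs("CCCCCCCCC") if o.requires_start] == []

    def test_reverse_strand_symmetry(self):
        seq = reverse_complement("ATGGCCTAA")
        orfs = [o for o in scan_orfs(seq) if o.requires_start]
        assert len(orfs) == 1
        assert orfs[0].frame >= 3
        assert orfs[0].peptide_length == 2

    def test_n_does_not_terminate(self):
        orfs = [o for o in scan_orfs("ATGNNNGCCTAA") if o.requires_start]
        assert len(orfs) == 1
        assert orfs[0].peptide_length == 3

    def test_empty_sequence(self):
        assert scan_orfs("") == []

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 200))
            seq = "".join(rng.choice(list("ACGT"), n))
            got = {
                (o.frame, o.start, o.end)
                for o in scan_orfs(seq)
                if o.requires_start and o.has_stop
            }
            assert got == orf_oracle(seq)

    def test_orf_fraction(self):
        orfs = [o for o in scan_orfs("ATGGCCTAA") if o.requires_start]
        assert orf_fraction(orfs[0], 9) == pytest.approx(1.0)
        assert orf_fraction(None, 300) == 0.0
        # 105-nt ORF on a 300-nt transcript
        seq = "ATG" + "GCC" * 33 + "TAA"
        orfs = [o for o in scan_orfs(seq) if o.requires_start and o.frame == 0]
        assert orf_fraction(orfs[0], 300) == pytest.approx(0.35)

    def test_max_peptide(self):
        assert max_peptide_length(scan_orfs("ATGGCCGCCTAA")) == 3
        assert max_peptide_length(scan_orfs("CCC")) == 0


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


class TestClassify:
    def test_paper_threshold_examples(self):
        assert classify_transcript(Evidence(120, 0.9, 15.0)).label == CODING
        assert classify_transcript(Evidence(30, 0.20, -12.0)).label == LNCRNA
        assert classify_transcript(Evidence(70, 0.5, 0.0)).label == AMBIGUOUS

    def test_boundaries_fall_to_ambiguous(self):
        assert classify_transcript(Evidence(100, 0.9, 50.0)).label == AMBIGUOUS
        assert classify_transcript(Evidence(50, 0.1, -50.0)).label == AMBIGUOUS
        assert classify_transcript(Evidence(30, 0.35, -50.0)).label == AMBIGUOUS
        assert classify_transcript(Evidence(101, 0.9, 10.0)).label == AMBIGUOUS

    def test_domain_veto(self):
        assert classify_transcript(Evidence(30, 0.2, -20.0, has_domain=True)).label == AMBIGUOUS

    def test_domain_lookup(self):
        table = {"x": True}
        assert domain_lookup("x", table) is True
        assert domain_lookup("y", table) is False
        assert domain_lookup("x", {}) is False
        assert domain_lookup("x", None) is False


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _neutral(tree, scale=1.0, kappa=2.5):
    return NeutralModel(pi=np.full(4, 0.25), kappa=kappa, scale=scale, tree=tree)


class TestCodingScore:
    def test_per_codon_sums_to_total(self, tree6, rng):
        rows = simulate_coding(tree6, CodingSpec(omega=0.2), 30, rng)
        aln = make_region(rows)
        nm = _neutral(tree6)
        s = coding_score(aln, 0, nm, CodingModel(nm, 0.2))
        assert s.per_codon.sum() == pytest.approx(s.total_decibans, abs=1e-6)
        assert s.n_codons == 30

    def test_antisymmetry_in_model_swap(self, tree6, rng):
        """10*log10(La/Lb) must negate when the two likelihoods swap roles."""
        rows = simulate_coding(tree6, CodingSpec(omega=0.2), 20, rng)
        nm = _neutral(tree6)
        cm = CodingModel(nm, 0.2)
        parts_c = {sp: codon_partials(s) for sp, s in rows.items()}
        parts_n = {sp: nucleotide_partials(s) for sp, s in rows.items()}
        ll_c = site_log_likelihoods(tree6, cm.model, parts_c, nm.scale).sum()
        ll_n = site_log_likelihoods(tree6, nm.model, parts_n, nm.scale).sum()
        db = 10 / math.log(10) * (ll_c - ll_n)
        db_swapped = 10 / math.log(10) * (ll_n - ll_c)
        assert db_swapped == pytest.approx(-db)
        s = coding_score(make_region(rows), 0, nm, cm)
        assert s.total_decibans == pytest.approx(db, abs=1e-6)

    def test_reference_only_alignment_scores_zero(self, tree6):
        aln = make_region({"ref": "ATGGCCGCC", "sA": "---------"})
        nm = _neutral(tree6)
        s = coding_score(aln, 0, nm, CodingModel(nm))
        assert s.total_decibans == 0.0
        assert "no informative species" in s.warnings

    def test_reference_stop_codons_contribute_zero(self, tree6):
        aln = make_region({"ref": "TAAGCC", "sA": "TAAGCC"})
        nm = _neutral(tree6)
        s = coding_score(aln, 0, nm, CodingModel(nm))
        assert s.per_codon[0] == 0.0
        assert s.per_codon[1] != 0.0

    def test_coding_positive_neutral_negative(self, tree6, rng):
        from lnckit.synthetic_data import NeutralSpec, simulate_neutral

        nm = _neutral(tree6)
        cm = CodingModel(nm, 0.2)
        rows_c = simulate_coding(tree6, CodingSpec(omega=0.1), 100, rng)
        assert coding_score(make_region(rows_c), 0, nm, cm).total_decibans > 0
        rows_n = simulate_neutral(tree6, NeutralSpec(), 300, rng)
        assert coding_score(make_region(rows_n), 0, nm, cm).total_decibans < 0


class TestScanningModes:
    def _setup(self, tree6, rng, n_codons=60):
        rows = simulate_coding(tree6, CodingSpec(omega=0.1), n_codons, rng)
        rows = {sp: "ATG" + s + "TAA" for sp, s in rows.items()}
        store = make_store(rows)
        n = len(rows["ref"])
        t = Transcript("t", [GenomicInterval("chr1", 0, n, "+")])
        nm = _neutral(tree6)
        return rows, store, t, nm, CodingModel(nm, 0.2)

    def test_per_exon_single_exon_reduction(self, tree6, rng):
        rows, store, t, nm, cm = self._setup(tree6, rng)
        from lnckit.annotation_io import extract_region_alignment

        (exon, best) = score_per_exon(t, store, nm, cm)[0]
        aln = extract_region_alignment(store, t.exons[0])
        expected = max(
            coding_score(aln, f, nm, cm).total_decibans for f in range(6)
        )
        assert best.total_decibans == pytest.approx(expected)

    def test_short_exon_flagged(self, tree6, rng):
        rows, store, _t, nm, cm = self._setup(tree6, rng)
        t = Transcript("s", [GenomicInterval("chr1", 0, 2, "+")])
        (_exon, score) = score_per_exon(t, store, nm, cm)[0]
        assert score.total_decibans == 0.0
        assert score.warnings

    def test_per_gene_finds_planted_orf(self, tree6, rng):
        rows, store, t, nm, cm = self._setup(tree6, rng)
        orf, score = score_per_gene(t, store, nm, cm)
        assert orf is not None and orf.requires_start
        assert orf.frame == 0 and orf.start == 0
        assert score.total_decibans > 10

    def test_minus_strand_mirror_symmetry(self, tree6, rng):
        rows, store, t, nm, cm = self._setup(tree6, rng, n_codons=40)
        n = len(rows["ref"])
        orf_p, score_p = score_per_gene(t, store, nm, cm)
        rc_rows = {sp: reverse_complement(s) for sp, s in rows.items()}
        store_rc = make_store(rc_rows)
        t_m = Transcript("tm", [GenomicInterval("chr1", 0, n, "-")])
        orf_m, score_m = score_per_gene(t_m, store_rc, nm, cm)
        assert score_m.total_decibans == pytest.approx(score_p.total_decibans, abs=1e-6)

    def test_per_codon_profiles_all_frames(self, tree6, rng):
        from lnckit.coding_potential import score_per_codon

        rows, store, t, nm, cm = self._setup(tree6, rng, n_codons=20)
        profiles = score_per_codon(t, store, nm, cm, flank=50, chrom_length=len(rows["ref"]))
        assert set(profiles) == set(range(6))
        for s in profiles.values():
            assert s.per_codon.sum() == pytest.approx(s.total_decibans, abs=1e-6)


class TestNeutralFit:
    def _fit(self, tree, kappa, rng, n_codons=2500, scale=1.0):
        spec = CodingSpec(omega=0.5, kappa=kappa, scale=scale)
        rows = simulate_coding(tree, spec, n_codons, rng)
        store = make_store(rows)
        n = len(rows["ref"])
        t = Transcript(
            "cds1",
            [GenomicInterval("chr1", 0, n, "+")],
            attributes={"gene_id": "cds1", "cds": [(0, n, 0)]},
        )
        return fit_neutral_model(store, [t], tree)

    def test_kappa_recovery(self, tree6, rng):
        nm = self._fit(tree6, kappa=4.0, rng=rng)
        assert 3.3 <= nm.kappa <= 4.7
        assert 0.7 <= nm.scale <= 1.3
        assert nm.n_sites >= 100

    def test_scale_halves_when_branches_double(self, tree6, rng):
        """Same data, branch lengths doubled -> fitted scale halves (the
        likelihood depends only on the product scale x branch length)."""
        rows = simulate_coding(tree6, CodingSpec(omega=0.5, kappa=2.5), 2000, rng)
        store = make_store(rows)
        n = len(rows["ref"])
        t = Transcript(
            "cds1",
            [GenomicInterval("chr1", 0, n, "+")],
            attributes={"gene_id": "cds1", "cds": [(0, n, 0)]},
        )
        nm1 = fit_neutral_model(store, [t], tree6)
        nm2 = fit_neutral_model(store, [t], tree6.scaled(2.0))
        assert nm2.scale * 2 == pytest.approx(nm1.scale, rel=0.02)

    def test_identical_rows_drive_scale_to_floor(self, tree6, rng):
        codons = "".join(
            SENSE_CODONS[i] for i in rng.integers(0, 61, 600)
        )
        rows = {sp: codons for sp in tree6.leaf_names}
        store = make_store(rows)
        t = Transcript(
            "cds1",
            [GenomicInterval("chr1", 0, len(codons), "+")],
            attributes={"gene_id": "cds1", "cds": [(0, len(codons), 0)]},
        )
        nm = fit_neutral_model(store, [t], tree6)
        assert nm.scale <= 1e-3

    def test_too_few_columns_error(self, tree6):
        rows = {sp: "GGA" * 10 for sp in tree6.leaf_names}
        store = make_store(rows)
        t = Transcript(
            "cds1",
            [GenomicInterval("chr1", 0, 30, "+")],
            attributes={"gene_id": "cds1", "cds": [(0, 30, 0)]},
        )
        from lnckit.coding_potential import NeutralFitError

        with pytest.raises(NeutralFitError, match="columns"):
            fit_neutral_model(store, [t], tree6)
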