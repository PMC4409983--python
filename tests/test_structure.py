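import numpy as np
import pytest

from lnckit.annotation_io import GenomicInterval, Transcript
from lnckit.structure_conservation import (
    DivergencePoint,
    StructureScoreParams,
    calibrate_score_weights,
    combined_score,
    consensus_fold,
    divergence_regression,
    drop_allgap_columns,
    fold,
    mfe_zscore,
    sci,
    scan_windows,
    species_structure_presence,
    structure_score,
)
from lnckit.structure_conservation.fold import PAIR_SCORES, SecondaryStructure
from lnckit.synthetic_data import (
    NeutralSpec,
    StructuredSpec,
    hairpin_pairs,
    simulate_alignment,
)

from .conftest import make_region, make_store


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle for nested structures
# ---------------------------------------------------------------------------

def _pair_score(a, b):
    return PAIR_SCORES.get((a.replace("T", "U"), b.replace("T", "U")), 0.0)


def enumerate_best_score(seq, min_loop=3):
    """Max pair-score sum over ALL nested structures, by brute recursion."""
    seq = seq.upper().replace("T", "U")

    def best(i, j):
        if j - i <= min_loop:
            return 0.0
        # position i unpaired, or paired with some k
        result = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            s = _pair_score(seq[i], seq[k])
            if s > 0:
                result = max(result, s + best(i + 1, k - 1) + best(k + 1, j))
        return result

    return best(0, len(seq) - 1)


class TestFold:
    def test_unpairable(self):
        st = fold("AAAAAA")
        assert st.n_pairs == 0 and st.energy == 0.0

    def test_minimal_hairpin(self):
        st = fold("GAAAC")
        assert st.pairs == [(0, 4)]
        assert st.energy == -3.0

    def test_three_pair_hairpin(self):
        st = fold("GCGAAACGC")
        assert st.pairs == [(0, 8), (1, 7), (2, 6)]
        # all three pairs are G-C: enumeration oracle confirms the score
        assert -st.energy == enumerate_best_score("GCGAAACGC")
        assert st.energy == -9.0

    def test_loop_constraint(self):
        # pair would need j - i > 3
        assert fold("GAAC").n_pairs == 0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(5, 15))
            seq = "".join(rng.choice(list("ACGU"), n))
            st = fold(seq)
            assert -st.energy == pytest.approx(enumerate_best_score(seq))

    def test_structure_is_valid_nested(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), 30))
            st = fold(seq)
            seen = set()
            for i, j in st.pairs:
                assert j - i > 3
                assert _pair_score(seq[i], seq[j]) > 0
                assert i not in seen and j not in seen
                seen.update((i, j))
            # nestedness: no crossing pairs
            for a, b in st.pairs:
                for c, d in st.pairs:
                    assert not (a < c < b < d)

    def test_energy_equals_pair_sum(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGU"), 25))
            st = fold(seq)
            assert -st.energy == pytest.approx(
                sum(_pair_score(seq[i], seq[j]) for i, j in st.pairs)
            )

    def test_deterministic(self):
        seq = "GCAUGCAUGCAUGCAUGGCC"
        assert fold(seq).pairs == fold(seq).pairs


class TestConsensusFold:
    def test_identical_rows_equal_single_fold(self):
        row = "GCGAAACGCAAA"
        st_single = fold(row)
        st_cons, energy = consensus_fold([row, row, row])
        assert st_cons.pairs == st_single.pairs
        assert energy == pytest.approx(st_single.energy)

    def test_compensatory_pair_retained_with_bonus(self):
        r1, r2 = "GCGAAACGC", "GAGAAACUC"
        st, energy = consensus_fold([r1, r2])
        assert (1, 7) in st.pairs
        # column pair (1,7): mean(3, 2) = 2.5 plus covariation bonus 1.0
        from lnckit.structure_conservation import consensus_score_matrix

        s = consensus_score_matrix([r1, r2])
        assert s[1, 7] == pytest.approx(3.5)

    def test_single_row_fallback_flagged(self):
        st, _ = consensus_fold(["GCGAAACGC"])
        assert st.single_row_fallback

    def test_allgap_columns_dropped(self):
        rows = drop_allgap_columns(["A--C", "G--C"])
        assert rows == ["AC", "GC"]


class TestZScore:
    def test_homopolymer_zero(self):
        assert mfe_zscore("AAAAAAAAAAAAAA", n_shuffles=30, seed=1) == 0.0

    def test_strong_hairpin_negative(self):
        z = mfe_zscore("GGGGGAAAACCCCC", n_shuffles=100, seed=42)
        assert z < -1

    def test_seed_stability(self):
        seq = "GGGCCAUAGCAUGGCCC"
        z1 = mfe_zscore(seq, n_shuffles=1000, seed=1)
        z2 = mfe_zscore(seq, n_shuffles=1000, seed=2)
        assert abs(z1 - z2) < 0.5

    def test_min_shuffles_enforced(self):
        with pytest.raises(ValueError):
            mfe_zscore("GGGAAACCC", n_shuffles=10, seed=1)

    def test_dinucleotide_shuffle_preserves_counts(self, rng):
        from lnckit.structure_conservation.scores import _dinucleotide_shuffle

        seq = "".join(rng.choice(list("ACGU"), 60))
        shuf = _dinucleotide_shuffle(seq, rng)
        def dinucs(s):
            out = {}
            for a, b in zip(s, s[1:]):
                out[a + b] = out.get(a + b, 0) + 1
            return out
        assert dinucs(shuf) == dinucs(seq)


class TestSci:
    def test_identical_rows_unity(self):
        rows = ["GCGAAACGCAAA"] * 3
        assert sci(rows) == pytest.approx(1.0)

    def test_unpairable_rows_zero(self):
        assert sci(["AAAAAAAA", "AAAAAAAA"]) == 0.0

    def test_unrelated_rows_low(self, rng):
        base = "".join(rng.choice(list("ACGU"), 60))
        rows = [base, "".join(rng.permutation(list(base))),
                "".join(rng.permutation(list(base)))]
        assert sci(rows) < sci([base] * 3)


class TestStructureScore:
    def test_logistic_formula(self):
        assert combined_score(0.0, 0.0) == pytest.approx(1 / (1 + np.exp(4)), abs=1e-9)
        assert combined_score(0.0, 0.0) < 0.5

    def test_monotonicity(self):
        base = combined_score(-1.0, 0.8)
        assert combined_score(-2.0, 0.8) > base       # more negative z
        assert combined_score(-1.0, 1.2) > base       # higher sci

    def test_degenerate_window_scores_zero(self, tree6):
        aln = make_region({"ref": "N" * 50, "sA": "-" * 50})
        score = structure_score(aln, StructureScoreParams(n_shuffles=30), seed=1)
        assert score.combined == 0.0

    def test_conserved_hairpins_beat_shuffles(self, tree6):
        rng = np.random.default_rng(5)
        params = StructureScoreParams(n_shuffles=30, max_z_rows=4)
        spec = StructuredSpec(
            pairs=tuple(p for off in (0, 30, 60) for p in hairpin_pairs(off)),
            decay_rate=0.0, pair_sub_rate=1.5,
        )
        hit, ctrl = [], []
        for i in range(10):
            rows, _ = simulate_alignment(tree6, spec, 90, rng=rng)
            pad = simulate_alignment(tree6, NeutralSpec(), 30, rng=rng)
            rows = {sp: rows[sp] + pad[sp] for sp in rows}
            hit.append(structure_score(make_region(rows), params, seed=i).combined)
            n = simulate_alignment(tree6, NeutralSpec(), 120, rng=rng)
            shuffled = {sp: "".join(rng.permutation(list(v))) for sp, v in n.items()}
            ctrl.append(structure_score(make_region(shuffled), params, seed=100 + i).combined)
        assert np.mean(hit) - np.mean(ctrl) >= 0.3

    def test_calibration_separates_training_data(self, rng):
        pos = np.column_stack([rng.normal(2.0, 0.5, 60), rng.normal(1.0, 0.05, 60)])
        neg = np.column_stack([rng.normal(0.0, 0.5, 60), rng.normal(0.7, 0.05, 60)])
        X = np.vstack([pos, neg])
        y = np.array([1] * 60 + [0] * 60)
        w = calibrate_score_weights(X, y)
        pred = 1 / (1 + np.exp(-(w[0] + X @ np.array(w[1:]))))
        acc = np.mean((pred > 0.5) == y)
        assert acc >= 0.9


class TestScanWindows:
    def test_no_confident_windows(self, tree6, rng):
        rows = simulate_alignment(tree6, NeutralSpec(), 300, rng=rng)
        store = make_store(rows)
        gene = Transcript("g", [GenomicInterval("chr1", 0, 300, "+")])
        loci = scan_windows(gene, store, params=StructureScoreParams(n_shuffles=30, max_z_rows=4), seed=3)
        assert loci == []

    def test_merged_loci_do_not_overlap(self, tree6):
        rng = np.random.default_rng(8)
        spec = StructuredSpec(
            pairs=tuple(p for off in (0, 30, 60) for p in hairpin_pairs(off)),
            decay_rate=0.0, pair_sub_rate=1.5,
        )
        pieces = []
        for _ in range(3):
            s, _ = simulate_alignment(tree6, spec, 90, rng=rng)
            n = simulate_alignment(tree6, NeutralSpec(), 70, rng=rng)
            pieces.append({sp: s[sp] + n[sp] for sp in s})
        rows = {sp: "".join(p[sp] for p in pieces) for sp in pieces[0]}
        store = make_store(rows)
        gene = Transcript("g", [GenomicInterval("chr1", 0, len(rows["ref"]), "+")])
        loci = scan_windows(gene, store, params=StructureScoreParams(n_shuffles=30, max_z_rows=4), seed=4)
        assert loci, "expected at least one locus"
        for a, b in zip(loci, loci[1:]):
            assert a.interval.end <= b.interval.start
        for l in loci:
            assert l.best_score.combined > 0.5
            assert gene.span.contains(l.interval)

    def test_short_gene_flagged(self, tree6, rng):
        rows = simulate_alignment(tree6, NeutralSpec(), 60, rng=rng)
        store = make_store(rows)
        gene = Transcript("g", [GenomicInterval("chr1", 0, 60, "+")])
        loci = scan_windows(gene, store, params=StructureScoreParams(n_shuffles=30), seed=3)
        assert loci == [] or "gene_shorter_than_window" in loci[0].flagged


class TestSpeciesStructurePresence:
    def _confident_locus(self, tree6, rng):
        spec = StructuredSpec(
            pairs=tuple(p for off in (0, 30, 60) for p in hairpin_pairs(off)),
            decay_rate=0.0, pair_sub_rate=1.5,
        )
        s, _ = simulate_alignment(tree6, spec, 90, rng=rng)
        pad = simulate_alignment(tree6, NeutralSpec(), 30, rng=rng)
        rows = {sp: s[sp] + pad[sp] for sp in s}
        store = make_store(rows)
        gene = Transcript("g", [GenomicInterval("chr1", 0, 120, "+")])
        loci = scan_windows(gene, store, params=StructureScoreParams(n_shuffles=30, max_z_rows=4), seed=5)
        return store, loci

    def test_retained_species_present_and_unalignable_absent(self, tree6):
        rng = np.random.default_rng(12)
        store, loci = self._confident_locus(tree6, rng)
        assert loci
        locus = loci[0]
        params = StructureScoreParams(n_shuffles=30)
        assert species_structure_presence(locus, store, "sA", seed=1, params=params)
        assert not species_structure_presence(locus, store, "missing_sp", seed=1, params=params)


class TestDivergenceRegression:
    @staticmethod
    def _points(slope, intercept, noise, rng, n=10):
        ages = np.linspace(1, 50, n)
        return [
            DivergencePoint(f"s{i}", float(a), max(0, int(round(intercept + slope * a + rng.normal(0, noise)))))
            for i, a in enumerate(ages)
        ]

    def test_same_line_gives_p_one(self, rng):
        pts = [DivergencePoint(f"s{i}", float(a), int(100 - 2 * a)) for i, a in enumerate(range(1, 9))]
        rep = divergence_regression(pts, pts)
        assert rep.p_value == pytest.approx(1.0)
        assert abs(rep.interaction_estimate) < 1e-8

    def test_exact_slope(self):
        pts = [DivergencePoint(f"s{i}", float(a), int(2 * a)) for i, a in enumerate(range(1, 8))]
        rep = divergence_regression(pts, [DivergencePoint(f"t{i}", float(a), int(a)) for i, a in enumerate(range(1, 8))])
        assert rep.regions.slope == pytest.approx(2.0, abs=1e-8)
        assert rep.structures.slope == pytest.approx(1.0, abs=1e-8)

    def test_different_slopes_detected(self):
        rng = np.random.default_rng(3)
        a = self._points(-1.0, 80, 2.0, rng, n=20)
        b = self._points(-2.0, 80, 2.0, rng, n=20)
        rep = divergence_regression(a, b)
        assert rep.p_value < 0.01

    def test_too_few_points(self):
        pts = [DivergencePoint("a", 1.0, 5), DivergencePoint("b", 2.0, 4)]
        with pytest.raises(ValueError):
            divergence_regression(pts, pts)

    def test_degenerate_ages(self):
        pts = [DivergencePoint(f"s{i}", 5.0, 5) for i in range(4)]
        with pytest.raises(ValueError, match="degenerate"):
            divergence_regression(pts, pts)
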