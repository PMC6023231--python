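import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flscan as fl
from flscan.search import ENGINES

from conftest import exact_match_matrix, random_scoring_matrix


def hit_set(hits):
    return {(h.position, h.score) for h in hits}


class TestFailureExpectations:
    def test_gata3_column1_hand_arithmetic(self, gata3):
        M, bg = gata3
        E = fl.failure_expectations(M, bg)
        # |min| + max - E_bg[score] = 1.06 + 0.17 - (-0.109)
        assert E[0] == pytest.approx(1.339, abs=1e-3)

    def test_gata3_column2_dominates_column1(self, gata3):
        M, bg = gata3
        E = fl.failure_expectations(M, bg)
        assert E[1] == pytest.approx(8.153, abs=1e-3)
        assert E[1] > E[0]

    def test_constant_nonnegative_column(self, uniform_bg):
        c = 0.7
        M = fl.ScoringMatrix(np.full((1, 4), c))
        E = fl.failure_expectations(M, uniform_bg)
        assert E[0] == pytest.approx(c)


class TestMatchingOrder:
    def test_sorts_by_decreasing_expectation(self):
        assert fl.matching_order([1.3, 8.1, 2.0]) == (2, 3, 1)

    def test_ties_keep_original_order(self):
        assert fl.matching_order([1.0, 1.0, 1.0]) == (1, 2, 3)

    def test_increasing_input_reverses(self):
        assert fl.matching_order([1.0, 2.0, 3.0, 4.0]) == (4, 3, 2, 1)


class TestBuildTables:
    def test_gata3_identity_suffix_maxima(self, gata3):
        M, _ = gata3
        tables = fl.build_tables(M, k=0)
        # grid units: sums of printed per-column maxima 0.17+1.64+1.03+1.18+0.58+1.12
        assert tables.suffix_max[0] == 5720
        assert tables.suffix_max[5] == 1120
        assert tables.suffix_max[6] == 0
        assert tables.thresholds[6] == 0  # == k

    def test_width_one(self, uniform_bg):
        M = fl.ScoringMatrix(np.array([[1.0, -1.0, 0.0, 0.5]]))
        tables = fl.build_tables(M, k=700)
        np.testing.assert_array_equal(tables.thresholds, [700 - 1000, 700])

    def test_threshold_at_global_max_requires_consensus(self, uniform_bg):
        rng = np.random.default_rng(3)
        M = random_scoring_matrix(rng, 8)
        k = int(M.int_scores.max(axis=1).sum())
        seq = fl.random_sequence(fl.GeneratorSpec(seed=5, length=5000))
        hits, _ = fl.lookahead_search(seq, M, k)
        consensus_codes = M.int_scores.argmax(axis=1)
        for h in hits:
            window = seq[h.position - 1 : h.position - 1 + 8]
            assert all(
                fl.ALPHABET.index(s) == c for s, c in zip(window, consensus_codes)
            )

    def test_invalid_permutation_rejected(self, gata3):
        M, _ = gata3
        with pytest.raises(ValueError, match="permutation"):
            fl.build_tables(M, k=0, order=(1, 1, 2, 3, 4, 5))


class TestEnginesOnExactStringMatching:
    def test_substring_positions(self, uniform_bg):
        M = exact_match_matrix("ACG")
        k = 3 * 1000  # grid units
        for engine_fn in (
            lambda s: fl.naive_search(s, M, k),
            lambda s: fl.lookahead_search(s, M, k),
            lambda s: fl.fls_search(s, M, uniform_bg, k),
        ):
            hits, _ = engine_fn("TACGACGT")
            assert [h.position for h in hits] == [2, 5]

    def test_minimal_threshold_hits_everything(self, gata3):
        M, _ = gata3
        seq = "ACGTACGTACGT"
        k_min = int(M.int_scores.min(axis=1).sum())
        hits, stats = fl.naive_search(seq, M, k_min)
        assert len(hits) == len(seq) - M.width + 1
        assert stats.hits == len(hits)

    def test_above_max_threshold_hits_nothing(self, gata3):
        M, _ = gata3
        k_over = int(M.int_scores.max(axis=1).sum()) + 1
        hits, _ = fl.naive_search("ACGTACGTACGT", M, k_over)
        assert hits == []


class TestEngineEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_identical_hits(self, seed, uniform_bg):
        """NA, LS, FLS agree on hits and scores for seeded random inputs."""
        rng = np.random.default_rng(seed)
        width = int(rng.integers(5, 16))
        spec = fl.GeneratorSpec(seed=seed + 100, length=10_000)
        seq = fl.random_sequence(spec)
        pm = fl.random_matrix_with_ic(
            fl.GeneratorSpec(seed=seed + 200, length=width, target_ic=0.9 * width)
        )
        M = fl.log_odds(pm, uniform_bg)
        k = fl.p_to_threshold(fl.compute_pmf(M, uniform_bg), 1e-3).k
        na, s_na = fl.naive_search(seq, M, k)
        ls, s_ls = fl.lookahead_search(seq, M, k)
        fls, s_fls = fl.fls_search(seq, M, uniform_bg, k)
        assert hit_set(na) == hit_set(ls) == hit_set(fls)
        assert len(na) > 0 or k > int(M.int_scores.max(axis=1).sum())
        assert s_na.column_lookups == s_na.windows_scanned * width
        assert s_ls.column_lookups <= s_na.column_lookups
        assert s_fls.column_lookups <= s_na.column_lookups

    def test_adversarial_negative_column_maxima(self, uniform_bg):
        """Pruning stays sound when every entry of some columns is negative."""
        scores = np.array(
            [
                [-1.0, -2.0, -3.0, -1.5],
                [2.0, -1.0, 0.5, -2.0],
                [-0.5, -0.25, -4.0, -1.0],
                [1.0, 1.5, -1.0, 0.0],
            ]
        )
        M = fl.ScoringMatrix(scores)
        seq = fl.random_sequence(fl.GeneratorSpec(seed=11, length=20_000))
        for k_real in (-2.0, 0.0, 1.0, 2.5):
            k = int(round(k_real * 1000))
            na, _ = fl.naive_search(seq, M, k)
            ls, _ = fl.lookahead_search(seq, M, k)
            fls, _ = fl.fls_search(seq, M, uniform_bg, k)
            assert hit_set(na) == hit_set(ls) == hit_set(fls)

    def test_fls_with_identity_order_degenerates_to_ls(self, uniform_bg):
        rng = np.random.default_rng(2)
        M = random_scoring_matrix(rng, 10)
        seq = fl.random_sequence(fl.GeneratorSpec(seed=3, length=10_000))
        k = int(0.5 * M.int_scores.max(axis=1).sum())
        ls, s_ls = fl.lookahead_search(seq, M, k)
        fls, s_fls = fl.fls_search(seq, M, uniform_bg, k, order=tuple(range(1, 11)))
        assert hit_set(ls) == hit_set(fls)
        assert s_ls.column_lookups == s_fls.column_lookups
        np.testing.assert_array_equal(s_ls.windows_pruned_at, s_fls.windows_pruned_at)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        width = int(rng.integers(3, 10))
        M = random_scoring_matrix(rng, width, scale_digits=2)
        seq = "".join(rng.choice(list(fl.ALPHABET), size=500))
        bg = fl.Background(rng.dirichlet(np.full(4, 5.0)))
        k = int(rng.integers(M.int_scores.min(axis=1).sum(), M.int_scores.max(axis=1).sum() + 2))
        na, _ = fl.naive_search(seq, M, k)
        ls, _ = fl.lookahead_search(seq, M, k)
        fls, _ = fl.fls_search(seq, M, bg, k)
        assert hit_set(na) == hit_set(ls) == hit_set(fls)


class TestAmbiguousBasesAndEdges:
    def test_windows_with_n_are_skipped(self):
        M = exact_match_matrix("ACG")
        hits, stats = fl.naive_search("ACGNACG", M, 3000)
        # windows 1..5: only 1 and 5 are clean; 2,3,4 contain the N
        assert [h.position for h in hits] == [1, 5]
        assert stats.skipped_windows == 3
        assert stats.windows_scanned == 2

    def test_sequence_shorter_than_matrix_warns_empty(self, gata3):
        M, _ = gata3
        with pytest.warns(UserWarning, match="shorter"):
            hits, stats = fl.naive_search("ACG", M, 0)
        assert hits == [] and stats.windows_scanned == 0

    def test_hits_reported_in_position_order(self, uniform_bg):
        M = exact_match_matrix("AC")
        hits, _ = fl.fls_search("ACACAC", M, uniform_bg, 2000)
        positions = [h.position for h in hits]
        assert positions == sorted(positions)


class TestScanPipeline:
    def test_p_of_one_hits_every_clean_window(self, uniform_bg):
        seq = "ACGTNACGTACGT"
        pm = fl.ProbabilityMatrix(np.full((4, 4), 0.25))
        result = fl.scan([("r", seq)], pm, bg=uniform_bg, p=1.0, engine="na")
        assert len(result.hits) == result.stats.windows_scanned

    @pytest.mark.parametrize("engine", ENGINES)
    def test_engines_agree_through_scan(self, engine, uniform_bg):
        seq = fl.random_sequence(fl.GeneratorSpec(seed=42, length=20_000))
        pm = fl.random_matrix_with_ic(fl.GeneratorSpec(seed=43, length=9, target_ic=10.0))
        result = fl.scan([("r", seq)], pm, bg=uniform_bg, p=1e-3, engine=engine)
        ref = fl.scan([("r", seq)], pm, bg=uniform_bg, p=1e-3, engine="na")
        assert hit_set(result.hits) == hit_set(ref.hits)

    def test_background_estimated_when_absent(self):
        seq = "ACGT" * 500
        pm = fl.ProbabilityMatrix(np.full((4, 4), 0.25))
        result = fl.scan([("r", seq)], pm, p=0.5)
        np.testing.assert_allclose(result.background.probs, 0.25)

    def test_reverse_strand_hits(self, uniform_bg):
        # CCGTT on the forward strand is AACGG on the reverse strand
        M = exact_match_matrix("AACGG")
        result = fl.scan(
            [("r", "TTCCGTTTT")], M, bg=uniform_bg, k=5000, engine="na", both_strands=True
        )
        minus = [h for h in result.hits if h.strand == "-"]
        assert [(h.record_id, h.position) for h in minus] == [("r", 3)]

    def test_counts_are_pseudocounted_then_transformed(self, uniform_bg):
        cm = fl.CountMatrix(np.array([[8.0, 0, 0, 0], [0, 8.0, 0, 0]]))
        result = fl.scan([("r", "ACACAC")], cm, bg=uniform_bg, p=1 / 16, engine="ls")
        assert [h.position for h in result.hits] == [1, 3, 5]

    def test_requires_exactly_one_of_p_and_k(self, gata3):
        M, bg = gata3
        with pytest.raises(ValueError, match="exactly one"):
            fl.scan([("r", "ACGTACGT")], M, bg=bg)
        with pytest.raises(ValueError, match="exactly one"):
            fl.scan([("r", "ACGTACGT")], M, bg=bg, p=0.5, k=10)

    def test_empty_record_set_rejected(self, gata3):
        M, bg = gata3
        with pytest.raises(ValueError, match="records"):
            fl.scan([], M, bg=bg, p=0.5)


class TestPruningTrendSmoke:
    def test_fls_prunes_no_later_than_ls_on_average(self, uniform_bg):
        """Permuted order should not increase total lookups on informative motifs."""
        total_ls = total_fls = 0
        seq = fl.random_sequence(fl.GeneratorSpec(seed=0, length=20_000))
        for seed in range(10):
            pm = fl.random_matrix_with_ic(
                fl.GeneratorSpec(seed=seed, length=12, target_ic=0.7 * 24)
            )
            M = fl.log_odds(pm, uniform_bg)
            k = fl.p_to_threshold(fl.compute_pmf(M, uniform_bg), 1e-4).k
            _, s_ls = fl.lookahead_search(seq, M, k)
            _, s_fls = fl.fls_search(seq, M, uniform_bg, k)
            total_ls += s_ls.column_lookups
            total_fls += s_fls.column_lookups
        assert total_fls <= total_ls
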