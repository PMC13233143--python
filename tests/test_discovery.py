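"""Motif discovery: scoring, candidate selection, matching, enrichment, merging."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promotif.attention import AttentionProfile, tokenize
from promotif.discovery import (
    AhoCorasick,
    CandidateMotif,
    aggregate_heads,
    best_ungapped_overlap,
    count_occurrences,
    dedupe_candidates,
    extract_instance_windows,
    fdr_correct,
    filter_min_instances,
    hypergeometric_enrichment,
    hypergeometric_pmf,
    layer_specificity,
    merge_motifs_gapless,
    motif_set_difference,
    normalize_scores,
    select_candidate_motifs,
    select_layers,
)


def _profile(rows, token_len=3):
    """Build a 1-layer profile from per-head rows over J tokens."""
    rows = np.asarray(rows, dtype=float)
    seq = "ACG" * rows.shape[1]
    spans = tokenize(seq, k=token_len)
    return AttentionProfile(rows[None, :, :], spans)


class TestScoring:
    def test_aggregate_heads_is_head_mean(self):
        prof = _profile([[0.2, 0.3, 0.5], [0.4, 0.4, 0.2]])
        assert np.allclose(aggregate_heads(prof, 1), [0.3, 0.35, 0.35])

    def test_single_head_identity(self):
        prof = _profile([[0.1, 0.2, 0.7]])
        assert np.allclose(aggregate_heads(prof, 1), [0.1, 0.2, 0.7])

    def test_sum_vs_mean_aggregation_same_normalized_scores(self, rng):
        # the constant H cancels under max-normalization
        for _ in range(20):
            rows = rng.dirichlet(np.ones(8), size=4)
            mean_s = normalize_scores(rows.mean(axis=0))
            sum_s = normalize_scores(rows.sum(axis=0))
            assert np.allclose(mean_s, sum_s, atol=1e-12)

    def test_normalize_max_is_one(self, rng):
        alpha = rng.random(50) + 1e-9
        s = normalize_scores(alpha)
        assert s.max() == 1.0
        assert np.argmax(s) == np.argmax(alpha)
        assert np.allclose(normalize_scores([0.2, 0.4]), [0.5, 1.0])
        assert np.allclose(normalize_scores([0.3, 0.3]), [1.0, 1.0])

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_scores(np.zeros(4))

    def test_specificity_examples(self):
        assert layer_specificity(np.ones(4)) == 0.0
        # s = [1,0,0,0]: mean 0.25, sample sd 0.5, Sp = 1.5
        assert layer_specificity(np.array([1.0, 0, 0, 0])) == pytest.approx(1.5)

    def test_specificity_single_token_raises(self):
        with pytest.raises(ValueError):
            layer_specificity(np.array([1.0]))


class TestSelectLayers:
    def test_identical_layers_equal_any_layer(self):
        s = np.array([0.2, 1.0, 0.4])
        combined = select_layers([s, s, s, s], strategy="mid_plus_final")
        assert np.allclose(combined, s)

    def test_final_layer_dominates_when_others_uniform(self):
        L, J = 12, 10
        uniform = np.ones(J)
        final = np.ones(J)
        final[7] = 10.0
        layers = [uniform.copy() for _ in range(L - 1)] + [normalize_scores(final)]
        combined = select_layers(layers, strategy="mid_plus_final")
        assert np.argmax(combined) == 7

    def test_top_sp_picks_most_specific_layer(self):
        flat = np.ones(6)
        peaked = normalize_scores(np.array([1, 1, 1, 9.0, 1, 1]))
        combined = select_layers([flat, peaked, flat], strategy="top_sp")
        assert np.argmax(combined) == 3

    def test_single_layer_strategy(self):
        layers = [np.array([1.0, 0.5]), np.array([0.5, 1.0])]
        assert np.allclose(select_layers(layers, strategy="layer:2"), [0.5, 1.0])

    def test_unknown_strategy_raises(self):
        with pytest.raises(ValueError):
            select_layers([np.ones(3)], strategy="bogus")


class TestCandidateSelection:
    def test_hand_evaluated_run(self):
        # s = [1.0, 0.9, 0.1, 0.05], token length 3: mean 0.5125, 2*min 0.1;
        # tokens 1-2 pass both strict conditions -> one 6 bp region
        seq = "AAACCCGGGTTT"
        spans = tokenize(seq, k=3)
        cands = select_candidate_motifs(
            np.array([1.0, 0.9, 0.1, 0.05]), spans, seq, seq_id="s")
        assert len(cands) == 1
        assert cands[0].motif_sequence == "AAACCC"
        assert cands[0].instances[0][:3] == ("s", 0, 6)

    def test_uniform_scores_yield_nothing(self):
        seq = "ACGTACGTACGT"
        spans = tokenize(seq, k=4)
        assert select_candidate_motifs(np.ones(3), spans, seq) == []

    def test_short_region_discarded(self):
        # one passing 3 bp token flanked by failing tokens -> dropped (< 4 bp)
        seq = "AAACCCGGG"
        spans = tokenize(seq, k=3)
        cands = select_candidate_motifs(np.array([0.01, 1.0, 0.012]), spans, seq)
        assert cands == []

    def test_double_min_floor_can_exclude_everything(self):
        # min(s) >= 0.5 makes 2*min >= 1 >= every score: empty output
        seq = "AAAACCCCGGGG"
        spans = tokenize(seq, k=4)
        assert select_candidate_motifs(np.array([1.0, 0.6, 0.55]), spans, seq) == []


class TestAhoCorasick:
    @staticmethod
    def naive_matches(motif, text):
        return [i for i in range(len(text) - len(motif) + 1)
                if text[i:i + len(motif)] == motif]

    def test_presence_and_overlap_counting(self):
        stats = count_occurrences(["ACGT"], [("s1", 1, "ACGTACGT")])
        assert stats["ACGT"]["n"] == 1 and stats["ACGT"]["k"] == 1
        assert [p for _, p in stats["ACGT"]["positions"]] == [0, 4]

    def test_overlapping_occurrences(self):
        stats = count_occurrences(["AAA"], [("s1", 0, "AAAA")])
        assert [p for _, p in stats["AAA"]["positions"]] == [0, 1]
        assert stats["AAA"]["n"] == 1 and stats["AAA"]["k"] == 0

    def test_non_acgt_pattern_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            AhoCorasick(["ACGN"])

    def test_matches_equal_naive_scan_random(self, rng):
        bases = np.array(list("ACGT"))
        motifs = list({"".join(bases[rng.integers(0, 4, rng.integers(4, 10))])
                       for _ in range(30)})
        seqs = [(f"s{i}", i % 2, "".join(bases[rng.integers(0, 4, 300)]))
                for i in range(40)]
        stats = count_occurrences(motifs, seqs)
        for m in motifs:
            naive_pos, naive_n, naive_k = [], 0, 0
            for sid, lab, seq in seqs:
                hits = self.naive_matches(m, seq)
                naive_pos += [(sid, h) for h in hits]
                if hits:
                    naive_n += 1
                    naive_k += lab
            assert sorted(stats[m]["positions"]) == sorted(naive_pos)
            assert (stats[m]["n"], stats[m]["k"]) == (naive_n, naive_k)

    def test_nested_and_shared_prefix_patterns(self):
        # suffix-link output propagation: ACGT inside TACGTA, AC prefix-shared
        stats = count_occurrences(["ACGT", "TACGTA", "ACGTACG"],
                                  [("s", 1, "GTACGTACGTA")])
        assert [p for _, p in stats["ACGT"]["positions"]] == [2, 6]
        assert [p for _, p in stats["TACGTA"]["positions"]] == [1, 5]
        assert [p for _, p in stats["ACGTACG"]["positions"]] == [2]


class TestHypergeometric:
    def test_enumeration_examples(self):
        # N=10, K=5, n=4, k=4: C(5,4)*C(5,0)/C(10,4) = 5/210
        assert hypergeometric_enrichment(10, 5, 4, 4) == pytest.approx(5 / 210, abs=1e-12)
        # N=4, K=2, n=2, k=2: 1/6
        assert hypergeometric_enrichment(4, 2, 2, 2) == pytest.approx(1 / 6, abs=1e-12)

    def test_zero_k_tail_is_one(self):
        assert hypergeometric_enrichment(10, 5, 4, 0) == 1.0

    def test_pmf_matches_closed_form(self):
        for N, K, n, k in [(10, 5, 4, 2), (12, 7, 6, 3), (8, 3, 5, 1)]:
            expected = comb(K, k) * comb(N - K, n - k) / comb(N, n)
            assert hypergeometric_pmf(N, K, n, k) == pytest.approx(expected, rel=1e-12)

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(10, 5, 4, 5)
        with pytest.raises(ValueError):
            hypergeometric_enrichment(10, 12, 4, 2)

    def test_tail_equals_exhaustive_enumeration_small(self):
        # draw every n-subset of N items (first K positive) and count those
        # with >= k positives
        for N in (5, 8):
            for K in range(N + 1):
                for n in range(N + 1):
                    subsets = list(itertools.combinations(range(N), n))
                    for k in range(max(0, n - (N - K)), min(K, n) + 1):
                        frac = sum(1 for S in subsets
                                   if sum(x < K for x in S) >= k) / len(subsets)
                        assert hypergeometric_enrichment(N, K, n, k) == pytest.approx(
                            frac, abs=1e-12)


class TestFDR:
    @staticmethod
    def brute_force_bh(p, alpha):
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        passed = [i for i in range(m) if p[order[i]] <= (i + 1) * alpha / m]
        cutoff = max(passed) if passed else -1
        reject = np.zeros(m, dtype=bool)
        reject[order[: cutoff + 1]] = True
        return reject

    def test_hand_example(self):
        q, flags = fdr_correct([0.001, 0.02, 0.03], alpha=0.05)
        assert np.allclose(q, [0.003, 0.03, 0.03])
        assert flags.tolist() == [True, True, True]

    def test_single_p(self):
        q, flags = fdr_correct([0.005], alpha=0.01)
        assert q[0] == pytest.approx(0.005) and flags[0]

    def test_all_ones_nothing_significant(self):
        _, flags = fdr_correct([1.0] * 10, alpha=0.01)
        assert not flags.any()

    def test_flags_match_brute_force(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 30))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            _, flags = fdr_correct(p, alpha=0.01)
            assert np.array_equal(flags, self.brute_force_bh(p, 0.01))

    def test_q_monotone_and_bounded(self, rng):
        p = rng.random(50)
        q, _ = fdr_correct(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestInstanceFilterAndMerge:
    def _motif(self, seq, n_inst, sid="s"):
        return CandidateMotif(seq, [(f"{sid}{i}", 0, len(seq), 1.0)
                                    for i in range(n_inst)])

    def test_min_instance_boundary(self):
        motifs = [self._motif("ACGTAA", 2), self._motif("CCGGTT", 3)]
        kept = filter_min_instances(motifs, 3)
        assert [m.motif_sequence for m in kept] == ["CCGGTT"]
        assert filter_min_instances([], 3) == []

    def test_best_ungapped_overlap_oracle(self, rng):
        # brute-force offset scan agrees with the implementation
        bases = np.array(list("ACGT"))
        for _ in range(50):
            a = "".join(bases[rng.integers(0, 4, rng.integers(4, 12))])
            b = "".join(bases[rng.integers(0, 4, rng.integers(4, 12))])
            best = -1
            for off in range(-(len(b) - 1), len(a)):
                m = sum(1 for i in range(len(a))
                        if 0 <= i - off < len(b) and a[i] == b[i - off])
                best = max(best, m)
            assert best_ungapped_overlap(a, b)[0] == best

    def test_identical_motifs_merge_with_instance_union(self):
        a = CandidateMotif("ACGTAC", [("s1", 0, 6, 1.0)])
        b = CandidateMotif("ACGTAC", [("s2", 3, 9, 0.9)])
        merged = merge_motifs_gapless([a, b])
        assert len(merged) == 1
        assert merged[0].motif_sequence == "ACGTAC"
        assert len(merged[0].instances) == 2

    def test_overlapping_motifs_build_consensus(self):
        # best overlap of ACGTAC/CGTACG is 5 matches >= 0.8*6; union "ACGTACG"
        a = CandidateMotif("ACGTAC", [("s1", 0, 6, 1.0)])
        b = CandidateMotif("CGTACG", [("s2", 0, 6, 1.0)])
        merged = merge_motifs_gapless([a, b])
        assert [m.motif_sequence for m in merged] == ["ACGTACG"]

    def test_dissimilar_motifs_not_merged(self):
        a = CandidateMotif("AAAA", [("s1", 0, 4, 1.0)])
        b = CandidateMotif("CCCC", [("s2", 0, 4, 1.0)])
        assert len(merge_motifs_gapless([a, b])) == 2

    def test_idempotent_and_order_independent(self):
        motifs = [
            CandidateMotif("ACGTACGT", [("a", 0, 8, 1.0)]),
            CandidateMotif("CGTACGTA", [("b", 0, 8, 1.0)]),
            CandidateMotif("TTTTGGGG", [("c", 0, 8, 1.0)]),
            CandidateMotif("ACGTACGT", [("d", 2, 10, 1.0)]),
        ]
        once = merge_motifs_gapless(motifs)
        twice = merge_motifs_gapless(once)
        assert sorted(m.motif_sequence for m in once) == sorted(
            m.motif_sequence for m in twice)
        reordered = merge_motifs_gapless(motifs[::-1])
        assert sorted(m.motif_sequence for m in once) == sorted(
            m.motif_sequence for m in reordered)


class TestWindowsAndSetLogic:
    def test_window_arithmetic(self):
        seq = "A" * 200
        m = CandidateMotif("AAAAAA", [("s", 100, 106, 1.0)])
        windows = extract_instance_windows([m], {"s": seq})
        header, w = windows[0]
        # center = 103, window [91, 115)
        assert len(w) == 24 and header.endswith("|91")

    def test_left_clipped_window(self):
        seq = "ACGT" * 10
        m = CandidateMotif("GTAC", [("s", 2, 6, 1.0)])
        (_, w), = extract_instance_windows([m], {"s": seq})
        assert len(w) == 16  # [0, 16): clipped at the sequence start
        assert w == seq[:16]

    def test_windows_deterministic(self, tmp_path):
        from promotif.discovery import write_windows_fasta
        seq = "ACGTACGTACGTACGTACGTACGTACGT"
        m = CandidateMotif("ACGTAC", [("s", 8, 14, 1.0), ("s", 16, 22, 0.5)])
        w1, w2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_windows_fasta(extract_instance_windows([m], {"s": seq}), w1)
        write_windows_fasta(extract_instance_windows([m], {"s": seq}), w2)
        assert w1.read_bytes() == w2.read_bytes()

    def test_exact_set_difference(self):
        B = [CandidateMotif("ACGTAA", []), CandidateMotif("CCCCGG", [])]
        A = [CandidateMotif("CCCCGG", [])]
        out = motif_set_difference(B, A)
        assert [m.motif_sequence for m in out] == ["ACGTAA"]
        assert [m.motif_sequence for m in motif_set_difference(B, [])] == [
            "ACGTAA", "CCCCGG"]

    def test_similarity_mode_excludes_near_duplicates(self):
        # one-base difference on 6-mers: 5/6 matches >= 0.8*6 -> shared
        B = [CandidateMotif("ACGTAC", [])]
        A = [CandidateMotif("ACGGAC", [])]
        assert motif_set_difference(B, A, matching="exact") == B
        assert motif_set_difference(B, A, matching="similar") == []


def test_dedupe_candidates_pools_instances():
    cands = [CandidateMotif("ACGTAA", [("s1", 0, 6, 1.0)]),
             CandidateMotif("ACGTAA", [("s2", 4, 10, 0.8)]),
             CandidateMotif("TTTTCC", [("s1", 9, 15, 0.9)])]
    pooled = dedupe_candidates(cands)
    by_seq = {m.motif_sequence: m for m in pooled}
    assert len(pooled) == 2 and by_seq["ACGTAA"].n_instances == 2
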