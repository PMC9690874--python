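import pytest
from hypothesis import given, strategies as st

from anchalign import (
    AffineScoring,
    Candidate,
    FixedScoring,
    LookupConfig,
    LookupIndex,
    LookupRow,
    MemoryBackend,
    SubalignmentStore,
    align_residuals,
    distance_filter,
    exact_align,
    find_occurrences,
    greedy_select,
    heuristic_align,
    nw_align,
    pair_candidates,
    preset_family,
    rescore_alignment,
)
from anchalign.heuristic import AnchorBlock


def index_of(subseqs, rows):
    return LookupIndex(subseqs, rows)


def row(rid, a_id, b_id, aligned_a, aligned_b, score):
    return LookupRow(rid, a_id, b_id, aligned_a, aligned_b, score)


class TestFindOccurrences:
    def test_overlapping_occurrences(self):
        idx = index_of([(1, "ACA")], [])
        assert [(h.subseq_id, h.start) for h in idx.find_occurrences("ACACA")] == [
            (1, 0),
            (1, 2),
        ]

    def test_empty_table(self):
        assert index_of([], []).find_occurrences("ACGT") == []

    def test_pattern_longer_than_sequence(self):
        idx = index_of([(1, "ACGTACGT")], [])
        assert idx.find_occurrences("ACGT") == []

    def test_sorted_by_id_then_start(self):
        idx = index_of([(2, "CA"), (1, "AC")], [])
        hits = idx.find_occurrences("ACACA")
        assert [(h.subseq_id, h.start) for h in hits] == [
            (1, 0), (1, 2), (2, 1), (2, 3),
        ]

    def test_store_entry_point(self, backend_factory, fixed_scheme):
        store = SubalignmentStore(backend_factory())
        store.load_sequences([("s1", "ACGTACGT"), ("s2", "ACGTACGT")])
        store.draw_sample(2, seed=0)
        store.build_lookup(LookupConfig(k=4, z=2, scheme=fixed_scheme))
        hits = find_occurrences(store, "ACGTACGT")
        assert hits  # the stored windows occur in their source sequence


class TestPairCandidates:
    subseqs = [(1, "ACA"), (2, "ACCA")]
    lookup = [row(1, 1, 2, "AC-A", "ACCA", 4)]

    def test_forward_orientation(self):
        idx = index_of(self.subseqs, self.lookup)
        hits_a = idx.find_occurrences("TTTACATT")    # ACA at 3
        hits_b = idx.find_occurrences("TTTTTACCAT")  # ACCA at 5
        cands = pair_candidates(idx, hits_a, hits_b)
        assert [(c.score, c.ind1, c.ind2, c.swapped) for c in cands] == [
            (4, 3, 5, False)
        ]
        assert cands[0].row_a == "AC-A" and cands[0].row_b == "ACCA"

    def test_swapped_orientation(self):
        idx = index_of(self.subseqs, self.lookup)
        hits_a = idx.find_occurrences("ACCATT")  # ACCA at 0
        hits_b = idx.find_occurrences("TTACA")   # ACA at 2
        cands = pair_candidates(idx, hits_a, hits_b)
        assert [(c.ind1, c.ind2, c.swapped) for c in cands] == [(0, 2, True)]
        # rows are exchanged on use
        assert cands[0].row_a == "ACCA" and cands[0].row_b == "AC-A"
        assert (cands[0].r_a, cands[0].r_b) == (4, 3)

    def test_no_matching_pair(self):
        idx = index_of(self.subseqs, self.lookup)
        hits_a = idx.find_occurrences("TTTACATT")
        hits_b = idx.find_occurrences("TTTACATT")  # ACA on both sides only
        assert pair_candidates(idx, hits_a, hits_b) == []

    def test_score_descending_with_deterministic_ties(self):
        subseqs = [(1, "AC"), (2, "CA")]
        lookup = [
            row(1, 1, 1, "AC", "AC", 2),
            row(2, 2, 2, "CA", "CA", 2),
        ]
        idx = index_of(subseqs, lookup)
        hits = idx.find_occurrences("ACA")
        cands = pair_candidates(idx, hits, hits)
        assert [c.score for c in cands] == sorted(
            (c.score for c in cands), reverse=True
        )
        keys = [(-c.score, c.ind1, c.ind2, c.lookup.id) for c in cands]
        assert keys == sorted(keys)

    def test_multiple_occurrences_multiply_candidates(self):
        idx = index_of([(1, "ACA")], [row(1, 1, 1, "ACA", "ACA", 3)])
        hits_a = idx.find_occurrences("ACACA")  # two occurrences
        hits_b = idx.find_occurrences("TACAT")  # one occurrence
        assert len(pair_candidates(idx, hits_a, hits_b)) == 2


class TestDistanceFilter:
    def mk(self, score, ind1, ind2):
        return Candidate(row(1, 1, 1, "ACA", "ACA", score), ind1, ind2)

    def test_fixed_keep(self, fixed_scheme):
        assert distance_filter(self.mk(4, 10, 11), fixed_scheme)   # 2 < 4

    def test_fixed_discard_at_equality(self, fixed_scheme):
        assert not distance_filter(self.mk(4, 10, 12), fixed_scheme)  # 4 < 4 fails

    def test_affine_keep(self, affine_scheme):
        assert distance_filter(self.mk(5, 7, 8), affine_scheme)  # 4 < 5

    def test_affine_discard(self, affine_scheme):
        assert not distance_filter(self.mk(5, 0, 2), affine_scheme)  # 5 < 5 fails

    @pytest.mark.parametrize("scheme_name", ["fixed", "affine"])
    def test_zero_offset_always_kept(self, scheme_name, fixed_scheme, affine_scheme):
        scheme = fixed_scheme if scheme_name == "fixed" else affine_scheme
        assert distance_filter(self.mk(1, 5, 5), scheme)


class TestGreedySelect:
    def cand(self, rid, score, ind1, ind2, s="ACA"):
        return Candidate(row(rid, 1, 1, s, s, score), ind1, ind2)

    def test_single_candidate(self):
        blocks = greedy_select([self.cand(1, 3, 0, 0)], 10, 10)
        assert len(blocks) == 1
        assert (blocks[0].p_a, blocks[0].p_b, blocks[0].r_a) == (0, 0, 3)

    def test_overlap_in_one_sequence_rejected(self):
        cands = [self.cand(1, 4, 0, 0), self.cand(2, 3, 2, 6)]  # overlap in A
        blocks = greedy_select(cands, 12, 12)
        assert [b.score for b in blocks] == [4]

    def test_order_crossing_rejected(self):
        # disjoint intervals but reversed order between A and B
        cands = [self.cand(1, 4, 0, 6), self.cand(2, 3, 6, 0)]
        blocks = greedy_select(cands, 12, 12)
        assert [b.score for b in blocks] == [4]

    def test_compatible_anchors_both_kept_in_order(self):
        cands = [self.cand(1, 4, 6, 6), self.cand(2, 3, 0, 0)]
        blocks = greedy_select(cands, 12, 12)
        assert [(b.p_a, b.p_b) for b in blocks] == [(0, 0), (6, 6)]


class TestAlignResiduals:
    def test_no_blocks_is_exact_alignment(self, fixed_scheme):
        aln = align_residuals("ACGT", "AGT", [], fixed_scheme)
        assert aln == nw_align("ACGT", "AGT", fixed_scheme)

    def test_full_score_with_matching_block(self, fixed_scheme):
        seq = "ACGTACGT"
        block = AnchorBlock(2, 2, 4, 4, "GTAC", "GTAC", 4)
        aln = align_residuals(seq, seq, [block], fixed_scheme)
        assert aln.score == 8
        assert aln.row_a == aln.row_b == seq

    def test_block_mismatching_sequence_rejected(self, fixed_scheme):
        from anchalign import ContractError

        block = AnchorBlock(0, 0, 4, 4, "AAAA", "AAAA", 4)
        with pytest.raises(ContractError):
            align_residuals("ACGTACGT", "ACGTACGT", [block], fixed_scheme)

    @given(st.integers(0, 2**31 - 1))
    def test_reconstruction_property(self, seed):
        """De-gapped heuristic rows always reproduce the inputs."""
        import random

        fixed_scheme = FixedScoring(1, -1, -2)
        rng = random.Random(seed)
        a = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 40)))
        b = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 40)))
        store = SubalignmentStore(MemoryBackend())
        store.load_sequences([("a", a), ("b", b)])
        store.draw_sample(2, seed=seed % 1000)
        store.build_lookup(LookupConfig(k=4, z=2, scheme=fixed_scheme))
        res = heuristic_align(a, b, store, fixed_scheme)
        aln = res.alignment
        assert aln.row_a.replace("-", "") == a
        assert aln.row_b.replace("-", "") == b
        assert not any(x == y == "-" for x, y in zip(aln.row_a, aln.row_b))
        assert rescore_alignment(aln.row_a, aln.row_b, fixed_scheme) == aln.score


class TestHeuristicAlign:
    def test_empty_lookup_falls_back_exactly(self, backend_factory, fixed_scheme):
        store = SubalignmentStore(backend_factory())
        store.load_sequences([("a", "ACGTAC"), ("b", "AGGTAC")])
        res = heuristic_align("ACGTAC", "AGGTAC", store, fixed_scheme)
        exact = nw_align("ACGTAC", "AGGTAC", fixed_scheme)
        assert res.alignment == exact
        assert res.utilized is False and res.n_anchors == 0

    def test_self_pair_with_lookup_from_itself(self, backend_factory, fixed_scheme):
        seq = "ACGTACGTACGTACGT"
        store = SubalignmentStore(backend_factory())
        store.load_sequences([("a", seq), ("b", seq)])
        store.draw_sample(2, seed=0)
        store.build_lookup(LookupConfig(k=4, z=2, scheme=fixed_scheme))
        res = heuristic_align(seq, seq, store, fixed_scheme)
        assert res.utilized is True
        assert res.alignment.score == len(seq) * fixed_scheme.match
        assert res.alignment.score == nw_align(seq, seq, fixed_scheme).score

    @pytest.mark.parametrize("scheme_name", ["fixed", "affine"])
    def test_score_never_exceeds_optimum(self, scheme_name):
        scheme = FixedScoring() if scheme_name == "fixed" else AffineScoring()
        family = preset_family("d50", n_sequences=6, seed=11)
        store = SubalignmentStore(MemoryBackend())
        store.load_sequences(family)
        store.draw_sample(4, seed=11)
        store.build_lookup(LookupConfig(k=5, z=4, scheme=scheme))
        index = LookupIndex.from_store(store)
        from itertools import combinations

        any_utilized = False
        for sa, sb in combinations(family, 2):
            res = heuristic_align(sa.seq, sb.seq, store, scheme, index=index)
            opt = exact_align(sa.seq, sb.seq, scheme)
            assert res.alignment.score <= opt.score
            any_utilized = any_utilized or res.utilized
        assert any_utilized  # the lookup is actually exercised

    def test_utilization_monotone_in_k(self):
        """Smaller k (at the default threshold rule) never reduces how often
        anchors are found, averaged over repeated sample draws."""
        from anchalign import LookupConfig, evaluate_all_pairs, mean_report

        family = preset_family("d50", n_sequences=10, seed=5)
        rates = []
        for k in (5, 10, 15):
            cfg = LookupConfig(k=k, z=5)
            reports = evaluate_all_pairs(family, cfg, repeats=3, seed=5)
            rates.append(mean_report(reports).utilization_rate)
        assert rates[0] >= rates[1] >= rates[2]
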