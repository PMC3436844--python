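import numpy as np
import pytest

from sanslite.fixtures import mutate, random_protein
from sanslite.sequence_io import db_from_records
from sanslite.sans_engine import SearchParams, search
from sanslite.greedy_align import (
    HSP,
    Seed,
    chain_hsps,
    extend_hsp,
    find_two_hit_seeds,
    greedy_align_pair,
    load_matrix,
    rescore_hits,
)

from oracles import best_segment_on_diagonal, optimal_chain_score


@pytest.fixture(scope="module")
def blosum62():
    return load_matrix()


def diag_self_score(seq, m):
    return sum(int(m[ord(c), ord(c)]) for c in seq)


class TestSeeds:
    def test_self_pair_has_main_diagonal_seed(self):
        seeds = find_two_hit_seeds("MKVLAQR", "MKVLAQR")
        assert any(s.diagonal == 0 and s.q_start == 0 and s.q_end == 6 for s in seeds)

    def test_no_shared_three_mers(self):
        assert find_two_hit_seeds("MKVLAQR", "CDEFGHI") == []

    def test_distance_beyond_forty_is_rejected(self):
        q = "MKV" + "A" * 50 + "MKV"
        s = "MKV" + "C" * 50 + "MKV"
        assert find_two_hit_seeds(q, s) == []

    def test_distance_at_forty_is_accepted(self):
        q = "MKV" + "A" * 37 + "MKV"
        s = "MKV" + "C" * 37 + "MKV"
        seeds = find_two_hit_seeds(q, s)
        assert any(s_.diagonal == 0 and s_.q_start == 0 for s_ in seeds)

    def test_overlapping_hits_count_as_one(self):
        # "AAAA" vs itself: the diagonal-0 word hits start 1 apart (overlap),
        # so no two-hit forms; with two words 3 apart a seed does form
        assert all(s.diagonal != 0 for s in find_two_hit_seeds("AAAA", "AAAA"))
        assert any(
            s.diagonal == 0 and s.q_start == 0 and s.q_end == 6
            for s in find_two_hit_seeds("MKVMKV", "MKVMKV")
        )


class TestExtendHsp:
    def test_homopolymer_full_span(self, blosum62):
        hsp = extend_hsp("AAAAAA", "AAAAAA", Seed(0, 0, 6), blosum62)
        assert (hsp.q_start, hsp.q_end, hsp.s_start, hsp.s_end) == (0, 6, 0, 6)
        assert hsp.score == 6 * int(blosum62[ord("A"), ord("A")])  # 24

    def test_identical_sequences_cover_full_diagonal(self, blosum62, nprng):
        for _ in range(10):
            seq = random_protein(int(nprng.integers(10, 60)), nprng)
            hsp = extend_hsp(seq, seq, Seed(0, 2, 8), blosum62)
            assert (hsp.q_start, hsp.q_end) == (0, len(seq))
            assert hsp.score == diag_self_score(seq, blosum62)

    def test_extension_stops_inside_mismatch_block(self, blosum62, nprng):
        # identity block + long scrambled block + identity block on diagonal 0;
        # a seed in the left block must yield exactly that block, as found by
        # the exhaustive best-segment oracle restricted to the diagonal
        left = "MKVLAQRWYEDH"
        right = "CEFGHIKLNPQR"
        q = left + "W" * 30 + right
        s = left + "D" * 30 + right
        hsp = extend_hsp(q, s, Seed(0, 0, 6), blosum62)
        assert (hsp.q_start, hsp.q_end) == (0, len(left))
        a, b, score = best_segment_on_diagonal(q[: len(left) + 10], s[: len(left) + 10], 0, blosum62)
        assert (hsp.q_start, hsp.q_end, hsp.score) == (a, b, score)


class TestChaining:
    def test_single_hsp(self):
        h = HSP(0, 5, 0, 5, 20)
        ga = chain_hsps([h])
        assert ga.hsps == [h] and ga.total_score == 20

    def test_two_colinear_hsps(self):
        a, b = HSP(0, 5, 0, 5, 20), HSP(10, 15, 8, 13, 15)
        ga = chain_hsps([b, a])
        assert ga.hsps == [a, b] and ga.total_score == 35

    def test_crossing_hsps_keep_highest(self):
        a, b = HSP(0, 5, 10, 15, 30), HSP(10, 15, 0, 5, 20)
        ga = chain_hsps([a, b])
        assert ga.hsps == [a] and ga.total_score == 30

    def test_non_positive_hsps_dropped(self):
        assert chain_hsps([HSP(0, 3, 0, 3, 0), HSP(4, 7, 4, 7, -5)]).hsps == []

    def test_chain_is_strictly_ordered_and_sums(self, nprng):
        for _ in range(50):
            n = int(nprng.integers(1, 12))
            hsps = []
            for _ in range(n):
                qa = int(nprng.integers(0, 80))
                sa = int(nprng.integers(0, 80))
                ln = int(nprng.integers(3, 25))
                hsps.append(HSP(qa, qa + ln, sa, sa + ln, int(nprng.integers(1, 60))))
            ga = chain_hsps(hsps)
            assert ga.total_score == sum(h.score for h in ga.hsps)
            for u, v in zip(ga.hsps, ga.hsps[1:]):
                assert u.q_end <= v.q_start and u.s_end <= v.s_start

    def test_never_beats_optimal_chain(self, nprng):
        for _ in range(100):
            n = int(nprng.integers(1, 10))
            hsps = []
            for _ in range(n):
                qa = int(nprng.integers(0, 80))
                sa = int(nprng.integers(0, 80))
                ln = int(nprng.integers(3, 25))
                hsps.append(HSP(qa, qa + ln, sa, sa + ln, int(nprng.integers(1, 60))))
            assert chain_hsps(hsps).total_score <= optimal_chain_score(hsps)


class TestGreedyAlignPair:
    def test_identical_sequences_score_exact_diagonal_sum(self, blosum62, nprng):
        for length in (6, 20, 80, 300):
            seq = random_protein(length, nprng)
            ga = greedy_align_pair(seq, seq, blosum62)
            assert ga.total_score == diag_self_score(seq, blosum62)

    def test_no_seeds_scores_zero(self, blosum62):
        assert greedy_align_pair("MKVLAQR", "CDEFGHI", blosum62).total_score == 0

    def test_near_identical_pairs_cost_less_work_than_distant_ones(self, blosum62, nprng):
        # close hits align in one long extension with the scan jumping past
        # it; distant pairs pay for many scan positions and restarted
        # extensions — the rationale for rescoring being cheap on close hits
        wins = 0
        for _ in range(5):
            q = random_protein(500, nprng)
            near = mutate(q, 0.02, nprng)
            far = mutate(q, 0.5, nprng, indel_rate=0.05)
            sn, sf = {}, {}
            greedy_align_pair(q, near, blosum62, stats=sn)
            greedy_align_pair(q, far, blosum62, stats=sf)
            work_near = sn.get("scan_steps", 0) + sn.get("ext_steps", 0)
            work_far = sf.get("scan_steps", 0) + sf.get("ext_steps", 0)
            wins += work_near < work_far
        assert wins >= 4


class TestRescoreHits:
    def test_identical_target_outranks_half_identity_mutant(self, nprng):
        founder = random_protein(120, nprng)
        db = db_from_records([("half", mutate(founder, 0.5, nprng)), ("same", founder)])
        qdb = db_from_records([("q", founder)])
        hits = search(db, qdb, SearchParams(H=2, W=2))
        rescored = rescore_hits(hits, db, qdb, keep=2)
        assert rescored["q"][0].target_id == "same"
        assert rescored["q"][0].greedy_score > (rescored["q"][1].greedy_score or 0)

    def test_unalignable_hits_sink_to_zero(self, nprng):
        founder = random_protein(60, nprng)
        # a target sharing single 3-mers at most scores 0 and ranks below any
        # aligned hit regardless of its retrieval score
        db = db_from_records([("same", founder), ("junk", "ACDEFGHIKLMNPQRSTVWY")])
        qdb = db_from_records([("q", founder)])
        hits = search(db, qdb, SearchParams(H=2, W=2))
        rescored = rescore_hits(hits, db, qdb, keep=2)
        assert rescored["q"][0].target_id == "same"
        tail = [h for h in rescored["q"] if h.target_id == "junk"]
        assert all(h.greedy_score == 0 for h in tail)

    def test_keep_zero_empties_lists(self, nprng):
        founder = random_protein(40, nprng)
        db = db_from_records([("p", founder)])
        qdb = db_from_records([("q", founder)])
        hits = search(db, qdb, SearchParams(H=1, W=1))
        assert rescore_hits(hits, db, qdb, keep=0) == {"q": []}

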