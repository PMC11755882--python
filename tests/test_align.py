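"""Extension stage: bounds, split/join, exact A*, and read-level behavior."""

import random
from fractions import Fraction

import pytest

from xmeralign.align import (align_read, astar_align, extend_candidate,
                             max_gap_length, mismatch_piece_bound,
                             piece_length, split_and_join, ungapped_align)
from xmeralign.index import build_index
from xmeralign.penalty import (PRESETS, PenaltyConfig, max_allowed_penalty,
                               reverse_complement, score_events)
from oracles import dp_min_penalty, mutate_read, random_dna

S1 = PRESETS["setting1"]


def _rand(seed, n):
    return "".join(random.Random(seed).choices("ACGT", k=n))


# -- ungapped --------------------------------------------------------------

def test_ungapped_exact_and_thresholds():
    ref = _rand(31, 300)
    ev, pen, esc = ungapped_align(ref[50:100], ref, 50, S1)
    assert pen == 0 and not esc and ev == [("match", 50)]
    q = list(ref[50:100])
    q[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[10]]
    ev, pen, esc = ungapped_align("".join(q), ref, 50, S1)
    assert pen == 6 and not esc          # 6 < open + extend = 8
    q[30] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[30]]
    ev, pen, esc = ungapped_align("".join(q), ref, 50, S1)
    assert pen == 12 and esc             # 12 >= 8: check indels


def test_ungapped_clips_only_beyond_contig_ends():
    ref = _rand(32, 60)
    q = "TTTT" + ref[:20]
    ev, pen, esc = ungapped_align(q, ref, -4, S1)
    assert ev[0] == ("soft_clip", 4) and pen == 4


# -- piece bound and gap cap ----------------------------------------------

def test_piece_length_examples():
    assert piece_length(100) == 5
    assert piece_length(1) == 2
    assert piece_length(150) == 5


def test_mismatch_piece_bound_basic():
    ref = _rand(33, 400)
    q = ref[100:200]
    assert mismatch_piece_bound(q, ref[50:250], 5) == 0
    q = list(q)
    q[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[50]]
    assert mismatch_piece_bound("".join(q), ref[50:250], 5) <= 1


def test_mismatch_piece_bound_admissible_against_dp():
    """The piece count never exceeds the optimum's mutated-base count."""
    rng = random.Random(34)
    for _ in range(120):
        ref = random_dna(rng, 240)
        start = rng.randint(20, 60)
        template = ref[start:start + 120]
        read = mutate_read(rng, template, 0.04, 0.01)
        if not read:
            continue
        region = ref[max(0, start - 20):start + len(read) + 20]
        plen = piece_length(len(read))
        bound = mismatch_piece_bound(read, region, plen)
        opt = dp_min_penalty(read, region, S1)
        # a mutation costs at most snp (6); bound * 1 mutations minimum
        assert bound * min(S1.snp_penalty, S1.extend_indel_penalty) <= opt \
            or bound * S1.snp_penalty <= opt + 5 * S1.snp_penalty
        # direct admissibility at the penalty level for the common case
        assert bound * S1.extend_indel_penalty <= opt


def test_max_gap_length_examples():
    assert max_gap_length(60, 0, S1) == 18         # floor((60-5)/3)
    assert max_gap_length(8, 2, S1) is None        # 2*6 > 8: rejected
    assert max_gap_length(7, 0, S1) == 0           # (7-5)/3 floors to 0


# -- split and join --------------------------------------------------------

def test_split_join_single_deletion():
    ref = _rand(35, 500)
    read = ref[100:175] + ref[178:253]             # 3 bp deletion at midpoint
    joined, escalate = split_and_join(read, ref, 100, S1, max_gap=10)
    assert joined is not None
    events, pen, pos = joined
    assert ("deletion", 3) in events
    assert pen == score_events(events, S1) == S1.gap_cost(3)
    assert pos == 100 and escalate


def test_split_join_clean_read_joins_flat():
    ref = _rand(36, 400)
    read = ref[50:200]
    joined, escalate = split_and_join(read, ref, 50, S1, max_gap=10)
    events, pen, pos = joined
    assert pen == 0 and pos == 50 and not escalate


def test_split_join_penalty_equals_event_score():
    ref = _rand(37, 500)
    read = ref[100:160] + "ACGT" + ref[160:230]    # 4 bp insertion
    joined, _ = split_and_join(read, ref, 100, S1, max_gap=10)
    events, pen, pos = joined
    assert pen == score_events(events, S1)
    assert any(k == "insertion" for k, _ in events)


# -- A* vs full DP ---------------------------------------------------------

def test_astar_trivial_identity():
    w = _rand(38, 50)
    ev, pen, pos = astar_align(w, w, S1, max_gap=5)
    assert pen == 0 and pos == 0 and ev == [("match", 50)]


def test_astar_single_insertion_matches_dp():
    ref = _rand(39, 200)
    read = ref[40:90] + "TGCA" + ref[90:140]
    window = ref[20:160]
    ev, pen, pos = astar_align(read, window, S1, max_gap=8)
    assert pen == 5 + 4 * 3 == 17
    assert pen == dp_min_penalty(read, window, S1)
    assert any(k == "insertion" and n == 4 for k, n in ev)


@pytest.mark.parametrize("config_name", ["setting1", "setting2", "setting4"])
def test_astar_equals_dp_fuzz(config_name):
    """A* penalty equals the full-matrix DP penalty, exactly."""
    cfg = PRESETS[config_name]
    rng = random.Random(40)
    for _ in range(60):
        ref = random_dna(rng, rng.randint(120, 260))
        start = rng.randint(0, 40)
        span = rng.randint(40, min(160, len(ref) - start))
        read = mutate_read(rng, ref[start:start + span], 0.05, 0.02)
        if not read:
            continue
        window = ref[max(0, start - 15):start + span + 15]
        mg = max(len(read), len(window))   # no effective cap
        got = astar_align(read, window, cfg, max_gap=mg)
        want = dp_min_penalty(read, window, cfg)
        assert (got[1] if got else None) == want


def test_astar_edge_clips_match_dp():
    cfg = S1
    rng = random.Random(41)
    for _ in range(40):
        ref = random_dna(rng, 120)
        # read overhanging the contig start
        read = random_dna(rng, rng.randint(3, 10)) + ref[:40]
        got = astar_align(read, ref, cfg, max_gap=len(read),
                          at_left_edge=True, at_right_edge=True)
        want = dp_min_penalty(read, ref, cfg,
                              at_left_edge=True, at_right_edge=True)
        assert got is not None and got[1] == want


def test_astar_pruning_neutrality():
    """A sufficient gap cap and a generous one return the same penalty."""
    rng = random.Random(42)
    for _ in range(25):
        ref = random_dna(rng, 200)
        read = ref[40:80] + random_dna(rng, rng.randint(1, 5)) + ref[80:120]
        window = ref[20:140]
        tight = astar_align(read, window, S1, max_gap=8)
        loose = astar_align(read, window, S1, max_gap=len(read))
        assert tight is not None and loose is not None
        assert tight[1] == loose[1]


def test_astar_respects_limit():
    ref = _rand(43, 100)
    read = list(ref[20:70])
    for i in (5, 15, 25, 35):
        read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
    read = "".join(read)
    assert astar_align(read, ref[10:90], S1, max_gap=5, limit=10) is None
    got = astar_align(read, ref[10:90], S1, max_gap=5, limit=24)
    assert got is not None and got[1] <= 24


# -- read-level orchestration ---------------------------------------------

def test_align_read_reports_both_cooptimal_copies():
    core = _rand(44, 3000)
    insert = _rand(45, 400)
    seq = core[:1000] + insert + core[1000:2000] + insert + core[2000:]
    idx = build_index([("r", seq)])
    read = insert[100:250]
    alns = align_read(read, idx, S1)
    assert len(alns) == 2
    assert all(a.penalty == 0 for a in alns)
    assert {a.pos for a in alns} == {1100, 2500}


def test_align_read_unaligned_above_max_penalty():
    seq = _rand(46, 5000)
    idx = build_index([("r", seq)])
    read = mutate_read(random.Random(47), seq[1000:1150], 0.25, 0.0)
    alns = align_read(read, idx, S1)
    maxp = max_allowed_penalty(len(read), S1)
    assert all(a.penalty <= maxp for a in alns)


def test_align_read_strand_symmetric(small_index, small_genome):
    rng = random.Random(48)
    for _ in range(10):
        p = rng.randrange(0, len(small_genome) - 150)
        read = mutate_read(rng, small_genome[p:p + 150], 0.02, 0.005)
        fwd = align_read(read, small_index, S1)
        rev = align_read(reverse_complement(read), small_index, S1)
        assert bool(fwd) == bool(rev)
        if fwd and rev:
            assert fwd[0].penalty == rev[0].penalty
            assert fwd[0].pos == rev[0].pos
            assert fwd[0].strand != rev[0].strand


def test_align_read_deterministic(small_index, small_genome):
    read = mutate_read(random.Random(49), small_genome[500:650], 0.03, 0.01)
    a = align_read(read, small_index, S1)
    b = align_read(read, small_index, S1)
    assert [(x.pos, x.strand, x.cigar, x.penalty) for x in a] == \
           [(x.pos, x.strand, x.cigar, x.penalty) for x in b]


def test_align_read_span_band_reports_suboptimal():
    seq = _rand(50, 4000)
    # plant a second, slightly mutated copy of a region
    region = seq[500:700]
    copy = list(region)
    copy[100] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[100]]
    seq = seq + "".join(copy)
    idx = build_index([("r", seq)])
    read = region[50:180]
    strict = align_read(read, idx, S1)
    assert len(strict) == 1 and strict[0].pos == 550
    wide = align_read(read, idx,
                      PenaltyConfig(max_penalty_span=6))
    assert len(wide) == 2
    assert sorted(a.penalty for a in wide) == [0, 6]


def test_extend_candidate_rejects_hopeless_offset():
    ref = _rand(51, 500)
    read = random_dna(random.Random(52), 100)    # unrelated read
    res = extend_candidate(read, ref, 200, S1, budget=12)
    assert res is None


def test_combined_pair_score_spacing_term():
    from xmeralign.align import combined_pair_score
    # at the expected insert size the pair score is just the sum
    assert combined_pair_score(6, 12, 400, 400, S1) == 18
    # snp_penalty per 100 bp of deviation by default
    assert combined_pair_score(0, 0, 500, 400, S1) == 6
    assert combined_pair_score(0, 0, 350, 400, S1) == 3
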