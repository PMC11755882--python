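"""Pyramid construction: determinism, coverage, size, symmetry, Fig-style
simplified-mode vectors."""

import random
from itertools import product

import pytest

from xmeralign.penalty import reverse_complement
from xmeralign.pyramid import (build_leaf_level, build_pyramid,
                               canonical_hash, expand_ambiguous, merge_level)


def _rand(rng, n):
    return "".join(rng.choices("ACGT", k=n))


# -- simplified-mode exact vectors ----------------------------------------

def test_simplified_leaf_hashcodes():
    groups = build_leaf_level("ACGT", simplified=True)
    assert [g[0].hashcode for g in groups] == [1, 2, 3, 4]


def test_simplified_child_hash_is_4_left_plus_right():
    groups = build_leaf_level("AC", simplified=True)   # hashes 1, 2
    children = merge_level(groups, simplified=True)
    assert len(children) == 1
    assert children[0][0].hashcode == 4 * 1 + 2


def test_simplified_merge_left_iff_A_plus_C_odd():
    # "A": one A -> odd -> requests left; "G": zero -> even -> right
    a = build_leaf_level("A", simplified=True)[0][0]
    g = build_leaf_level("G", simplified=True)[0][0]
    assert a.merge_request == "left"
    assert g.merge_request == "right"
    # "GA" (G requests right, so the pair merges): one A -> odd -> left
    child = merge_level(build_leaf_level("GA", simplified=True),
                        simplified=True)[0][0]
    assert child.merge_request == "left"
    # "GT": zero A+C -> even -> right
    child = merge_level(build_leaf_level("GT", simplified=True),
                        simplified=True)[0][0]
    assert child.merge_request == "right"


def test_simplified_gap_side_iff_A_plus_G_odd():
    child_ga = merge_level(build_leaf_level("GA", simplified=True),
                           simplified=True)[0][0]
    assert child_ga.gap_side == "right"      # A+G count = 2, even
    child_ta = merge_level(build_leaf_level("TA", simplified=True),
                           simplified=True)[0][0]
    assert child_ta.gap_side == "left"       # A+G count = 1, odd


def test_no_merge_when_neither_requests():
    # simplified: left x-mer even A+C (requests right)? build a pair where
    # left requests left and right requests right: left="A" (odd -> left),
    # right="G" (even -> right) -> no child from that pair
    groups = build_leaf_level("AG"[::-1], simplified=True)  # "GA"
    # left G requests right -> merges; use A then G instead
    groups = build_leaf_level("AG", simplified=True)
    # A requests left, G requests right: neither requests the other
    assert merge_level(groups, simplified=True) == []


# -- leaf level ------------------------------------------------------------

def test_leaf_level_one_xmer_per_position_distinct_directions():
    groups = build_leaf_level("ACGT")
    assert [g[0].start for g in groups] == [0, 1, 2, 3]
    combos = {(g[0].merge_request, g[0].descendant_recommendation)
              for g in groups}
    assert len(combos) == 4      # each base a different combination
    # canonical hashes pair complementary bases (A with T, C with G);
    # forward hashes are distinct per base
    hashes = {g[0].hashcode for g in groups}
    assert len(hashes) == 2
    assert groups[0][0].hashcode == groups[3][0].hashcode  # A ~ T
    assert groups[1][0].hashcode == groups[2][0].hashcode  # C ~ G
    assert len({g[0].fh for g in groups}) == 4


def test_leaf_level_single_base_and_empty():
    pyr = build_pyramid("A")
    assert pyr.n_levels == 1
    assert pyr.levels[0][0][0].start == 0
    assert build_leaf_level("") == []


def test_leaf_ambiguity_expands_to_variants():
    groups = build_leaf_level("ANT", ambiguity_limit=3)
    assert len(groups) == 3
    assert len(groups[1]) == 4       # N -> A, C, G, T variants
    assert len({v.fh for v in groups[1]}) == 4
    assert len({v.hashcode for v in groups[1]}) == 2  # canonical pairs A~T, C~G


# -- ambiguity windows -----------------------------------------------------

def test_expand_ambiguous_examples():
    assert sorted(expand_ambiguous("ANT", 3)) == ["AAT", "ACT", "AGT", "ATT"]
    assert expand_ambiguous("NNN", 3) is None          # 3 not < 3
    assert expand_ambiguous("ACG", 3) == ["ACG"]
    with pytest.raises(ValueError):
        expand_ambiguous("AXZ", 3)


# -- whole-pyramid properties ---------------------------------------------

def test_determinism_byte_identical():
    rng = random.Random(5)
    seq = _rand(rng, 2000)
    assert build_pyramid(seq).dump_tsv() == build_pyramid(seq).dump_tsv()


def test_identical_records_produce_identical_pyramids():
    rng = random.Random(6)
    seq = _rand(rng, 500)
    a, b = build_pyramid(seq, seq_id="a"), build_pyramid(seq, seq_id="b")
    assert a.dump_tsv() == b.dump_tsv()


def test_every_level_covers_contiguously():
    rng = random.Random(7)
    for _ in range(5):
        pyr = build_pyramid(_rand(rng, 1500))
        for lvl in range(pyr.n_levels):
            assert pyr.covers_contiguously(lvl)
        # edge shrinkage at each level is bounded by that level's max span
        for lvl in range(pyr.n_levels):
            lo, hi = pyr.coverage_span(lvl)
            longest = max(x.length for x in pyr.iter_xmers(lvl))
            assert lo <= longest and len(pyr.seq) - hi <= longest


def test_size_bound_under_4x():
    rng = random.Random(8)
    ratios = []
    for seed in range(8):
        seq = _rand(random.Random(seed), 10000)
        pyr = build_pyramid(seq)
        ratios.append(pyr.total_xmers() / len(seq))
    assert max(ratios) <= 4.0
    if max(ratios) > 3.99:        # headroom warning channel
        import warnings
        warnings.warn(f"x-mer ratio close to bound: {max(ratios):.3f}")


def test_merge_probability_approaches_three_quarters():
    """Leaf direction bits are uniform and independent, so ~3/4 of adjacent
    pairs merge (1 - 1/2 * 1/2); Monte Carlo within 3 sigma."""
    rng = random.Random(9)
    seq = _rand(rng, 100001)
    leaf = build_leaf_level(seq)
    merged = merge_level(leaf)
    n = len(leaf) - 1
    freq = len(merged) / n
    sigma = (0.75 * 0.25 / n) ** 0.5
    assert abs(freq - 0.75) <= 3 * sigma


def test_level_sizes_decay_geometrically():
    rng = random.Random(10)
    pyr = build_pyramid(_rand(rng, 8000))
    sizes = [len(l) for l in pyr.levels]
    for i in range(6):
        assert sizes[i + 1] < sizes[i]


def test_rc_symmetry_exhaustive_short():
    """Every x-mer of seq has an equal-hashcode partner from revcomp(seq)."""
    for n in range(1, 7):
        for tup in product("ACGT", repeat=n):
            s = "".join(tup)
            ha = sorted(x.hashcode for x in build_pyramid(s).iter_xmers())
            hb = sorted(x.hashcode
                        for x in build_pyramid(
                            reverse_complement(s)).iter_xmers())
            assert ha == hb, s


def test_rc_symmetry_sampled_length8():
    rng = random.Random(11)
    for _ in range(300):
        s = _rand(rng, 8)
        ha = sorted(x.hashcode for x in build_pyramid(s).iter_xmers())
        hb = sorted(x.hashcode
                    for x in build_pyramid(reverse_complement(s)).iter_xmers())
        assert ha == hb, s


def test_canonical_hash_rc_and_position_independence():
    assert canonical_hash("ACGT") == canonical_hash("ACGT")
    assert canonical_hash("AAAC") == canonical_hash("GTTT")
    for tup in product("ACGT", repeat=4):
        w = "".join(tup)
        assert canonical_hash(w) == canonical_hash(reverse_complement(w))


def test_hashcodes_position_independent():
    seq = "TTACGGACGTTT" + "GATTACA" + "CCGTACGGA" + "GATTACA" + "AAT"
    pyr = build_pyramid(seq)
    # x-mers with identical contents at the two GATTACA loci share hashcodes
    by_span = {}
    for x in pyr.iter_xmers():
        by_span.setdefault((x.length, seq[x.start:x.end]), set()).add(
            x.hashcode)
    for (_, contents), hashes in by_span.items():
        assert len(hashes) == 1, contents
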