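"""Evaluation rules: optimality comparison, cause taxonomy, consistency,
effective abundance."""

import random

import pytest

from xmeralign.align import align_read
from xmeralign.evaluate import (RunAlignment, classify_suboptimal,
                                compare_runs, consistency_eval,
                                effective_abundance, genome_breadth,
                                parse_sam_run)
from xmeralign.index import build_index
from xmeralign.penalty import PRESETS
from xmeralign.seqio import ReadRecord, write_sam

S1 = PRESETS["setting1"]


def _aln(seq_id="c", pos=100, strand="+", cigar="50M", penalty=0):
    return RunAlignment(seq_id, pos, strand, cigar, penalty)


def _runs(**kwargs):
    """kwargs: label -> {read_id: [RunAlignment, ...]}"""
    return kwargs


# -- compare_runs ----------------------------------------------------------

def test_identical_runs_have_zero_suboptimal_rate():
    runs = _runs(a={"r1": [_aln()], "r2": [_aln(pos=5)]},
                 b={"r1": [_aln()], "r2": [_aln(pos=5)]})
    cmps, rates = compare_runs(runs, total_reads=2)
    assert rates == {"a": 0.0, "b": 0.0}
    assert all(v == "optimal" for c in cmps for v in c.verdicts.values())


def test_higher_penalty_is_suboptimal():
    runs = _runs(a={"r1": [_aln(penalty=6)]},
                 b={"r1": [_aln(penalty=12)]})
    cmps, rates = compare_runs(runs, total_reads=1)
    assert cmps[0].verdicts == {"a": "optimal", "b": "suboptimal"}
    assert rates == {"a": 0.0, "b": 1.0}


def test_missing_read_counts_as_failed():
    runs = _runs(a={"r1": [_aln(penalty=6)]}, b={})
    cmps, rates = compare_runs(runs, total_reads=1)
    assert cmps[0].verdicts["b"] == "suboptimal"
    assert classify_suboptimal(cmps[0], "b") == "failed_to_align"


def test_compare_runs_symmetric_in_order():
    runs1 = _runs(a={"r1": [_aln(penalty=6)]}, b={"r1": [_aln(penalty=9)]})
    runs2 = _runs(b={"r1": [_aln(penalty=9)]}, a={"r1": [_aln(penalty=6)]})
    c1, _ = compare_runs(runs1, total_reads=1)
    c2, _ = compare_runs(runs2, total_reads=1)
    assert c1[0].verdicts == c2[0].verdicts


def test_single_run_suboptimal_rate_zero():
    runs = _runs(only={"r1": [_aln(penalty=42)], "r2": []})
    _, rates = compare_runs(runs, total_reads=2)
    assert rates == {"only": 0.0}


def test_middle_clip_filter_excludes_reads():
    clipped = _aln(cigar="10S40M", pos=500, penalty=10)
    runs = _runs(a={"r1": [clipped], "r2": [_aln()]},
                 b={"r1": [_aln()], "r2": [_aln()]})
    cmps, _ = compare_runs(runs, total_reads=2, ref_lens={"c": 10000},
                           filter_middle_clips_of="a")
    assert [c.read_id for c in cmps] == ["r2"]
    # clip at the contig edge is not a middle clip
    edge = _aln(cigar="10S40M", pos=0, penalty=10)
    runs = _runs(a={"r1": [edge]}, b={"r1": [_aln(pos=0)]})
    cmps, _ = compare_runs(runs, total_reads=1, ref_lens={"c": 10000},
                           filter_middle_clips_of="a")
    assert [c.read_id for c in cmps] == ["r1"]


# -- classification --------------------------------------------------------

def test_classification_taxonomy():
    opt = _aln(pos=1000, penalty=0)
    runs = _runs(best={"r": [opt]},
                 close={"r": [_aln(pos=1040, penalty=6)]},
                 same={"r": [_aln(pos=1000, penalty=12)]},
                 wrong={"r": [_aln(pos=5000, penalty=6)]},
                 gone={"r": []})
    cmps, _ = compare_runs(runs, total_reads=1)
    c = cmps[0]
    assert classify_suboptimal(c, "close") == "close_site"
    assert classify_suboptimal(c, "same") == "same_site_higher_penalty"
    assert classify_suboptimal(c, "wrong") == "wrong_site"
    assert classify_suboptimal(c, "gone") == "failed_to_align"
    with pytest.raises(ValueError):
        classify_suboptimal(c, "best")


def test_close_site_boundary_is_100bp():
    runs = _runs(best={"r": [_aln(pos=1000)]},
                 at100={"r": [_aln(pos=1100, penalty=6)]},
                 at101={"r": [_aln(pos=1101, penalty=6)]})
    cmps, _ = compare_runs(runs, total_reads=1)
    assert classify_suboptimal(cmps[0], "at100") == "close_site"
    assert classify_suboptimal(cmps[0], "at101") == "wrong_site"


# -- consistency -----------------------------------------------------------

def test_consistency_perfect_reproduction():
    simple = {"r1": [_aln(pos=10)], "r2": [_aln(pos=20)]}
    complexr = {"r1": [_aln(pos=10)], "r2": [_aln(pos=20)]}
    res = consistency_eval(simple, complexr)
    assert res["inconsistency"] == 0.0
    assert res["suboptimal_report_fraction"] == 0.0


def test_consistency_better_complex_alignment_is_consistent():
    simple = {"r1": [_aln(pos=10, penalty=6)]}
    complexr = {"r1": [_aln(seq_id="other", pos=99, penalty=0)]}
    res = consistency_eval(simple, complexr)
    assert res["inconsistency"] == 0.0


def test_consistency_lost_alignment_is_inconsistent():
    simple = {"r1": [_aln(pos=10)], "r2": [_aln(pos=20)]}
    complexr = {"r1": [_aln(pos=999, penalty=6)], "r2": [_aln(pos=20)]}
    res = consistency_eval(simple, complexr)
    assert res["inconsistency"] == pytest.approx(0.5)


def test_consistency_counts_suboptimal_reports():
    simple = {"r1": [_aln(pos=10)]}
    complexr = {"r1": [_aln(pos=10, penalty=0), _aln(pos=400, penalty=12)]}
    res = consistency_eval(simple, complexr)
    assert res["inconsistency"] == 0.0
    assert res["suboptimal_report_fraction"] == 1.0


# -- effective abundance ---------------------------------------------------

def test_abundance_unique_read():
    ab = effective_abundance({"r": ["A1"]}, {"A1": 0.9})
    assert ab == {"A1": 1.0}


def test_abundance_even_split_and_coverage_filter():
    cov = {"A1": 0.8, "G2": 0.5}
    ab = effective_abundance({"r": ["A1", "G2"]}, cov)
    assert ab == {"A1": 0.5, "G2": 0.5}
    cov = {"A1": 0.8, "G2": 0.02}
    ab = effective_abundance({"r": ["A1", "G2"]}, cov)
    assert ab == {"A1": 1.0}


def test_abundance_normalizes_to_one():
    reads = {"r1": ["A"], "r2": ["A", "B"], "r3": ["B"], "r4": ["C"]}
    cov = {"A": 1.0, "B": 1.0, "C": 0.01}
    ab = effective_abundance(reads, cov)
    assert sum(ab.values()) == pytest.approx(1.0)
    assert ab["A"] == pytest.approx(1.5 / 3)
    assert "C" not in ab


# -- SAM round trip through the evaluation parser --------------------------

def test_parse_sam_run_recomputes_penalties(tmp_path):
    rng = random.Random(71)
    genome = "".join(rng.choices("ACGT", k=6000))
    refs = [("chr", genome)]
    idx = build_index(refs)
    results = []
    for i in range(10):
        p = rng.randrange(0, len(genome) - 120)
        read = list(genome[p:p + 120])
        for j in range(120):
            if rng.random() < 0.03:
                read[j] = rng.choice([b for b in "ACGT" if b != read[j]])
        rec = ReadRecord(f"r{i}", "".join(read))
        results.append((rec, align_read(rec.sequence, idx, S1,
                                        read_id=rec.id)))
    sam = str(tmp_path / "run.sam")
    write_sam(results, refs, sam)
    parsed = parse_sam_run(sam, refs, S1)
    for rec, alns in results:
        got = parsed[rec.id]
        assert len(got) == len(alns)
        for a, b in zip(sorted(got, key=lambda x: x.pos),
                        sorted(alns, key=lambda x: x.pos)):
            assert a.penalty == b.penalty and a.pos == b.pos


def test_parse_sam_run_excludes_over_10pct_divergence(tmp_path):
    genome = "A" * 200 + "C" * 200
    refs = [("chr", genome)]
    sam = str(tmp_path / "d.sam")
    with open(sam, "w") as fh:
        fh.write("@HD\tVN:1.6\n@SQ\tSN:chr\tLN:400\n")
        # 20 mismatches on a 100 bp read: penalty 120 > 6*0.1*100
        fh.write("bad\t0\tchr\t1\t255\t100M\t*\t0\t0\t" +
                 "A" * 80 + "G" * 20 + "\t*\n")
        fh.write("good\t0\tchr\t1\t255\t100M\t*\t0\t0\t" +
                 "A" * 99 + "G" + "\t*\n")
    parsed = parse_sam_run(sam, refs, S1)
    assert parsed["bad"] == []
    assert len(parsed["good"]) == 1 and parsed["good"][0].penalty == 6


def test_genome_breadth():
    run = {"r1": [_aln(seq_id="g", pos=0, cigar="50M")],
           "r2": [_aln(seq_id="g", pos=25, cigar="50M")]}
    cov = genome_breadth(run, {"g": 100, "h": 50})
    assert cov["g"] == pytest.approx(0.75)
    assert cov["h"] == 0.0
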