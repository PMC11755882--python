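"""Candidate extension: penalty bounds, split/join, and exact A* alignment.

A candidate offset is turned into an end-to-end alignment in stages. The
ungapped alignment is final whenever its penalty is below the cost of a
single 1 bp gap. Otherwise short query *pieces* of length about
``log4(3L+1)+1`` are matched against the region around the candidate: every
nonoverlapping piece absent from the region implies at least one mutation,
which yields a lower penalty bound (offsets whose bound exceeds the budget
are rejected) and a cap on the longest gap any within-budget alignment can
contain. Splitting the query in half and re-aligning the halves provides an
upper bound (incumbent) when the halves land a gap-length apart. The final
answer comes from A* over a lazily materialized Needleman-Wunsch grid —
x-moves consume query bases, y-moves reference bases — with an admissible
suffix-piece heuristic and pruning of gap runs longer than the cap, so the
returned penalty equals the full-DP optimum exactly.

Reads overhanging contig ends receive end soft clips costed per base;
everything is scored with exact (integer-scaled rational) arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from heapq import heappush, heappop
from typing import Dict, List, Optional, Tuple

from .index import ReferenceIndex
from .penalty import (Event, PenaltyConfig, compare_bases, events_to_cigar,
                      max_allowed_penalty, reverse_complement, score_events,
                      _as_number)
from .search import (accumulate_offsets,
                     candidate_priority, optimistic_best, prove_optimal,
                     walk_query)


@dataclass
class Alignment:
    """One reported end-to-end alignment of a read."""
    seq_id: str
    ref_idx: int
    pos: int                  # 0-based reference start of the aligned part
    strand: str
    cigar: str
    events: List[Event]
    penalty: object           # int or Fraction
    read_id: str = ""
    is_reported: bool = True


# ---------------------------------------------------------------------------
# penalty-bound machinery
# ---------------------------------------------------------------------------

def piece_length(query_len: int) -> int:
    """Piece size for the mismatch bound: ~log4(3L+1)+1, floored, min 1."""
    if query_len < 1:
        raise ValueError("query length must be >= 1")
    return max(1, int(math.log(query_len * 3 + 1) / math.log(4) + 1 + 1e-9))


def mismatch_piece_bound(query: str, ref_region: str, piece_len: int) -> int:
    """Greedy count of nonoverlapping query pieces absent from the region.

    Each counted piece must contain at least one mutated base in any
    alignment placed within the region, so the count lower-bounds the
    mutation content of the optimal alignment there.
    """
    query = query.upper()
    ref_region = ref_region.upper()
    count, i = 0, 0
    while i + piece_len <= len(query):
        if query[i:i + piece_len] in ref_region:
            i += 1
        else:
            count += 1
            i += piece_len
    return count


def offset_rejected(budget, min_mutations: int, config: PenaltyConfig) -> bool:
    """Reject an offset whose piece bound alone exceeds the budget."""
    return min_mutations * config.snp_penalty > budget


def max_gap_length(budget, min_mutations: int, config: PenaltyConfig
                   ) -> Optional[int]:
    """Longest gap any within-budget alignment at this offset can contain.

    Reserves (min_mutations - 1) point mutations — one mutation may be the
    gap itself. Returns None when the offset is rejected outright and 0
    when only an ungapped alignment can fit the budget.
    """
    if offset_rejected(budget, min_mutations, config):
        return None
    ext = config.extend_indel_penalty
    reserve = max(0, min_mutations - 1) * config.snp_penalty
    room = budget - reserve - config.new_indel_penalty
    if room < 0:
        return 0
    if ext == 0:
        return 10 ** 6
    return int(room / ext)


# ---------------------------------------------------------------------------
# ungapped check and split/join
# ---------------------------------------------------------------------------

def ungapped_align(query: str, ref: str, offset: int, config: PenaltyConfig
                   ) -> Tuple[List[Event], object, bool]:
    """Base-by-base alignment at a fixed offset; clips only beyond contig ends.

    Returns (events, penalty, escalate); escalate means the penalty is at
    least the cost of one 1 bp gap, so indels must be checked.
    """
    events: List[Event] = []

    def push(kind: str, n: int = 1):
        if events and events[-1][0] == kind:
            events[-1] = (kind, events[-1][1] + n)
        else:
            events.append((kind, n))

    for qi in range(len(query)):
        ri = offset + qi
        if ri < 0 or ri >= len(ref):
            push("soft_clip")
        else:
            push(compare_bases(query[qi], ref[ri]))
    penalty = score_events(events, config) if events else 0
    return events, penalty, penalty >= config.gap_cost(1)


def _ungapped_penalty(query: str, window: str, config: PenaltyConfig):
    """Penalty of a gap-free, clip-free base-to-base comparison."""
    if len(query) != len(window):
        raise ValueError("length mismatch")
    total = Fraction(0)
    for a, b in zip(query, window):
        if a == b and a in "ACGT":
            continue
        kind = compare_bases(a, b)
        if kind == "mismatch":
            total += config.snp_penalty
        elif kind == "ambiguous_match":
            total += config.ambiguity_penalty
    return _as_number(total)


def split_and_join(query: str, ref: str, offset: int, config: PenaltyConfig,
                   max_gap: int
                   ) -> Tuple[Optional[Tuple[List[Event], object, int]], bool]:
    """Align the two query halves independently and re-join them.

    Each half is scanned ungapped over offsets within ``max_gap`` of the
    candidate. If the halves' best placements are adjacent (same offset) the
    joined alignment is the plain ungapped one; if they sit a small shift
    apart the halves are bridged with one gap of that length. Returns
    ``((events, penalty, pos), escalate)``; the joined alignment is exact
    for its own arrangement (penalty == score of the joined event list) but
    escalation to the exhaustive indel search still follows whenever the
    arrangement is not trivially optimal.
    """
    lq = len(query)
    if lq < 2 or max_gap < 1:
        return None, True
    mid = lq // 2
    best: List[Tuple[Optional[int], object]] = []
    for qoff, half in ((0, query[:mid]), (mid, query[mid:])):
        best_pen, best_o = None, None
        for d in range(-max_gap, max_gap + 1):
            lo = offset + d + qoff
            if lo < 0 or lo + len(half) > len(ref):
                continue
            pen = _ungapped_penalty(half, ref[lo:lo + len(half)], config)
            if best_pen is None or pen < best_pen or \
                    (pen == best_pen and abs(d) < abs(best_o - offset)):
                best_pen, best_o = pen, offset + d
        best.append((best_o, best_pen))
    (o1, _), (o2, _) = best
    if o1 is None or o2 is None:
        return None, True
    d = o2 - o1
    if d == 0:
        events, pen, escalate = ungapped_align(query, ref, o1, config)
        return (events, pen, max(o1, 0)), escalate
    if d > 0:     # halves a deletion apart
        ev1 = ungapped_align(query[:mid], ref, o1, config)[0]
        ev2, _, _ = ungapped_align(query[mid:], ref, o2 + mid, config)
        events = ev1 + [("deletion", d)] + ev2
    else:         # halves an insertion apart: first |d| bases of 2nd half
        k = -d
        if mid + k > lq:
            return None, True
        ev1 = ungapped_align(query[:mid], ref, o1, config)[0]
        ev2, _, _ = ungapped_align(query[mid + k:], ref, o1 + mid, config)
        events = ev1 + [("insertion", k)] + ev2
    pen = score_events(events, config)
    return (events, pen, max(o1, 0)), True


# ---------------------------------------------------------------------------
# exact A* over the lazy Needleman-Wunsch grid
# ---------------------------------------------------------------------------

class _Scale:
    """Integer scaling of all costs so the search runs on exact ints."""

    def __init__(self, config: PenaltyConfig, extra=()):
        vals = [config.snp_penalty, config.new_indel_penalty,
                config.extend_indel_penalty, config.ambiguity_penalty,
                config.soft_clip_per_base]
        vals += [Fraction(v) for v in extra if v is not None]
        scale = 1
        for v in vals:
            scale = scale * v.denominator // math.gcd(scale, v.denominator)
        self.scale = scale
        self.snp = int(config.snp_penalty * scale)
        self.open = int(config.new_indel_penalty * scale)
        self.ext = int(config.extend_indel_penalty * scale)
        self.amb = int(config.ambiguity_penalty * scale)
        self.clip = int(config.soft_clip_per_base * scale)

    def to_int(self, v) -> int:
        return int(Fraction(v) * self.scale)

    def back(self, v: int):
        return _as_number(Fraction(v, self.scale))


#: A* states: (qi, ri, kind, gap_run); kind 0 = match lane, 1 = insertion,
#: 2 = deletion, 3 = leading soft clip.
_M, _I, _D, _CLIP = 0, 1, 2, 3


def _diag_mismatches(sub: bytes, win):
    """Mismatch count of ``sub`` at every placement inside ``win`` (numpy)."""
    import numpy as np
    q = np.frombuffer(sub, dtype=np.uint8)
    views = np.lib.stride_tricks.sliding_window_view(win, len(q))
    return (views != q).sum(axis=1)


def _incumbent_scan(query: str, window: str, sc: "_Scale", max_gap: int):
    """Upper bound on the optimum from cheap restricted alignments.

    Considers every clip-free ungapped placement, and every placement of the
    two query halves bridged by one gap (the split/join family). Each
    considered arrangement is a valid alignment, so the minimum is a sound
    branch-and-bound incumbent. Returns a scaled int or None.
    """
    lq, lw = len(query), len(window)
    if lw < lq or lq < 2:
        return None
    if any(c not in "ACGT" for c in query) or \
            any(c not in "ACGT" for c in window):
        return None
    import numpy as np
    win = np.frombuffer(window.encode(), dtype=np.uint8)
    best = int(_diag_mismatches(query.encode(), win).min()) * sc.snp
    mid = lq // 2
    q1, q2 = query[:mid], query[mid:]
    pen1 = _diag_mismatches(q1.encode(), win) * sc.snp
    pen2 = _diag_mismatches(q2.encode(), win) * sc.snp
    gmax = min(max_gap, 60)
    # deletion of g reference bases between the halves
    for g in range(1, min(gmax, lw - lq) + 1):
        n = min(len(pen1), len(pen2) - mid - g)
        if n > 0:
            lo = pen1[:n] + pen2[mid + g:mid + g + n]
            best = min(best, int(lo.min()) + sc.open + g * sc.ext)
    # insertion: the first k bases of the second half are unaligned
    for k in range(1, min(gmax, len(q2) - 1) + 1):
        pk = _diag_mismatches(q2[k:].encode(), win) * sc.snp
        n = min(len(pen1), len(pk) - mid)
        if n > 0:
            lo = pen1[:n] + pk[mid:mid + n]
            best = min(best, int(lo.min()) + sc.open + k * sc.ext)
    return best


def astar_align(query: str, ref_window: str, config: PenaltyConfig,
                max_gap: int, *, limit=None, at_left_edge: bool = False,
                at_right_edge: bool = False
                ) -> Optional[Tuple[List[Event], object, int]]:
    """Minimum-penalty end-to-end path through the alignment grid.

    Grid cells are materialized lazily as the search reaches them. The
    heuristic (suffix piece bound times the cheapest per-mutation cost) is
    admissible, so the returned penalty equals the full-DP optimum; gap runs
    longer than ``max_gap`` are pruned. The window's unused leading/trailing
    reference bases are free; query bases can be soft-clipped only at contig
    ends (flags). Returns (events, penalty, window-relative reference start)
    or None when nothing scores within ``limit``.
    """
    query = query.upper()
    w = ref_window.upper()
    lq, lw = len(query), len(w)
    if lq == 0 or lw == 0:
        return None
    sc = _Scale(config, extra=[limit])
    lim = sc.to_int(limit) if limit is not None else None
    inc = _incumbent_scan(query, w, sc, max_gap)
    if inc is not None:
        # a valid-alignment upper bound: pruning keeps every optimal path
        lim = inc if lim is None else min(lim, inc)
    # the gap-run cap cannot bind when it exceeds both extents
    track_runs = max_gap < max(lq, lw)

    unit = sc.snp
    if max_gap > 0:
        unit = min(unit, sc.ext)
    if at_left_edge or at_right_edge:
        unit = min(unit, sc.clip)
    if any(c not in "ACGT" for c in w):
        unit = min(unit, sc.amb)

    # admissible suffix bound: disjoint window-absent pieces fully in [qi:]
    plen = piece_length(lq)
    hq = [0] * (lq + 1)
    if unit > 0 and lq >= plen:
        chosen: List[int] = []
        i = lq - plen
        while i >= 0:
            if query[i:i + plen] in w:
                i -= 1
            else:
                chosen.append(i)
                i -= plen
        acc = 0
        ci = 0  # chosen is sorted descending
        for qi in range(lq, -1, -1):
            while ci < len(chosen) and chosen[ci] >= qi:
                acc += unit
                ci += 1
            hq[qi] = acc

    cost_cache: Dict[Tuple[str, str], int] = {}

    def diag_cost(qc: str, rc: str) -> int:
        v = cost_cache.get((qc, rc))
        if v is None:
            kind = compare_bases(qc, rc)
            v = 0 if kind == "match" else (sc.snp if kind == "mismatch"
                                           else sc.amb)
            cost_cache[(qc, rc)] = v
        return v

    INF = 1 << 62
    nrun_dim = (max_gap + 1) if track_runs else 1
    row = (lw + 1) * 4 * nrun_dim
    dist: Dict[int, int] = {}
    # parent: key -> (prev_key or -1, move, qi_after, ri_after)
    parent: Dict[int, Tuple[int, str, int, int]] = {}
    heap: List[Tuple[int, int, int, int, int, int, int]] = []
    tie = 0

    def push_state(qi, ri, st, run, g, mv, prev_key):
        nonlocal tie
        key = qi * row + (ri * 4 + st) * nrun_dim + run
        if g < dist.get(key, INF):
            h = hq[qi]
            if lim is not None and g + h > lim:
                return
            dist[key] = g
            parent[key] = (prev_key, mv, qi, ri)
            heappush(heap, (g + h, tie, g, qi, ri, st, key))
            tie += 1

    for ri in range(lw + 1):
        push_state(0, ri, _M, 0, 0, "", -1)
    if at_left_edge:
        for qi in range(1, lq):
            g = qi * sc.clip
            if lim is not None and g + hq[qi] > lim:
                break
            push_state(qi, 0, _CLIP, 0, g, "S", -1)

    goal = None
    while heap:
        f, _, g, qi, ri, st, key = heappop(heap)
        if dist.get(key, INF) != g:
            continue
        if qi == lq:
            goal = key
            break
        run = key % nrun_dim if track_runs else 0
        if at_right_edge and ri == lw and qi > 0:
            push_state(lq, lw, _M, 0, g + (lq - qi) * sc.clip, "T", key)
        if ri < lw:
            push_state(qi + 1, ri + 1, _M, 0,
                       g + diag_cost(query[qi], w[ri]), "M", key)
        if max_gap > 0 and st != _CLIP:
            nrun = (run + 1 if st == _I else 1) if track_runs else 0
            if nrun <= max_gap:
                push_state(qi + 1, ri, _I, nrun,
                           g + sc.ext + (0 if st == _I else sc.open),
                           "I", key)
            if ri < lw and qi > 0:
                nrun = (run + 1 if st == _D else 1) if track_runs else 0
                if nrun <= max_gap:
                    push_state(qi, ri + 1, _D, nrun,
                               g + sc.ext + (0 if st == _D else sc.open),
                               "D", key)
    if goal is None:
        return None
    g = dist[goal]
    if lim is not None and g > lim:
        return None

    # traceback
    moves: List[Tuple[str, Tuple[int, int]]] = []
    cur = goal
    while cur != -1:
        prev, mv, tqi, tri = parent[cur]
        if mv:
            moves.append((mv, (tqi, tri)))
        cur = prev
    moves.reverse()

    events: List[Event] = []

    def push_ev(kind: str, n: int = 1):
        if events and events[-1][0] == kind:
            events[-1] = (kind, events[-1][1] + n)
        else:
            events.append((kind, n))

    qpos = 0
    ref_start: Optional[int] = None
    for mv, to in moves:
        if mv == "S":
            push_ev("soft_clip", to[0])
            qpos = to[0]
        elif mv == "T":
            push_ev("soft_clip", lq - qpos)
            qpos = lq
        elif mv == "M":
            if ref_start is None:
                ref_start = to[1] - 1
            push_ev(compare_bases(query[qpos], w[to[1] - 1]))
            qpos += 1
        elif mv == "I":
            push_ev("insertion")
            qpos += 1
        elif mv == "D":
            if ref_start is None:
                ref_start = to[1] - 1
            push_ev("deletion")
    if ref_start is None:
        return None  # degenerate: no reference base consumed
    return events, sc.back(g), ref_start


# ---------------------------------------------------------------------------
# per-candidate extension pipeline and the read-level orchestration
# ---------------------------------------------------------------------------

def extend_candidate(query: str, ref: str, offset: int,
                     config: PenaltyConfig, budget
                     ) -> Optional[Tuple[List[Event], object, int]]:
    """Best end-to-end alignment at one candidate offset within ``budget``.

    Returns (events, penalty, 0-based reference position) or None when the
    offset is rejected or nothing fits the budget.
    """
    lq = len(query)
    ev, pen, escalate = ungapped_align(query, ref, offset, config)
    if not escalate:
        return (ev, pen, max(offset, 0)) if pen <= budget else None

    plen = piece_length(lq)
    g0 = max_gap_length(budget, 0, config) or 0
    rs, re = max(0, offset - g0), min(len(ref), offset + lq + g0)
    if rs >= re:
        return None
    min_mut = mismatch_piece_bound(query, ref[rs:re], plen)
    mg = max_gap_length(budget, min_mut, config)
    if mg is None:
        return None                     # offset rejected outright
    if mg == 0:
        return (ev, pen, max(offset, 0)) if pen <= budget else None

    incumbent = (ev, pen, max(offset, 0))
    joined, _ = split_and_join(query, ref, offset, config, mg)
    if joined is not None and joined[1] < incumbent[1]:
        incumbent = joined
    limit = min(budget, incumbent[1])

    ws, we = max(0, offset - mg), min(len(ref), offset + lq + mg)
    res = astar_align(query, ref[ws:we], config, mg, limit=limit,
                      at_left_edge=(ws == 0), at_right_edge=(we == len(ref)))
    if res is not None:
        ev2, pen2, rel = res
        return ev2, pen2, ws + rel
    if incumbent[1] <= budget:
        return incumbent
    return None


def combined_pair_score(penalty1, penalty2, observed_insert: int,
                        expected_insert: int, config: PenaltyConfig, *,
                        spacing_per_100bp=None):
    """Combined score for a read pair: both penalties plus a spacing term.

    Mates are aligned independently; the spacing penalty grows with the
    deviation of the observed insert size from the expected one, scaled in
    proportion to the point-mutation penalty (by default snp_penalty per
    100 bp of deviation). The exact proportionality is a configuration
    knob, not a calibrated model.
    """
    if spacing_per_100bp is None:
        spacing_per_100bp = config.snp_penalty
    deviation = abs(observed_insert - expected_insert)
    return _as_number(Fraction(penalty1) + Fraction(penalty2)
                      + Fraction(spacing_per_100bp) * deviation / 100)


def align_read(query: str, index: ReferenceIndex, config: PenaltyConfig, *,
               read_id: str = "", tolerance: Optional[int] = None,
               max_candidates: int = 64,
               diagnostics: Optional[dict] = None) -> List[Alignment]:
    """Seed, search, and extend one read; return all reported alignments.

    Reports every alignment with penalty within ``max_penalty_span`` of the
    best (span 0 = co-optimal alignments only) and within the per-base
    maximum penalty. Deterministic; equal-penalty alignments are ordered by
    (reference id, position, strand).
    """
    query = query.upper()
    lq = len(query)
    if lq == 0:
        return []
    maxallow = max_allowed_penalty(lq, config)
    span = config.max_penalty_span
    if tolerance is None:
        tolerance = max_gap_length(maxallow, 0, config) or 0

    path = walk_query(query, index)
    clusters = accumulate_offsets(path, tolerance, min_support=1)
    cands = [c for c in clusters if c.support >= 2]
    if not cands:
        return []
    opt = optimistic_best(cands)
    ordered = candidate_priority(cands)
    if opt is not None:
        ordered = [opt] + [c for c in ordered if c is not opt]
    ordered = ordered[:max_candidates]

    ref_lens = [len(seq) for _, seq in index.refs]
    found: Dict[Tuple[int, int, str], Alignment] = {}
    best = None
    best_cluster = None
    for c in ordered:
        budget = maxallow if best is None else min(maxallow, best + span)
        rid, rseq = index.refs[c.ref_idx]
        q = query if c.strand == "+" else reverse_complement(query)
        res = extend_candidate(q, rseq, c.offset, config, budget)
        if res is not None:
            ev, pen, pos = res
            key = (c.ref_idx, pos, c.strand)
            prev = found.get(key)
            if prev is None or pen < prev.penalty:
                found[key] = Alignment(rid, c.ref_idx, pos, c.strand,
                                       events_to_cigar(ev), ev, pen, read_id)
            if best is None or pen < best:
                best, best_cluster = pen, c
        if best is not None and best_cluster is not None:
            if prove_optimal(best_cluster, path, clusters, best, config,
                             ref_lens=ref_lens, tolerance=tolerance):
                if diagnostics is not None:
                    diagnostics["proved_optimal"] = True
                    diagnostics["proved_penalty"] = best
                break
    if best is None:
        return []
    cutoff = min(maxallow, best + span)
    out = [a for a in found.values() if a.penalty <= cutoff]
    out.sort(key=lambda a: (a.penalty, a.seq_id, a.pos, a.strand))
    return out
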