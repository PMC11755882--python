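"""Adaptive walk of the query's x-mer pyramid and candidate-offset logic.

The walk starts at the first 1 bp x-mer and moves through the pyramid: a
seed that matches too many reference positions (more than its bin cap)
pushes the path up to longer seeds; a seed with an acceptable match count is
recorded and the path returns down-right to shorter seeds at the next
position. Matches are grouped into candidate *offsets* (reference position
minus query position); offsets supported by fewer than two seeds are
withheld, since singletons are often hash collisions.

The optimistic check returns the strict-majority candidate as soon as one
exists; ``prove_optimal`` certifies an alignment by lower-bounding every
alternative offset with the number of nonoverlapping recorded seeds that
have no match there (each such seed implies at least one mutation in any
alignment at that offset).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .index import ReferenceIndex, expand_to_gapped
from .penalty import PenaltyConfig
from .pyramid import build_pyramid


@dataclass
class SeedRecord:
    """One recorded (gapped) seed lookup along the walk."""
    step: int                 # walk step id (shared by ambiguity variants)
    q_start: int              # full gapped span in query coordinates
    q_end: int
    used_bp: int
    saturated: bool
    #: matches as (ref_idx, strand, offset); offsets for '-' are expressed
    #: in reverse-complemented-query coordinates.
    matches: List[Tuple[int, str, int]] = field(default_factory=list)


@dataclass
class SeedPath:
    """The walk's recorded seeds plus a debug trace."""
    records: List[SeedRecord] = field(default_factory=list)
    trace: List[Tuple[int, int, int, str]] = field(default_factory=list)
    query_len: int = 0

    @property
    def n_matches(self) -> int:
        return sum(len(r.matches) for r in self.records)


@dataclass
class CandidateOffset:
    """A clustered reference offset with its seed support."""
    ref_idx: int
    strand: str
    offset: int               # representative (modal) offset of the cluster
    support: int              # distinct seeds agreeing
    covered_query_bp: int
    discovered_rank: int
    lo: int                   # cluster offset range
    hi: int
    steps: frozenset = frozenset()


def walk_query(query: str, index: ReferenceIndex, *,
               max_steps: Optional[int] = None) -> SeedPath:
    """Adaptive pyramid walk of the query against the reference index."""
    query = query.upper()
    lq = len(query)
    path = SeedPath(query_len=lq)
    if lq == 0:
        return path
    if index.block_length is not None:
        return _walk_fixed(query, index, path)
    pyr = build_pyramid(query, simplified=index.simplified,
                        ambiguity_limit=index.ambiguity_limit,
                        max_span=lq)
    starts = [[g[0].start for g in level] for level in pyr.levels]
    lvl, pos = 0, 0
    step = 0
    budget_steps = max_steps if max_steps is not None else 40 * lq + 400
    while pos < lq and budget_steps > 0:
        budget_steps -= 1
        if lvl >= pyr.n_levels:
            lvl = pyr.n_levels - 1
        i = bisect_left(starts[lvl], pos)
        if i >= len(starts[lvl]):
            if lvl == 0:
                break
            lvl -= 1
            continue
        group = pyr.levels[lvl][i]
        node = group[0]
        if node.length < index.min_seed:
            # too short to be informative: necessarily matches everywhere
            path.trace.append((lvl, node.start, -1, "up"))
            if lvl + 1 < pyr.n_levels and \
                    bisect_left(starts[lvl + 1], node.start) < len(starts[lvl + 1]):
                lvl += 1
            else:
                pos = node.start + 1
            continue
        variants = []
        for xm in group:
            variants.extend(expand_to_gapped(
                xm, query, min_seed=index.min_seed,
                ambiguity_limit=index.ambiguity_limit,
                no_gap=index.no_gapmers, simplified=index.simplified))
        if not variants:
            # gapped form does not fit inside the query: skip right
            path.trace.append((lvl, node.start, -1, "skip"))
            pos = node.start + 1
            continue
        too_many = False
        recs = []
        for g in variants:
            entries, saturated = index.lookup(g.hashcode, g.used_bp,
                                              level=node.level)
            if saturated:
                too_many = True
                break
            rec = SeedRecord(step, g.anchor_start, g.span_end, g.used_bp,
                             saturated)
            span = g.total_span
            for ref_idx, rpos, ref_fwd in entries:
                if ref_fwd == g.winner_fwd:
                    rec.matches.append((ref_idx, "+", rpos - g.anchor_start))
                else:
                    rec.matches.append(
                        (ref_idx, "-", rpos - (lq - g.anchor_start - span)))
            recs.append(rec)
        if too_many:
            path.trace.append((lvl, node.start, -2, "up"))
            if lvl + 1 < pyr.n_levels and \
                    bisect_left(starts[lvl + 1], node.start) < len(starts[lvl + 1]):
                lvl += 1
            else:
                pos = node.start + 1
            continue
        path.records.extend(recs)
        n = sum(len(r.matches) for r in recs)
        path.trace.append((lvl, node.start, n, "down"))
        step += 1
        lvl = max(0, lvl - 1)
        pos = node.start + 1
    return path


def _walk_fixed(query: str, index: ReferenceIndex, path: SeedPath) -> SeedPath:
    """Fixed k-mer seeding (ablation mode): slide every k-mer of the query."""
    from .index import _simplified_hash
    from .pyramid import canonical_hash_winner, expand_ambiguous
    k = index.block_length
    lq = len(query)
    hashfn = _simplified_hash if index.simplified else canonical_hash_winner
    step = 0
    for pos in range(lq - k + 1):
        variants = expand_ambiguous(query[pos:pos + k], index.ambiguity_limit)
        if variants is None:
            continue
        for v in variants:
            h, fwd = hashfn(v)
            entries, saturated = index.lookup(h, k)
            rec = SeedRecord(step, pos, pos + k, k, saturated)
            if not saturated:
                for ref_idx, rpos, ref_fwd in entries:
                    if ref_fwd == fwd:
                        rec.matches.append((ref_idx, "+", rpos - pos))
                    else:
                        rec.matches.append((ref_idx, "-",
                                            rpos - (lq - pos - k)))
            path.records.append(rec)
        step += 1
    return path


def accumulate_offsets(path: SeedPath, tolerance: int = 0,
                       min_support: int = 2) -> List[CandidateOffset]:
    """Group seed matches into candidate offsets.

    Matches on the same reference and strand whose offsets lie within
    ``tolerance`` of each other are chained into one candidate (seeds
    separated by an indel disagree by the indel length). Candidates with
    fewer than ``min_support`` distinct supporting seeds are withheld.
    """
    entries: Dict[Tuple[int, str], List[Tuple[int, int, int]]] = {}
    rank = 0
    for ridx, rec in enumerate(path.records):
        for ref_idx, strand, off in rec.matches:
            entries.setdefault((ref_idx, strand), []).append(
                (off, rank, ridx))
            rank += 1
    out: List[CandidateOffset] = []
    for (ref_idx, strand), items in entries.items():
        items.sort()
        cluster: List[Tuple[int, int, int]] = []

        def flush():
            if not cluster:
                return
            steps = {path.records[ridx].step for _, _, ridx in cluster}
            counts: Dict[int, int] = {}
            for off, _, _ in cluster:
                counts[off] = counts.get(off, 0) + 1
            best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
            spans = sorted({(path.records[ridx].q_start,
                             path.records[ridx].q_end)
                            for _, _, ridx in cluster})
            covered, reach = 0, -1
            for a, b in spans:
                a = max(a, reach)
                if b > a:
                    covered += b - a
                    reach = b
                reach = max(reach, b)
            out.append(CandidateOffset(
                ref_idx, strand, best, len(steps), covered,
                min(r for _, r, _ in cluster),
                cluster[0][0], cluster[-1][0], frozenset(steps)))

        for item in items:
            if cluster and item[0] - cluster[-1][0] > tolerance:
                flush()
                cluster = []
            cluster.append(item)
        flush()
    out = [c for c in out if c.support >= min_support]
    out.sort(key=lambda c: (c.discovered_rank, -c.support, c.offset,
                            c.strand, c.ref_idx))
    return out


def candidate_priority(candidates: Sequence[CandidateOffset]
                       ) -> List[CandidateOffset]:
    """Earlier-discovered candidates first; ties by support then offset."""
    return sorted(candidates,
                  key=lambda c: (c.discovered_rank, -c.support, c.offset,
                                 c.strand, c.ref_idx))


def optimistic_best(candidates: Sequence[CandidateOffset]
                    ) -> Optional[CandidateOffset]:
    """The unique strict-majority candidate with >= 2 seed matches, if any."""
    if not candidates:
        return None
    top = max(c.support for c in candidates)
    if top < 2:
        return None
    winners = [c for c in candidates if c.support == top]
    return winners[0] if len(winners) == 1 else None


def _nonoverlap_count(records: Sequence[SeedRecord]) -> int:
    """Greedy maximum set of nonoverlapping seed spans (by earliest end)."""
    count, reach = 0, -1
    for rec in sorted(records, key=lambda r: r.q_end):
        if rec.q_start >= reach:
            count += 1
            reach = rec.q_end
    return count


def _matches_near(rec: SeedRecord, ref_idx: int, strand: str,
                  lo: int, hi: int) -> bool:
    return any(ri == ref_idx and st == strand and lo <= off <= hi
               for ri, st, off in rec.matches)


def prove_optimal(candidate: CandidateOffset, path: SeedPath,
                  clusters: Sequence[CandidateOffset],
                  current_penalty, config: PenaltyConfig, *,
                  ref_lens: Sequence[int], tolerance: int = 0) -> bool:
    """Certify that no other offset can beat ``current_penalty``.

    Sound: for every alternative offset the bound counts only seeds from
    unsaturated bins (whose match lists are complete); offsets where
    contig-edge soft clipping is possible get a discounted bound, because up
    to two seeds may straddle a clip boundary at below-snp cost. Never
    returns True when a strictly better alignment exists.
    """
    usable = [r for r in path.records if not r.saturated]
    if not usable:
        return False
    snp = config.snp_penalty
    lq = path.query_len

    def edge_capable(ref_idx: int, lo: int, hi: int) -> bool:
        margin = tolerance + lq
        return lo <= tolerance or hi >= ref_lens[ref_idx] - margin

    bounds = []
    # alternative candidate clusters (any support level)
    for c in clusters:
        if (c.ref_idx, c.strand) == (candidate.ref_idx, candidate.strand) \
                and not (c.hi < candidate.lo - tolerance
                         or c.lo > candidate.hi + tolerance):
            continue  # the candidate's own site
        non = [r for r in usable
               if not _matches_near(r, c.ref_idx, c.strand,
                                    c.lo - tolerance, c.hi + tolerance)]
        k = _nonoverlap_count(non)
        if edge_capable(c.ref_idx, c.lo, c.hi):
            k = max(0, k - 2)
        bounds.append(k * snp)
    # offsets never seen at all: no usable seed matched there
    k_all = _nonoverlap_count(usable)
    bounds.append(k_all * snp)            # unseen interior offsets
    # unseen offsets in contig-edge regions (clipping possible there)
    edge_free = []
    for r in usable:
        in_edge = False
        for ri, st, off in r.matches:
            margin = tolerance + lq
            if off <= tolerance or off >= ref_lens[ri] - margin:
                in_edge = True
                break
        if not in_edge:
            edge_free.append(r)
    bounds.append(max(0, _nonoverlap_count(edge_free) - 2) * snp)
    return min(bounds) > current_penalty


def alternative_bound(n_nonmatching_seeds: int, config: PenaltyConfig):
    """Lower bound on any alignment at an offset where the given number of
    nonoverlapping seeds found no match: one point mutation per seed."""
    return n_nonmatching_seeds * config.snp_penalty


def search_should_terminate(*, proved_optimal: bool,
                            no_candidate_within_budget: bool,
                            path_exhausted: bool) -> bool:
    """Stop when optimality is certified, no candidate can satisfy the
    penalty bound, or the x-mer path has reached the end of the query."""
    return proved_optimal or no_candidate_within_budget or path_exhausted
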