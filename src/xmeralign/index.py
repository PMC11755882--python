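"""Gapped x-mer expansion and the bin-capped reference hashtable.

An x-mer that is long enough to be informative is expanded into a *gapped
x-mer*: the original window, an ignored gap of about half its length, and a
post-gap extension of about the same length. The extra length is
``x + (hashcode mod 3)`` base pairs, split evenly (gap gets the ceiling);
the pseudorandom mod-3 term avoids systematically skipping certain seed
lengths. The gap extends left when the x-mer plans to merge right and vice
versa, and the gap contents never enter the hashcode, letting a seed skip
over clustered mutations.

Reference occurrences are stored in a hashtable keyed by (hashcode, used bp);
each bin accepts at most ``used_bp`` positions (configurable multiplier), so
repeats can never flood the table: a longer, rarer seed is allowed a deeper
bin than a short common one. Seeds shorter than ``min_seed_bp`` — which would
match about 16 random places in the reference — are never generated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .pyramid import (XMer, build_pyramid, canonical_hash_winner,
                      expand_ambiguous, _BASE_CODE)


def min_seed_bp(ref_total_len: int, target_matches: int = 16) -> int:
    """Smallest b with ``ref_total_len / 4**b <= target_matches``.

    Seeds using fewer base pairs than this are expected to match too many
    places in a random reference and are not generated.
    """
    if ref_total_len < 1:
        raise ValueError("reference length must be >= 1")
    b = 0
    while ref_total_len > target_matches * (4 ** b):
        b += 1
    return b


def bin_cap(used_bp: int, multiplier: int = 1) -> int:
    """Maximum positions stored per bin: the seed's used bp (times multiplier)."""
    if used_bp < 1:
        raise ValueError("used_bp must be >= 1")
    return used_bp * multiplier


def _simplified_hash(contents: str) -> Tuple[int, bool]:
    h = 0
    for c in contents:
        h = h * 4 + _BASE_CODE[c]
    return h, True


@dataclass(frozen=True)
class GappedXMer:
    """An x-mer plus gap plus post-gap extension; the unit stored/looked up.

    ``anchor_start`` is the 0-based start of the full span (including gap and
    extension); the hashcode covers the non-gap contents only.
    """

    seq_id: str
    anchor_start: int
    pre_len: int
    gap_len: int
    post_len: int
    gap_side: str          # side of the gap relative to the original x-mer
    hashcode: int
    winner_fwd: bool = True  # which orientation won the canonical hash

    @property
    def used_bp(self) -> int:
        return self.pre_len + self.post_len

    @property
    def total_span(self) -> int:
        return self.pre_len + self.gap_len + self.post_len

    @property
    def span_end(self) -> int:
        return self.anchor_start + self.total_span


def gap_split(extra: int) -> Tuple[int, int]:
    """Split the extra bp evenly: gap gets the ceiling, extension the floor."""
    gap = (extra + 1) // 2
    return gap, extra - gap


def expand_to_gapped(xmer: XMer, seq: str, *, seq_id: str = "",
                     min_seed: int = 1, ambiguity_limit: int = 3,
                     no_gap: bool = False,
                     simplified: bool = False) -> List[GappedXMer]:
    """Expand one x-mer into its gapped form(s), or [] when skipped.

    Returns a list because (a) ambiguity codes in the used contents expand
    into concrete variants and (b) a reverse-complement-palindromic x-mer has
    no preferred side and emits a gapped form on both sides.
    """
    x = xmer.length
    if x < min_seed:
        return []
    s = xmer.start
    hashfn = _simplified_hash if simplified else canonical_hash_winner

    def make(contents_parts, anchor, gap_len, post_len, side):
        used = "".join(contents_parts)
        variants = expand_ambiguous(used, max(0, ambiguity_limit - xmer.n_ambig))
        if variants is None:
            return []
        out = []
        for v in variants:
            h, fwd = hashfn(v)
            out.append(GappedXMer(seq_id, anchor, x, gap_len, post_len, side,
                                  h, fwd))
        return out

    if no_gap:
        return make([xmer.contents(seq)], s, 0, 0, "none")

    extra = x + (xmer.hashcode % 3)
    gap_len, post_len = gap_split(extra)
    sides = [xmer.gap_side]
    if not simplified and xmer.is_palindromic:
        sides = ["left", "right"]

    out: List[GappedXMer] = []
    core = xmer.contents(seq)
    for side in sides:
        if side == "left":
            anchor = s - extra
            if anchor < 0:
                continue
            post = seq[anchor:anchor + post_len].upper()
            out.extend(make([post, core], anchor, gap_len, post_len, "left"))
        else:
            end = s + x + extra
            if end > len(seq):
                continue
            post = seq[end - post_len:end].upper()
            out.extend(make([core, post], s, gap_len, post_len, "right"))
    return out


class ReferenceIndex:
    """Bin-capped hashtable of gapped x-mer occurrences, lazily extensible.

    Entries are ``(ref_idx, anchor_start, winner_fwd)``; the canonical
    (reverse-complement-symmetric) hash means one stored orientation serves
    both strands.
    """

    def __init__(self, refs: Sequence[Tuple[str, str]], *,
                 simplified: bool = False, ambiguity_limit: int = 3,
                 no_gapmers: bool = False, block_length: Optional[int] = None,
                 cap_multiplier: int = 1, target_matches: int = 16,
                 max_span: Optional[int] = 512):
        if not refs:
            raise ValueError("at least one reference record is required")
        self.refs = [(rid, seq.upper()) for rid, seq in refs]
        self.simplified = simplified
        self.ambiguity_limit = ambiguity_limit
        self.no_gapmers = no_gapmers
        self.block_length = block_length
        self.cap_multiplier = cap_multiplier
        self.max_span = max_span
        self.total_len = sum(len(s) for _, s in self.refs)
        self.min_seed = min_seed_bp(self.total_len, target_matches)
        self.bins: Dict[Tuple[int, int], List[Tuple[int, int, bool]]] = {}
        self.built_levels = 0
        self._finished = False
        if block_length is not None:
            self._build_fixed()
        else:
            self.pyramids = [
                build_pyramid(seq, max_level=0, simplified=simplified,
                              ambiguity_limit=ambiguity_limit,
                              max_span=max_span, seq_id=rid)
                for rid, seq in self.refs
            ]

    # -- construction ------------------------------------------------------
    def _insert(self, key: Tuple[int, int], entry: Tuple[int, int, bool]):
        cap = bin_cap(key[1], self.cap_multiplier)
        slot = self.bins.setdefault(key, [])
        if len(slot) < cap:
            slot.append(entry)

    def _build_fixed(self):
        """Fixed k-mer mode (seed-size ablations): index every k-mer."""
        k = self.block_length
        hashfn = _simplified_hash if self.simplified else canonical_hash_winner
        for ref_idx, (_, seq) in enumerate(self.refs):
            for pos in range(len(seq) - k + 1):
                variants = expand_ambiguous(seq[pos:pos + k],
                                            self.ambiguity_limit)
                if variants is None:
                    continue
                for v in variants:
                    h, fwd = hashfn(v)
                    self._insert((h, k), (ref_idx, pos, fwd))
        self._finished = True

    def extend_index_level(self) -> bool:
        """Build and insert exactly one more pyramid level across all refs.

        After any number of lazy extensions, lookups equal those on an
        eagerly built index (same per-level, per-reference insertion order).
        """
        if self._finished:
            return False
        level = self.built_levels
        any_nodes = False
        for ref_idx, pyr in enumerate(self.pyramids):
            while pyr.n_levels <= level:
                if not pyr.extend_one_level():
                    break
            if pyr.n_levels <= level:
                continue
            rid, seq = self.refs[ref_idx]
            for group in pyr.levels[level]:
                for xm in group:
                    any_nodes = True
                    for g in expand_to_gapped(
                            xm, seq, seq_id=rid, min_seed=self.min_seed,
                            ambiguity_limit=self.ambiguity_limit,
                            no_gap=self.no_gapmers,
                            simplified=self.simplified):
                        self._insert((g.hashcode, g.used_bp),
                                     (ref_idx, g.anchor_start, g.winner_fwd))
        self.built_levels += 1
        if not any_nodes:
            self._finished = True
            return False
        return True

    def ensure_level(self, level: int):
        while self.built_levels <= level and self.extend_index_level():
            pass

    def build_all(self):
        while self.extend_index_level():
            pass

    # -- queries -----------------------------------------------------------
    def lookup(self, hashcode: int, used_bp: int,
               level: Optional[int] = None
               ) -> Tuple[List[Tuple[int, int, bool]], bool]:
        """Positions stored for (hashcode, used bp class) and a saturation flag.

        May include hash-collision false positives; callers verify. If the
        requested pyramid ``level`` has not been built yet, it is built
        lazily first.
        """
        if level is not None:
            self.ensure_level(level)
        entries = self.bins.get((hashcode, used_bp), [])
        return entries, len(entries) >= bin_cap(used_bp, self.cap_multiplier)

    def walk_cap(self, used_bp: int) -> int:
        """Maximum acceptable match count during the query walk."""
        return bin_cap(used_bp, self.cap_multiplier)

    def stats(self) -> dict:
        n_pos = sum(len(v) for v in self.bins.values())
        return {
            "references": len(self.refs),
            "total_ref_bp": self.total_len,
            "min_seed_bp": self.min_seed,
            "bins": len(self.bins),
            "stored_positions": n_pos,
            "built_levels": self.built_levels,
        }


def build_index(refs: Sequence[Tuple[str, str]], *, eager: bool = True,
                **kwargs) -> ReferenceIndex:
    """Build a reference index (all levels up-front unless ``eager=False``)."""
    idx = ReferenceIndex(refs, **kwargs)
    if eager and idx.block_length is None:
        idx.build_all()
    return idx
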