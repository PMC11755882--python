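"""Deterministic pyramid of variable-length x-mers over a sequence.

Level 0 holds one x-mer per base. Each following level is formed by visiting
every pair of adjacent x-mers and merging the pair whenever either member
requests to merge toward the other; with direction bits behaving uniformly
this keeps roughly 3/4 of adjacent pairs per level, so level sizes decay
geometrically and the whole pyramid holds fewer than about 4n x-mers.

All merge decisions, hashcodes and gap plans are pure functions of the base
contents, never of position or of any RNG, so identical windows anywhere
(reference or query) grow identical sub-pyramids. Hashes and directions are
tracked for both orientations and resolved canonically so that a window and
its reverse complement always expose the same hashcode.

Two hashing modes exist: ``production`` (64-bit mixed hashes, fixed leaf
direction table) and ``simplified`` (the didactic scheme: leaf hashes
A=1..T=4, child hash = 4*left + right, merge-left iff #A+#C is odd,
gap-left iff #A+#G is odd), kept for exact small test vectors.
"""

from __future__ import annotations

import hashlib
from itertools import product
from typing import Iterator, List, Optional, Sequence, Tuple

from .penalty import IUPAC, reverse_complement

LEFT, RIGHT = 0, 1
_DIR_NAME = {LEFT: "left", RIGHT: "right"}

_MASK = (1 << 64) - 1
_BASE_CODE = {"A": 1, "C": 2, "G": 3, "T": 4}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Leaf (merge_request, descendant_recommendation) table, production mode.
# Each concrete base gets a distinct combination.
_LEAF_DIRS = {"A": (LEFT, LEFT), "C": (LEFT, RIGHT),
              "G": (RIGHT, LEFT), "T": (RIGHT, RIGHT)}


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK
    z = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK
    return z ^ (z >> 31)


def _combine(a: int, b: int) -> int:
    """Order-sensitive 64-bit mix of two child hashcodes."""
    return _splitmix64((a * 0x9E3779B97F4A7C15 + b * 0xC2B2AE3D27D4EB4F) & _MASK)


_LEAF_HASH = {b: _splitmix64(c) for b, c in _BASE_CODE.items()}


def string_hash(contents: str) -> int:
    """64-bit content hash of a concrete window (one orientation)."""
    return int.from_bytes(
        hashlib.blake2b(contents.encode(), digest_size=8).digest(), "big")


def canonical_hash_winner(contents: str) -> Tuple[int, bool]:
    """Canonical (orientation-independent) hash plus which orientation won.

    Returns ``(hash, forward_won)``; ties (reverse-complement palindromes)
    resolve to the forward orientation.
    """
    hf = string_hash(contents)
    hr = string_hash(reverse_complement(contents))
    return (hf, True) if hf >= hr else (hr, False)


def canonical_hash(contents: str) -> int:
    """Content hash equal for a window and its reverse complement."""
    return canonical_hash_winner(contents)[0]


def expand_ambiguous(window: str, limit: int = 3) -> Optional[List[str]]:
    """Cartesian expansion of ambiguity codes, or None (skip) at the limit.

    A window is expanded only while its number of ambiguous positions is
    strictly below ``limit``; otherwise no x-mer is generated for it.
    """
    if limit < 0:
        raise ValueError("limit must be >= 0")
    window = window.upper()
    ambig = [i for i, c in enumerate(window) if c not in _BASE_CODE]
    for i in ambig:
        if window[i] not in IUPAC:
            raise ValueError(f"unknown base {window[i]!r} in window")
    if len(ambig) >= limit:
        return None
    if not ambig:
        return [window]
    out = []
    choices = [IUPAC[window[i]] for i in ambig]
    chars = list(window)
    for combo in product(*choices):
        for i, b in zip(ambig, combo):
            chars[i] = b
        out.append("".join(chars))
    return out


class XMer:
    """One x-mer: a located window with hash and merge-direction plan.

    ``hashcode``, ``merge_request`` and ``descendant_recommendation`` are the
    canonical (orientation-resolved) values; the per-orientation state is kept
    internally so children can be derived purely per orientation.
    """

    __slots__ = ("start", "length", "level", "n_ambig", "subs",
                 "fh", "freq", "frec", "rh", "rreq", "rrec", "acp", "agp",
                 "simplified")

    def __init__(self, start, length, level, fh, freq, frec, rh, rreq, rrec,
                 acp=0, agp=0, n_ambig=0, subs=None, simplified=False):
        self.start = start
        self.length = length
        self.level = level
        self.fh = fh
        self.freq = freq
        self.frec = frec
        self.rh = rh
        self.rreq = rreq
        self.rrec = rrec
        self.acp = acp
        self.agp = agp
        self.n_ambig = n_ambig
        self.subs = subs
        self.simplified = simplified

    # -- canonical exposure ------------------------------------------------
    def _canon(self) -> Tuple[int, int, int]:
        if self.simplified:
            req = LEFT if self.acp & 1 else RIGHT
            return self.fh, req, req
        if self.fh >= self.rh:
            return self.fh, self.freq, self.frec
        return self.rh, 1 - self.rreq, 1 - self.rrec

    @property
    def hashcode(self) -> int:
        return self._canon()[0]

    @property
    def is_palindromic(self) -> bool:
        """True when both orientation hashes tie (reverse-complement palindrome).

        Such an x-mer has no consistent mirror-image direction, so it requests
        to merge in both directions; this keeps merge events exactly
        symmetric between a sequence and its reverse complement.
        """
        return (not self.simplified) and self.fh == self.rh

    @property
    def requests_left(self) -> bool:
        return self.is_palindromic or self._canon()[1] == LEFT

    @property
    def requests_right(self) -> bool:
        return self.is_palindromic or self._canon()[1] == RIGHT

    @property
    def merge_request(self) -> str:
        return _DIR_NAME[self._canon()[1]]

    @property
    def descendant_recommendation(self) -> str:
        return _DIR_NAME[self._canon()[2]]

    @property
    def gap_side(self) -> str:
        """Side the gap extends when this x-mer becomes a gapped x-mer.

        Opposite of the planned merge direction in production mode; in
        simplified mode, left iff the count of A's plus G's is odd.
        """
        if self.simplified:
            return "left" if self.agp & 1 else "right"
        return "left" if self._canon()[1] == RIGHT else "right"

    @property
    def end(self) -> int:
        return self.start + self.length

    def contents(self, seq: str) -> str:
        """Concrete window contents (ambiguity substitutions applied)."""
        w = seq[self.start:self.end].upper()
        if self.subs:
            chars = list(w)
            for pos, base in self.subs:
                chars[pos - self.start] = base
            w = "".join(chars)
        return w

    def __repr__(self):
        return (f"XMer(start={self.start}, len={self.length}, "
                f"level={self.level}, hash={self.hashcode})")


#: A group of variant x-mers sharing one span (singleton unless the span
#: covers ambiguity codes).
Group = List[XMer]


def _leaf(base: str, pos: int, simplified: bool, n_ambig: int,
          subs) -> XMer:
    if simplified:
        code = _BASE_CODE[base]
        return XMer(pos, 1, 0, code, 0, 0, code, 0, 0,
                    acp=int(base in "AC"), agp=int(base in "AG"),
                    n_ambig=n_ambig, subs=subs, simplified=True)
    freq, frec = _LEAF_DIRS[base]
    comp = _COMP[base]
    rreq, rrec = _LEAF_DIRS[comp]
    return XMer(pos, 1, 0, _LEAF_HASH[base], freq, frec,
                _LEAF_HASH[comp], rreq, rrec,
                acp=int(base in "AC"), agp=int(base in "AG"),
                n_ambig=n_ambig, subs=subs)


def build_leaf_level(seq: str, *, simplified: bool = False,
                     ambiguity_limit: int = 3) -> List[Group]:
    """One x-mer per position; ambiguity codes expand into concrete variants."""
    levels: List[Group] = []
    seq = seq.upper()
    for pos, c in enumerate(seq):
        if c in _BASE_CODE:
            levels.append([_leaf(c, pos, simplified, 0, None)])
            continue
        bases = IUPAC.get(c)
        if bases is None:
            raise ValueError(f"unknown base {c!r} at position {pos}")
        if 1 >= ambiguity_limit:
            continue  # too ambiguous: no x-mer for this position
        levels.append([_leaf(b, pos, simplified, 1, ((pos, b),))
                       for b in bases])
    return levels


def _merge_pair(ln: XMer, rn: XMer, level: int, simplified: bool) -> XMer:
    start = ln.start
    length = rn.end - ln.start
    subs = None
    if ln.subs or rn.subs:
        subs = tuple(sorted(set((ln.subs or ()) + (rn.subs or ()))))
    if simplified:
        h = 4 * ln.fh + rn.fh
        return XMer(start, length, level, h, 0, 0, h, 0, 0,
                    acp=ln.acp ^ rn.acp, agp=ln.agp ^ rn.agp,
                    n_ambig=ln.n_ambig + rn.n_ambig, subs=subs,
                    simplified=True)
    # A recommendation is expressed in its holder's own frame; a child reads
    # the right-hand member's bit mirrored. This keeps the direction bits of
    # children that share a parent decorrelated, which is what sustains the
    # ~3/4 merge rate (and hence the <~4n total size) at every level.
    # forward orientation: left parent wins ties
    fh = _combine(ln.fh, rn.fh)
    lbit, rbit = ln.frec, rn.frec ^ 1
    if ln.fh >= rn.fh:
        freq, frec = lbit, rbit
    else:
        freq, frec = rbit, lbit
    # reverse orientation: parents swap; the rc-left member is ``rn``
    rh = _combine(rn.rh, ln.rh)
    lbit_r, rbit_r = rn.rrec, ln.rrec ^ 1
    if rn.rh >= ln.rh:
        rreq, rrec = lbit_r, rbit_r
    else:
        rreq, rrec = rbit_r, lbit_r
    return XMer(start, length, level, fh, freq, frec, rh, rreq, rrec,
                acp=ln.acp ^ rn.acp, agp=ln.agp ^ rn.agp,
                n_ambig=ln.n_ambig + rn.n_ambig, subs=subs)


def merge_level(level: Sequence[Group], *, simplified: bool = False,
                ambiguity_limit: int = 3,
                max_span: Optional[int] = None) -> List[Group]:
    """Merge adjacent x-mer pairs into the next level.

    A pair produces a child iff the left member requests right OR the right
    member requests left, so every non-edge x-mer is guaranteed a child.
    """
    nxt: List[Group] = []
    next_level_idx = (level[0][0].level + 1) if level else 1
    for lg, rg in zip(level, level[1:]):
        span = rg[0].end - lg[0].start
        if max_span is not None and span > max_span:
            continue
        group: Group = []
        for ln in lg:
            for rn in rg:
                if ln.n_ambig + rn.n_ambig >= ambiguity_limit and \
                        (ln.n_ambig + rn.n_ambig) > 0:
                    continue
                if ln.requests_right or rn.requests_left:
                    group.append(_merge_pair(ln, rn, next_level_idx,
                                             simplified))
        if group:
            nxt.append(group)
    return nxt


class Pyramid:
    """All levels of x-mers over one sequence."""

    def __init__(self, seq: str, levels: List[List[Group]], *,
                 simplified: bool = False, ambiguity_limit: int = 3,
                 max_span: Optional[int] = None, seq_id: str = ""):
        self.seq = seq.upper()
        self.levels = levels
        self.simplified = simplified
        self.ambiguity_limit = ambiguity_limit
        self.max_span = max_span
        self.seq_id = seq_id

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def extend_one_level(self) -> bool:
        """Build one more level; returns False when the pyramid is finished."""
        if not self.levels or len(self.levels[-1]) <= 1:
            return False
        nxt = merge_level(self.levels[-1], simplified=self.simplified,
                          ambiguity_limit=self.ambiguity_limit,
                          max_span=self.max_span)
        if not nxt:
            return False
        self.levels.append(nxt)
        return True

    def iter_xmers(self, level: Optional[int] = None) -> Iterator[XMer]:
        levels = self.levels if level is None else [self.levels[level]]
        for lev in levels:
            for group in lev:
                yield from group

    def total_xmers(self) -> int:
        return sum(len(g) for lev in self.levels for g in lev)

    def coverage_span(self, level: int) -> Tuple[int, int]:
        lev = self.levels[level]
        return lev[0][0].start, lev[-1][0].end

    def covers_contiguously(self, level: int) -> bool:
        """True iff the level's x-mer spans leave no internal hole."""
        reach = None
        for group in self.levels[level]:
            node = group[0]
            if reach is not None and node.start > reach:
                return False
            reach = node.end if reach is None else max(reach, node.end)
        return True

    def dump_tsv(self) -> str:
        """Debug dump: level, start, length, hashcode, directions."""
        lines = ["level\tstart\tlength\thashcode\tmerge_request\trecommendation"]
        for x in self.iter_xmers():
            lines.append(f"{x.level}\t{x.start}\t{x.length}\t{x.hashcode}\t"
                         f"{x.merge_request}\t{x.descendant_recommendation}")
        return "\n".join(lines)


def build_pyramid(seq: str, max_level: Optional[int] = None, *,
                  simplified: bool = False, ambiguity_limit: int = 3,
                  max_span: Optional[int] = None, seq_id: str = "") -> Pyramid:
    """Build the full pyramid (or up to ``max_level`` / ``max_span``).

    Deterministic: identical input always yields an identical pyramid.
    """
    leaf = build_leaf_level(seq, simplified=simplified,
                            ambiguity_limit=ambiguity_limit)
    levels = [leaf] if leaf else []
    pyr = Pyramid(seq, levels, simplified=simplified,
                  ambiguity_limit=ambiguity_limit, max_span=max_span,
                  seq_id=seq_id)
    while (max_level is None or pyr.n_levels < max_level + 1):
        if not pyr.extend_one_level():
            break
    return pyr
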