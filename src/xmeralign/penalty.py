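"""Alignment penalty model.

An alignment is scored as an additive penalty over its events: mismatches,
ambiguous-base matches, gaps (open plus a per-base extension applied to every
gap base, including the first) and soft-clipped bases. Matches cost nothing;
lower is better. A read is reportable only if its total penalty does not
exceed ``max_penalty`` times the read length.

Penalties are kept as exact rationals so that optimal/suboptimal verdicts are
bit-stable; with the integer presets all totals are plain integers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, List, Sequence, Tuple, Union

Number = Union[int, float, str, Fraction]

#: Ordered event list: (kind, length) pairs.
Event = Tuple[str, int]

EVENT_KINDS = frozenset(
    {"match", "mismatch", "ambiguous_match", "insertion", "deletion", "soft_clip"}
)
_GAP_KINDS = frozenset({"insertion", "deletion"})
_QUERY_CONSUMING = frozenset(
    {"match", "mismatch", "ambiguous_match", "insertion", "soft_clip"}
)

# IUPAC nucleotide codes -> set of concrete bases they denote.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
IUPAC_SETS = {code: frozenset(bases) for code, bases in IUPAC.items()}

_COMPLEMENT = str.maketrans("ACGTUacgtuRYSWKMBDHVNryswkmbdhvn",
                            "TGCAAtgcaaYRSWMKVHDBNyrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _as_fraction(x: Number) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        # Go through the decimal string so 0.6 means six tenths exactly.
        return Fraction(repr(x))
    return Fraction(x)


def _as_number(f: Fraction):
    """Return an int when the fraction is integral, else the Fraction."""
    return int(f) if f.denominator == 1 else f


@dataclass(frozen=True)
class PenaltyConfig:
    """Penalty settings for end-to-end short-read alignment.

    ``max_penalty`` is interpreted per query base: the acceptance bound for a
    read of length L is ``max_penalty * L``. ``max_penalty_span`` is the band
    above the best penalty within which additional alignments are reported
    (0 = co-optimal alignments only).
    """

    snp_penalty: Fraction = field(default=Fraction(6))
    new_indel_penalty: Fraction = field(default=Fraction(5))
    extend_indel_penalty: Fraction = field(default=Fraction(3))
    ambiguity_penalty: Fraction = field(default=Fraction(1))
    soft_clip_per_base: Fraction = field(default=Fraction(1))
    max_penalty: Fraction = field(default=Fraction(6, 10))
    max_penalty_span: Fraction = field(default=Fraction(0))

    def __post_init__(self):
        for name in ("snp_penalty", "new_indel_penalty", "extend_indel_penalty",
                     "ambiguity_penalty", "soft_clip_per_base", "max_penalty",
                     "max_penalty_span"):
            value = _as_fraction(getattr(self, name))
            if value < 0:
                raise ValueError(f"{name} must be nonnegative, got {value}")
            object.__setattr__(self, name, value)

    def gap_cost(self, length: int) -> Fraction:
        """Cost of one gap of ``length`` bases: open + extend per gap base."""
        if length < 1:
            raise ValueError("gap length must be >= 1")
        return self.new_indel_penalty + length * self.extend_indel_penalty


#: The four named presets used throughout the evaluation (default settings of
#: Bowtie2, BWA, this aligner, and Minimap2 respectively).
PRESETS = {
    "setting1": PenaltyConfig(snp_penalty=6, new_indel_penalty=5,
                              extend_indel_penalty=3, ambiguity_penalty=1,
                              max_penalty=Fraction(6, 10)),
    "setting2": PenaltyConfig(snp_penalty=5, new_indel_penalty=6,
                              extend_indel_penalty=1, ambiguity_penalty=1,
                              max_penalty=Fraction(5, 10)),
    "setting3": PenaltyConfig(snp_penalty=10, new_indel_penalty=20,
                              extend_indel_penalty=5, ambiguity_penalty=1,
                              max_penalty=Fraction(1)),
    "setting4": PenaltyConfig(snp_penalty=6, new_indel_penalty=4,
                              extend_indel_penalty=2, ambiguity_penalty=1,
                              max_penalty=Fraction(6, 10)),
}


def validate_events(events: Iterable[Event]) -> List[Event]:
    out = []
    for kind, length in events:
        if kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {kind!r}")
        if not isinstance(length, (int,)) or isinstance(length, bool) or length < 1:
            raise ValueError(f"event length must be a positive integer, got {length!r}")
        out.append((kind, int(length)))
    return out


def score_events(events: Sequence[Event], config: PenaltyConfig):
    """Total penalty of an ordered event list.

    Each insertion/deletion event is one gap and costs
    ``new_indel_penalty + length * extend_indel_penalty``; consecutive gap
    events are NOT merged (a split event list is scored as separate gaps).
    """
    events = validate_events(events)
    total = Fraction(0)
    for kind, length in events:
        if kind == "mismatch":
            total += length * config.snp_penalty
        elif kind == "ambiguous_match":
            total += length * config.ambiguity_penalty
        elif kind in _GAP_KINDS:
            total += config.gap_cost(length)
        elif kind == "soft_clip":
            total += length * config.soft_clip_per_base
        # matches cost 0
    return _as_number(total)


def query_consumed(events: Sequence[Event]) -> int:
    return sum(n for kind, n in events if kind in _QUERY_CONSUMING)


def reference_consumed(events: Sequence[Event]) -> int:
    return sum(n for kind, n in events
               if kind in ("match", "mismatch", "ambiguous_match", "deletion"))


def max_allowed_penalty(read_len: int, config: PenaltyConfig):
    """Acceptance bound: ``max_penalty`` per query base."""
    if read_len < 1:
        raise ValueError("read length must be >= 1")
    return _as_number(config.max_penalty * read_len)


def compare_bases(read_base: str, ref_base: str) -> str:
    """Classify one aligned base pair as match/ambiguous_match/mismatch.

    A concrete base compared against an ambiguity code that includes it is an
    ambiguous match; against one that does not include it, a mismatch.
    """
    a = read_base.upper()
    b = ref_base.upper()
    sa = IUPAC_SETS.get(a)
    sb = IUPAC_SETS.get(b)
    if sa is None or sb is None:
        raise ValueError(f"unknown base {read_base!r}/{ref_base!r}")
    if len(sa) == 1 and len(sb) == 1:
        return "match" if sa == sb else "mismatch"
    return "ambiguous_match" if sa & sb else "mismatch"


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(cigar: str) -> List[Tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def score_cigar(cigar: str, read_seq: str, ref_seq: str, pos: int,
                config: PenaltyConfig):
    """Re-derive the event list and penalty from a CIGAR at a 0-based position.

    M ops are resolved base-by-base into match/mismatch/ambiguous_match;
    ``=``/``X`` are accepted on input and resolved the same way. Supported ops:
    M, I, D, S, =, X.
    """
    ops = parse_cigar(cigar)
    events: List[Event] = []

    def push(kind: str, n: int = 1):
        if events and events[-1][0] == kind and kind not in _GAP_KINDS:
            events[-1] = (kind, events[-1][1] + n)
        else:
            events.append((kind, n))

    qi, ri = 0, pos
    if pos < 0:
        raise ValueError("position must be >= 0")
    for n, op in ops:
        if op in ("M", "=", "X"):
            if ri + n > len(ref_seq) or qi + n > len(read_seq):
                raise ValueError("CIGAR walks off read/reference")
            for k in range(n):
                push(compare_bases(read_seq[qi + k], ref_seq[ri + k]))
            qi += n
            ri += n
        elif op == "I":
            events.append(("insertion", n))
            qi += n
        elif op == "D":
            events.append(("deletion", n))
            ri += n
        elif op == "S":
            push("soft_clip", n)
            qi += n
        else:
            raise ValueError(f"unsupported CIGAR op {op!r}")
    if qi != len(read_seq):
        raise ValueError(
            f"CIGAR consumes {qi} query bases but read has {len(read_seq)}")
    # merge event runs of the same kind produced above except gaps
    return events, score_events(events, config)


def events_to_cigar(events: Sequence[Event]) -> str:
    """Emit a CIGAR with M/I/D/S ops (mismatches and ambiguous matches as M)."""
    out: List[Tuple[int, str]] = []
    code = {"match": "M", "mismatch": "M", "ambiguous_match": "M",
            "insertion": "I", "deletion": "D", "soft_clip": "S"}
    for kind, n in validate_events(events):
        op = code[kind]
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + n, op)
        else:
            out.append((n, op))
    return "".join(f"{n}{op}" for n, op in out)
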