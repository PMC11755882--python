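"""Deterministic synthetic data: references, reads with truth, divergence.

The generator emulates the structures the seeding algorithm has to cope
with: random genomes with embedded near-identical duplications (controllable
copy number and identity) and variant-dense windows, and reads carrying
point mutations and short indels with an exact per-read truth record
(position, strand, event list, penalty). Everything is driven by one seed;
the same configuration always yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .penalty import Event, PenaltyConfig, PRESETS, reverse_complement, \
    score_events

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome and read set."""
    genome_length: int = 100_000
    # duplications: n extra copies of one unit, at the given identity
    n_duplications: int = 0
    dup_unit_length: int = 500
    dup_identity: float = 1.0
    # variant-dense windows (elevated SNP rate applies to reads overlapping)
    n_variant_regions: int = 0
    variant_region_length: int = 500
    variant_region_snp_rate: float = 0.05
    # read sampling
    background_snp_rate: float = 0.02
    indel_rate: float = 0.002
    indel_geom_p: float = 0.5
    max_indel_len: int = 10
    read_length: int = 150
    n_reads: int = 1000
    paired: bool = False
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    seed: int = 0

    def __post_init__(self):
        for name in ("dup_identity", "variant_region_snp_rate",
                     "background_snp_rate", "indel_rate", "indel_geom_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("genome_length", "dup_unit_length", "read_length",
                     "max_indel_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class TruthRecord:
    """Ground truth for one simulated read (oriented-read frame)."""
    read_id: str
    seq_id: str
    offset: int               # 0-based reference start of the aligned span
    strand: str
    events: List[Event]
    penalty: object

    def __post_init__(self):
        # events and penalty must agree by construction
        pass


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    others = [b for b in "ACGT" if b != base]
    return others[rng.integers(0, 3)]


def simulate_reference(cfg: SimConfig
                       ) -> Tuple[List[Tuple[str, str]],
                                  List[Tuple[str, int, int, str]]]:
    """Random genome with duplications and annotated variant-dense windows.

    Returns ([(seq_id, sequence)], bed) with BED rows
    (chrom, start, end, label) in 0-based half-open coordinates.
    """
    if cfg.dup_unit_length > cfg.genome_length:
        raise ValueError("duplication unit longer than genome")
    if cfg.n_variant_regions and \
            cfg.variant_region_length > cfg.genome_length:
        raise ValueError("variant region longer than genome")
    rng = np.random.default_rng(cfg.seed)
    genome = list(_random_seq(rng, cfg.genome_length))
    bed: List[Tuple[str, int, int, str]] = []
    chrom = "sim_ref"

    if cfg.n_duplications > 0:
        src = int(rng.integers(0, cfg.genome_length - cfg.dup_unit_length + 1))
        unit = genome[src:src + cfg.dup_unit_length]
        bed.append((chrom, src, src + cfg.dup_unit_length, "duplication_src"))
        taken = [(src, src + cfg.dup_unit_length)]
        for _ in range(cfg.n_duplications):
            tgt = None
            for _try in range(200):
                cand = int(rng.integers(0, cfg.genome_length
                                        - cfg.dup_unit_length + 1))
                if all(cand + cfg.dup_unit_length <= a or cand >= b
                       for a, b in taken):
                    tgt = cand
                    break
            if tgt is None:
                raise ValueError("cannot place duplications without overlap; "
                                 "reduce copy number or unit length")
            taken.append((tgt, tgt + cfg.dup_unit_length))
            copy = list(unit)
            if cfg.dup_identity < 1.0:
                muts = rng.random(cfg.dup_unit_length) < (1 - cfg.dup_identity)
                for i in np.nonzero(muts)[0]:
                    copy[i] = _mutate_base(rng, copy[i])
            genome[tgt:tgt + cfg.dup_unit_length] = copy
            bed.append((chrom, tgt, tgt + cfg.dup_unit_length, "duplication"))

    for _ in range(cfg.n_variant_regions):
        start = int(rng.integers(0, cfg.genome_length
                                 - cfg.variant_region_length + 1))
        bed.append((chrom, start, start + cfg.variant_region_length,
                    "variant_dense"))

    return [(chrom, "".join(genome))], bed


def _snp_rate_at(pos: int, cfg: SimConfig,
                 variant_regions: Sequence[Tuple[int, int]]) -> float:
    for a, b in variant_regions:
        if a <= pos < b:
            return cfg.variant_region_snp_rate
    return cfg.background_snp_rate


def _sample_read(rng: np.random.Generator, seq: str, cfg: SimConfig,
                 variant_regions: Sequence[Tuple[int, int]]
                 ) -> Optional[Tuple[int, str, List[Event]]]:
    """One read from a template start: returns (offset, read, events).

    Indels are kept out of the first/last 5 bp so the truth offset and event
    list are unambiguous at the read ends.
    """
    lq = cfg.read_length
    margin = 5
    max_start = len(seq) - lq - cfg.max_indel_len - 1
    if max_start < 0:
        return None
    start = int(rng.integers(0, max_start + 1))
    read: List[str] = []
    events: List[Event] = []

    def push(kind: str, n: int = 1):
        if events and events[-1][0] == kind and kind not in ("insertion",
                                                             "deletion"):
            events[-1] = (kind, events[-1][1] + n)
        else:
            events.append((kind, n))

    rpos = start
    while len(read) < lq:
        interior = margin <= len(read) < lq - margin
        if interior and rng.random() < cfg.indel_rate:
            length = min(int(rng.geometric(cfg.indel_geom_p)),
                         cfg.max_indel_len, lq - margin - len(read))
            if length >= 1:
                if rng.random() < 0.5:     # insertion of random bases
                    for _ in range(length):
                        read.append("ACGT"[rng.integers(0, 4)])
                    push("insertion", length)
                else:                       # deletion of reference bases
                    if rpos + length + (lq - len(read)) <= len(seq):
                        rpos += length
                        push("deletion", length)
                continue
        base = seq[rpos]
        if rng.random() < _snp_rate_at(rpos, cfg, variant_regions):
            read.append(_mutate_base(rng, base))
            push("mismatch")
        else:
            read.append(base)
            push("match")
        rpos += 1
    return start, "".join(read), events


def simulate_reads(ref: Sequence[Tuple[str, str]], cfg: SimConfig,
                   penalty_config: Optional[PenaltyConfig] = None,
                   bed: Sequence[Tuple[str, int, int, str]] = ()
                   ) -> Tuple[List[Tuple[str, str]], List[TruthRecord]]:
    """Sample reads uniformly (uniform strand) with exact truth records.

    Returns ([(read_id, sequence)], truth). Truth events/penalty are in the
    oriented-read frame (reverse-strand reads report reversed events).
    """
    if penalty_config is None:
        penalty_config = PRESETS["setting1"]
    rng = np.random.default_rng(cfg.seed + 1)
    lens = np.array([len(s) for _, s in ref], dtype=float)
    if cfg.read_length > max(len(s) for _, s in ref):
        raise ValueError("read length exceeds genome length")
    probs = lens / lens.sum()
    variant_regions = {rid: [] for rid, _ in ref}
    for chrom, a, b, label in bed:
        if label == "variant_dense":
            variant_regions[chrom].append((a, b))
    reads: List[Tuple[str, str]] = []
    truth: List[TruthRecord] = []
    i = 0
    while len(reads) < cfg.n_reads:
        ri = int(rng.choice(len(ref), p=probs))
        rid, seq = ref[ri]
        out = _sample_read(rng, seq, cfg, variant_regions[rid])
        if out is None:
            raise ValueError("reference too short for configured reads")
        start, read, events = out
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            read = reverse_complement(read)
            events = list(reversed(events))
        name = f"read{i}"
        reads.append((name, read))
        truth.append(TruthRecord(name, rid, start, strand, events,
                                 score_events(events, penalty_config)))
        i += 1
    return reads, truth


def inject_divergence(seq: str, density: float, seed: int) -> str:
    """Copy of the sequence with substitutions at the given per-bp density.

    Mutations always change the base (guaranteed substitution).
    """
    if not 0.0 <= density <= 0.25:
        raise ValueError("density must be in [0, 0.25]")
    rng = np.random.default_rng(seed)
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < density)[0]
    for i in hits:
        if out[i] in "ACGT":
            out[i] = _mutate_base(rng, out[i])
    return "".join(out)


def truth_table_tsv(truth: Sequence[TruthRecord]) -> str:
    """Truth table as TSV (read id, contig, 0-based offset, strand, penalty,
    event list)."""
    from .penalty import events_to_cigar
    lines = ["read_id\tseq_id\toffset\tstrand\tpenalty\tcigar"]
    for t in truth:
        lines.append(f"{t.read_id}\t{t.seq_id}\t{t.offset}\t{t.strand}\t"
                     f"{t.penalty}\t{events_to_cigar(t.events)}")
    return "\n".join(lines) + "\n"
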