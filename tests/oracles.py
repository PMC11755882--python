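"""Independent test oracles.

``dp_min_penalty`` is a plain row-by-row affine-gap dynamic program over the
full alignment grid (glocal: the read must be consumed entirely, unused
window ends are free, soft clips only at contig ends). It shares no code
with the package's search and serves as the exact reference for alignment
penalties. ``walk_cigar_penalty`` is an independent base-by-base CIGAR
scorer used to cross-check CIGAR rescoring.
"""

from __future__ import annotations

import re
from fractions import Fraction

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

INF = 1 << 40


def _scale_costs(config):
    vals = [Fraction(config.snp_penalty), Fraction(config.new_indel_penalty),
            Fraction(config.extend_indel_penalty),
            Fraction(config.ambiguity_penalty),
            Fraction(config.soft_clip_per_base)]
    scale = 1
    for v in vals:
        scale = np.lcm(scale, v.denominator)
    return int(scale), [int(v * scale) for v in vals]


def _diag_costs_row(qc, window, snp, amb):
    """Cost of aligning query base qc against each window base."""
    out = np.empty(len(window), dtype=np.int64)
    for j, rc in enumerate(window):
        if qc == rc and qc in "ACGT":
            out[j] = 0
        else:
            sa, sb = set(IUPAC.get(qc, "")), set(IUPAC.get(rc, ""))
            if len(IUPAC.get(qc, "XX")) == 1 and len(IUPAC.get(rc, "XX")) == 1:
                out[j] = 0 if qc == rc else snp
            else:
                out[j] = amb if (sa & sb) else snp
    return out


def dp_min_penalty(query: str, window: str, config, *,
                   at_left_edge: bool = False, at_right_edge: bool = False):
    """Exact minimum end-to-end penalty of query within the window.

    Mirrors the aligner's move semantics: the read is consumed entirely;
    unused leading/trailing window bases are free; each gap costs
    open + len*extend (every gap base); soft clips (per-base cost) are
    allowed only against contig ends (flags); deletions cannot precede the
    first consumed query base; a leading clip enters the alignment at the
    window start. Returns the penalty (int or Fraction) or None.
    """
    query, window = query.upper(), window.upper()
    lq, lw = len(query), len(window)
    if lq == 0 or lw == 0:
        return None
    scale, (snp, opn, ext, amb, clip) = _scale_costs(config)

    concrete = all(c in "ACGT" for c in query + window)
    warr = np.frombuffer(window.encode(), dtype="S1")

    M = np.zeros(lw + 1, dtype=np.int64)          # row 0: free start
    I = np.full(lw + 1, INF, dtype=np.int64)
    D = np.full(lw + 1, INF, dtype=np.int64)
    goal = INF
    for qi in range(lq):
        if concrete:
            qc = query[qi].encode()
            diag = np.where(warr == qc, 0, snp).astype(np.int64)
        else:
            diag = _diag_costs_row(query[qi], window, snp, amb)
        best = np.minimum(np.minimum(M, I), D)
        if at_right_edge and qi > 0:
            goal = min(goal, int(best[lw]) + (lq - qi) * clip)
        M2 = np.full(lw + 1, INF, dtype=np.int64)
        M2[1:] = best[:-1] + diag
        if at_left_edge and qi >= 1:
            M2[1] = min(M2[1], qi * clip + int(diag[0]))
        I2 = np.minimum(np.minimum(M, D) + opn, I) + ext
        # deletions within the new row (qi+1 >= 1 consumed query bases)
        srcs = np.minimum(M2, I2)
        t = np.minimum.accumulate(srcs + opn - ext * np.arange(lw + 1))
        D2 = np.full(lw + 1, INF, dtype=np.int64)
        D2[1:] = t[:-1] + ext * np.arange(1, lw + 1)
        np.minimum(D2, INF, out=D2)
        M, I, D = M2, I2, np.minimum(D2, INF)
    best = np.minimum(np.minimum(M, I), D)
    goal = min(goal, int(best.min()))
    if at_right_edge:
        goal = min(goal, int(best[lw]))
    if goal >= INF:
        return None
    res = Fraction(goal, scale)
    return int(res) if res.denominator == 1 else res


def genome_optimum(query: str, genome: str, config, revcomp):
    """Best end-to-end penalty over all offsets and both strands."""
    a = dp_min_penalty(query, genome, config,
                       at_left_edge=True, at_right_edge=True)
    b = dp_min_penalty(revcomp(query), genome, config,
                       at_left_edge=True, at_right_edge=True)
    vals = [v for v in (a, b) if v is not None]
    return min(vals) if vals else None


_CIG = re.compile(r"(\d+)([MIDS=X])")


def walk_cigar_penalty(cigar: str, read: str, ref: str, pos: int, config):
    """Independent CIGAR scorer (base-by-base walker)."""
    total = Fraction(0)
    qi, ri = 0, pos
    for n_s, op in _CIG.findall(cigar):
        n = int(n_s)
        if op in "M=X":
            for k in range(n):
                a, b = read[qi + k].upper(), ref[ri + k].upper()
                if a == b and a in "ACGT":
                    continue
                sa, sb = set(IUPAC[a]), set(IUPAC[b])
                if len(sa) == 1 and len(sb) == 1:
                    total += Fraction(config.snp_penalty)
                elif sa & sb:
                    total += Fraction(config.ambiguity_penalty)
                else:
                    total += Fraction(config.snp_penalty)
            qi += n
            ri += n
        elif op == "I":
            total += Fraction(config.new_indel_penalty) \
                + n * Fraction(config.extend_indel_penalty)
            qi += n
        elif op == "D":
            total += Fraction(config.new_indel_penalty) \
                + n * Fraction(config.extend_indel_penalty)
            ri += n
        elif op == "S":
            total += n * Fraction(config.soft_clip_per_base)
            qi += n
    return int(total) if total.denominator == 1 else total


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def mutate_read(rng, template: str, snp_rate: float, indel_rate: float,
                max_indel: int = 10):
    """Simple independent read mutator (returns the mutated read)."""
    out = []
    i = 0
    while i < len(template):
        r = rng.random()
        if r < indel_rate / 2:
            out.extend(rng.choice("ACGT")
                       for _ in range(rng.randint(1, max_indel)))
        elif r < indel_rate:
            i += rng.randint(1, max_indel)
            continue
        if i < len(template):
            base = template[i]
            if rng.random() < snp_rate:
                base = rng.choice([b for b in "ACGT" if b != base])
            out.append(base)
            i += 1
    return "".join(out)
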