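"""FASTA/FASTQ input and SAM/VCF output.

Reading goes through Biopython (gzip transparently accepted); SAM and VCF
are written as plain text in their standard dialects: SAM 1-based POS, FLAG
strand/unmapped bits, CIGAR restricted to M/I/D/S, the alignment penalty in
the ``ZP`` tag (MAPQ is emitted as 255, unavailable); VCF4 counts-only
records derived from the reported alignments (no genotype model).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO

from .align import Alignment
from .penalty import Event, reverse_complement


@dataclass
class ReadRecord:
    """One sequencing read; qualities are carried but never scored."""
    id: str
    sequence: str
    qualities: Optional[str] = None
    mate: int = 0          # 0 = unpaired, 1/2 = mate in a pair

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        if self.qualities is not None and \
                len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality length "
                             f"{len(self.qualities)} != sequence length "
                             f"{len(self.sequence)}")


def _open_text(path: str):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str) -> List[Tuple[str, str]]:
    """All records of a (possibly gzipped) FASTA, in file order."""
    out = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            out.append((rec.id, str(rec.seq).upper()))
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def read_fastq(path: str) -> List[ReadRecord]:
    """All records of a (possibly gzipped) FASTQ, in file order."""
    out = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                qual = "".join(chr(q + 33)
                               for q in rec.letter_annotations["phred_quality"])
                out.append(ReadRecord(rec.id, str(rec.seq).upper(), qual))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed FASTQ near record "
                             f"{len(out) + 1}: {exc}") from exc
    return out


def read_sequences(path: str) -> List[ReadRecord]:
    """Reads from FASTQ or FASTA (sniffed from the first character)."""
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    return [ReadRecord(rid, seq) for rid, seq in read_fasta(path)]


def write_fasta(records: Sequence[Tuple[str, str]], path: str, width: int = 70):
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq(records: Sequence, path: str):
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = (rec.id, rec.sequence) if hasattr(rec, "sequence") \
                else rec
            qual = getattr(rec, "qualities", None) or "I" * len(seq)
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def _penalty_tag(penalty) -> str:
    if isinstance(penalty, int) or (isinstance(penalty, Fraction)
                                    and penalty.denominator == 1):
        return f"ZP:i:{int(penalty)}"
    return f"ZP:f:{float(penalty)}"


def sam_header(refs: Sequence[Tuple[str, str]],
               program: str = "xmeralign") -> List[str]:
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for rid, seq in refs:
        lines.append(f"@SQ\tSN:{rid}\tLN:{len(seq)}")
    lines.append(f"@PG\tID:{program}\tPN:{program}")
    return lines


def write_sam(results: Iterable[Tuple[ReadRecord, List[Alignment]]],
              refs: Sequence[Tuple[str, str]], path: str):
    """Write alignments (and unmapped reads) as a valid SAM file.

    The first alignment of a read is primary; further reported alignments
    carry the secondary flag. Reverse-strand rows store the
    reverse-complemented sequence per the SAM convention.
    """
    ref_ids = {rid for rid, _ in refs}
    import contextlib
    ctx = open(path, "w") if isinstance(path, str) else contextlib.nullcontext(path)
    with ctx as fh:
        for line in sam_header(refs):
            fh.write(line + "\n")
        for read, alignments in results:
            if not alignments:
                fh.write(f"{read.id}\t4\t*\t0\t0\t*\t*\t0\t0\t"
                         f"{read.sequence}\t{read.qualities or '*'}\n")
                continue
            for i, a in enumerate(alignments):
                if a.seq_id not in ref_ids:
                    raise ValueError(f"alignment references unknown contig "
                                     f"{a.seq_id!r}")
                flag = 0
                seq = read.sequence
                qual = read.qualities or "*"
                if a.strand == "-":
                    flag |= 16
                    seq = reverse_complement(seq)
                    if qual != "*":
                        qual = qual[::-1]
                if i > 0:
                    flag |= 256
                fh.write("\t".join([
                    read.id, str(flag), a.seq_id, str(a.pos + 1), "255",
                    a.cigar, "*", "0", "0", seq, qual,
                    _penalty_tag(a.penalty)]) + "\n")


def _walk_events(events: Sequence[Event], read_seq: str, pos: int):
    """Yield (kind, ref_pos, length, read_bases) for each event."""
    qi, ri = 0, pos
    for kind, n in events:
        if kind in ("match", "mismatch", "ambiguous_match"):
            yield kind, ri, n, read_seq[qi:qi + n]
            qi += n
            ri += n
        elif kind == "insertion":
            yield kind, ri, n, read_seq[qi:qi + n]
            qi += n
        elif kind == "deletion":
            yield kind, ri, n, ""
            ri += n
        elif kind == "soft_clip":
            qi += n


def write_vcf(aligned: Iterable[Tuple[str, Alignment]],
              refs: Sequence[Tuple[str, str]], path: str):
    """Counts-only VCF4 from reported alignments.

    ``aligned`` yields (oriented read sequence, alignment). Each mismatch
    becomes a SNP record, each indel an anchored indel record; INFO carries
    total depth (reads covering the site) and per-allele counts. No
    genotype-likelihood model.
    """
    ref_seqs = dict(refs)
    depth: Dict[Tuple[str, int], int] = {}
    counts: Dict[Tuple[str, int, str, str], int] = {}
    for read_seq, a in aligned:
        ref = ref_seqs[a.seq_id]
        for kind, ri, n, bases in _walk_events(a.events, read_seq, a.pos):
            if kind in ("match", "mismatch", "ambiguous_match"):
                for k in range(n):
                    depth[(a.seq_id, ri + k)] = \
                        depth.get((a.seq_id, ri + k), 0) + 1
            if kind == "mismatch":
                for k in range(n):
                    key = (a.seq_id, ri + k, ref[ri + k], bases[k])
                    counts[key] = counts.get(key, 0) + 1
            elif kind == "insertion" and ri > 0:
                anchor = ref[ri - 1]
                key = (a.seq_id, ri - 1, anchor, anchor + bases)
                counts[key] = counts.get(key, 0) + 1
            elif kind == "deletion" and ri > 0:
                anchor = ref[ri - 1]
                key = (a.seq_id, ri - 1, anchor + ref[ri:ri + n], anchor)
                counts[key] = counts.get(key, 0) + 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,'
                 'Description="Reads covering the site">\n')
        fh.write('##INFO=<ID=AC,Number=1,Type=Integer,'
                 'Description="Reads supporting the alternate allele">\n')
        for rid, seq in refs:
            fh.write(f"##contig=<ID={rid},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for (chrom, p, ref_allele, alt), ac in sorted(counts.items()):
            dp = depth.get((chrom, p), ac)
            fh.write(f"{chrom}\t{p + 1}\t.\t{ref_allele}\t{alt}\t.\tPASS\t"
                     f"DP={max(dp, ac)};AC={ac}\n")
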