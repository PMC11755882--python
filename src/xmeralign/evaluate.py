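"""Evaluation of alignment runs: optimality, causes, consistency, abundance.

Penalties are always recomputed from the CIGAR and position against the
reference (never trusted from tags), so runs produced by any aligner can be
compared on an equal footing. A read's minimum recomputed penalty across the
compared runs defines "optimal"; anything above it is suboptimal.
Alignments more than 10% divergent (penalty above snp_penalty * 0.10 * read
length) are excluded, mirroring the per-base maximum-penalty convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .penalty import PenaltyConfig, parse_cigar, score_cigar

#: close-site window (bp) for classifying suboptimal alignments
CLOSE_SITE_BP = 100


@dataclass
class RunAlignment:
    """One alignment row parsed from a run's SAM output."""
    seq_id: str
    pos: int            # 0-based
    strand: str
    cigar: str
    penalty: object


@dataclass
class ReadComparison:
    """Per-read view across runs, with recomputed penalties and verdicts."""
    read_id: str
    per_run: Dict[str, Optional[RunAlignment]]
    min_penalty: object = None
    verdicts: Dict[str, str] = field(default_factory=dict)


def parse_sam_run(path: str, refs: Sequence[Tuple[str, str]],
                  config: PenaltyConfig, *,
                  dissimilarity_cutoff: float = 0.10
                  ) -> Dict[str, List[RunAlignment]]:
    """Parse a SAM file, recomputing every penalty from CIGAR + reference.

    Unmapped rows yield an empty list for the read. Alignments whose
    recomputed penalty exceeds ``snp_penalty * cutoff * read_length`` (more
    than ~10% divergence) are excluded.
    """
    import pysam

    ref_seqs = dict(refs)
    out: Dict[str, List[RunAlignment]] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            out.setdefault(rec.query_name, [])
            if rec.is_unmapped or rec.cigarstring is None:
                continue
            ref = ref_seqs.get(rec.reference_name)
            if ref is None:
                continue
            seq = rec.query_sequence
            if seq is None:
                continue
            _, penalty = score_cigar(rec.cigarstring, seq, ref,
                                     rec.reference_start, config)
            if penalty > config.snp_penalty * dissimilarity_cutoff * len(seq):
                continue
            out[rec.query_name].append(RunAlignment(
                rec.reference_name, rec.reference_start,
                "-" if rec.is_reverse else "+", rec.cigarstring, penalty))
    return out


def _middle_clip(aln: RunAlignment, ref_len: int) -> bool:
    """True when the alignment soft-clips away from the contig ends."""
    ops = parse_cigar(aln.cigar)
    ref_consumed = sum(n for n, op in ops if op in "MD=XN")
    if ops and ops[0][1] == "S" and aln.pos > 0:
        return True
    if ops and ops[-1][1] == "S" and aln.pos + ref_consumed < ref_len:
        return True
    return False


def compare_runs(runs: Mapping[str, Mapping[str, List[RunAlignment]]],
                 total_reads: Optional[int] = None, *,
                 ref_lens: Optional[Mapping[str, int]] = None,
                 filter_middle_clips_of: Optional[str] = None
                 ) -> Tuple[List[ReadComparison], Dict[str, float]]:
    """Cross-run optimality comparison.

    ``runs`` maps run label -> (read id -> alignments with recomputed
    penalties). A read missing from a run (or with no surviving alignment)
    counts as failed to align for that run. When ``filter_middle_clips_of``
    names a run, reads that run soft-clipped in the middle of a contig are
    excluded entirely. Returns the per-read comparisons and each run's
    suboptimal rate (suboptimal reads / total reads).
    """
    labels = list(runs)
    read_ids: Set[str] = set()
    for label in labels:
        read_ids.update(runs[label].keys())
    excluded: Set[str] = set()
    if filter_middle_clips_of is not None:
        if ref_lens is None:
            raise ValueError("ref_lens required for the middle-clip filter")
        for rid, alns in runs[filter_middle_clips_of].items():
            if any(_middle_clip(a, ref_lens[a.seq_id]) for a in alns):
                excluded.add(rid)
    comparisons: List[ReadComparison] = []
    sub_counts = {label: 0 for label in labels}
    for rid in sorted(read_ids - excluded):
        per_run: Dict[str, Optional[RunAlignment]] = {}
        for label in labels:
            alns = runs[label].get(rid, [])
            per_run[label] = min(alns, key=lambda a: a.penalty) if alns \
                else None
        pens = [a.penalty for a in per_run.values() if a is not None]
        cmp = ReadComparison(rid, per_run)
        if pens:
            cmp.min_penalty = min(pens)
            for label in labels:
                a = per_run[label]
                if a is None:
                    cmp.verdicts[label] = "suboptimal"
                    sub_counts[label] += 1
                elif a.penalty == cmp.min_penalty:
                    cmp.verdicts[label] = "optimal"
                else:
                    cmp.verdicts[label] = "suboptimal"
                    sub_counts[label] += 1
        comparisons.append(cmp)
    n = total_reads if total_reads is not None else max(1, len(comparisons))
    rates = {label: sub_counts[label] / n for label in labels}
    return comparisons, rates


SUBOPTIMAL_CLASSES = ("failed_to_align", "wrong_site", "close_site",
                      "same_site_higher_penalty")


def classify_suboptimal(cmp: ReadComparison, label: str) -> str:
    """Why is this run's alignment suboptimal for this read?

    failed_to_align: no (surviving) alignment; wrong_site: >100 bp from the
    optimal site or another contig; close_site: within 100 bp but not the
    same position; same_site_higher_penalty: same position, worse penalty.
    """
    if cmp.verdicts.get(label) != "suboptimal":
        raise ValueError(f"run {label!r} is not suboptimal for read "
                         f"{cmp.read_id!r}")
    a = cmp.per_run[label]
    if a is None:
        return "failed_to_align"
    optimal = [x for lab, x in cmp.per_run.items()
               if x is not None and x.penalty == cmp.min_penalty]
    best = optimal[0]
    if a.seq_id != best.seq_id or abs(a.pos - best.pos) > CLOSE_SITE_BP:
        return "wrong_site"
    if a.pos == best.pos:
        return "same_site_higher_penalty"
    return "close_site"


def consistency_eval(simple_run: Mapping[str, List[RunAlignment]],
                     complex_run: Mapping[str, List[RunAlignment]]
                     ) -> Dict[str, float]:
    """Simple-vs-complex reference consistency.

    A read (aligned in the simple run) is consistent when its simple-run
    optimal alignment is among the complex-run reports (same contig,
    position, strand) or when the complex run found a strictly lower
    penalty. Also reports the fraction of reads whose complex-run output
    includes any alignment worse than that read's best there.
    """
    aligned = 0
    consistent = 0
    with_suboptimal = 0
    complex_aligned = 0
    for rid, simple_alns in simple_run.items():
        if not simple_alns:
            continue
        aligned += 1
        best_simple = min(a.penalty for a in simple_alns)
        optimal_sites = {(a.seq_id, a.pos, a.strand) for a in simple_alns
                         if a.penalty == best_simple}
        complex_alns = complex_run.get(rid, [])
        if complex_alns:
            complex_aligned += 1
            best_complex = min(a.penalty for a in complex_alns)
            if any(a.penalty > best_complex for a in complex_alns):
                with_suboptimal += 1
            reported = {(a.seq_id, a.pos, a.strand) for a in complex_alns}
            if (optimal_sites & reported) or best_complex < best_simple:
                consistent += 1
    inconsistency = 1.0 - consistent / aligned if aligned else 0.0
    sub_fraction = with_suboptimal / complex_aligned if complex_aligned \
        else 0.0
    return {
        "aligned_reads": aligned,
        "inconsistency": inconsistency,
        "suboptimal_report_fraction": sub_fraction,
    }


def genome_breadth(run: Mapping[str, List[RunAlignment]],
                   ref_lens: Mapping[str, int]) -> Dict[str, float]:
    """Fraction of each genome's positions covered by >=1 alignment."""
    covered: Dict[str, Set[Tuple[int, int]]] = {g: set() for g in ref_lens}
    intervals: Dict[str, List[Tuple[int, int]]] = {g: [] for g in ref_lens}
    for alns in run.values():
        for a in alns:
            ops = parse_cigar(a.cigar)
            span = sum(n for n, op in ops if op in "MD=XN")
            if a.seq_id in intervals:
                intervals[a.seq_id].append((a.pos, a.pos + span))
    out = {}
    for g, ivs in intervals.items():
        ivs.sort()
        total, reach = 0, -1
        for s, e in ivs:
            s = max(s, reach)
            if e > s:
                total += e - s
                reach = e
        out[g] = total / ref_lens[g] if ref_lens[g] else 0.0
    return out


def effective_abundance(read_to_genomes: Mapping[str, Iterable[str]],
                        genome_coverage: Mapping[str, float],
                        min_cov: float = 0.05) -> Dict[str, float]:
    """Coverage-filtered even splitting of each read's unit weight.

    Genomes below ``min_cov`` coverage are dropped from a read's target set;
    the read's weight 1 is divided evenly among the survivors; abundances
    are normalized to fractions of the total distributed weight.
    """
    weights: Dict[str, float] = {}
    for rid, genomes in read_to_genomes.items():
        survivors = [g for g in set(genomes)
                     if genome_coverage.get(g, 0.0) >= min_cov]
        if not survivors:
            continue
        share = 1.0 / len(survivors)
        for g in survivors:
            weights[g] = weights.get(g, 0.0) + share
    total = sum(weights.values())
    if total == 0:
        return {}
    return {g: w / total for g, w in weights.items()}
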