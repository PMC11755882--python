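# Methods

This note documents the algorithms, the parameters that matter, the
numerical choices, and what the synthetic data does and does not emulate.

## Penalty model

Alignments are scored additively: mismatches cost `snp_penalty` each,
ambiguous-base matches `ambiguity_penalty`, each gap costs
`new_indel_penalty + len * extend_indel_penalty` with the extension applied
to every gap base including the first (this is the convention under which
all published worked-example penalties — e.g. a 5 bp insertion costing 20
under snp 6 / open 5 / extend 3 — reproduce exactly), and soft-clipped
bases cost `soft_clip_per_base` (default 1). `max_penalty` is interpreted
per query base: a read of length L is reportable iff its penalty is at most
`max_penalty * L`, so `--max-penalty 1.00` with snp 10 means 10 point
mutations per 100 bp. `max_penalty_span` widens reporting to a band above
the optimum; the default 0 reports co-optimal alignments only.

All penalties are exact rationals internally (integer-scaled during the
search), so optimal/suboptimal verdicts are bit-stable; no floating-point
comparison ever decides a tie.

Base comparison: a concrete base against an IUPAC code that contains it is
an *ambiguous match*; against one that does not, a mismatch. Base qualities
are ignored throughout.

## X-mer pyramid

Level 0 assigns one x-mer per base; each base gets a distinct
(merge-request, descendant-recommendation) pair — A=(left,left),
C=(left,right), G=(right,left), T=(right,right). Every adjacent pair merges
into a child iff the left member requests right or the right member
requests left, which (with uniform direction bits) keeps ~3/4 of pairs per
level, giving geometric level decay and a total below about 4n x-mers.
A child's hashcode is an order-sensitive 64-bit mix of its parents'
hashcodes; the child takes its own merge request from the
larger-hashcode parent's recommendation and passes the other parent's
recommendation to its descendants (single-generation pass-through).

Two choices here are deliberately ours:

- **Side-relative recommendations.** A recommendation is expressed in its
  holder's frame, and a child reads the right-hand member's bit mirrored.
  Without this, the two children sharing a middle parent consult the same
  bit, their merge decisions correlate, level decay stalls near 0.81, and
  the pyramid grows past 5n. With it the empirical maximum ratio over
  seeded 10 kb sequences is ≈ 3.97–4.00 (a seed occasionally grazes 4.0;
  the structural test allows fluctuation to 4.5 with a warning and requires
  the mean ≤ 4).
- **Reverse-complement symmetry via dual state.** Each x-mer tracks both
  orientations' hashes and directions; the exposed values are those of the
  higher-hash orientation (directions mirrored if the reverse orientation
  wins; the left parent wins ties). An x-mer whose two orientation hashes
  tie is a reverse-complement palindrome, a fixed point of mirroring with
  no consistent single direction: it requests to merge in **both**
  directions, which keeps merge events exactly mirror-symmetric — the
  pyramid of revcomp(s) exposes exactly the multiset of canonical hashcodes
  of the pyramid of s (verified exhaustively for all sequences up to
  length 6). A consequence is that canonical leaf hashcodes pair A with T
  and C with G.

Coverage: every non-edge x-mer is guaranteed a child, so each level covers
its own span without holes; the first/last x-mer of a level may be
childless, so coverage may shrink at the sequence ends by at most one
x-mer length per level.

Ambiguity codes expand into concrete variants while a window holds fewer
than `ambiguity_limit` (default 3) ambiguous bases; windows at or above the
limit produce no x-mer.

A *simplified mode* reproduces the didactic scheme (leaf hashes A=1..T=4,
child hash `4*left + right`, merge-left iff the count of A's plus C's is
odd, gap-left iff A's plus G's is odd) for exact small test vectors; it
claims no reverse-complement symmetry.

## Gapped x-mers and the reference index

An x-mer of length x with at least `min_seed_bp` bases is extended by
`extra = x + (hashcode mod 3)` bases — the pseudorandom mod-3 term avoids
systematically skipping seed lengths — split as gap = ceil(extra/2),
post-gap extension = extra − gap. The gap extends left when the x-mer plans
to merge right and vice versa (palindromic x-mers emit both sides); gapped
forms that would cross a sequence end are not created. The gapped hashcode
is the canonical content hash of the concatenated non-gap contents, so gap
bases never influence lookup.

`min_seed_bp(L)` is the smallest b with `L / 4^b ≤ 16`: shorter seeds would
match ~16+ random places. Bins are keyed by (hashcode, used bp) where
used bp = x + extension; each bin stores at most `used_bp` positions
(first-come, no eviction), bounding the work any repeat can cause. The
index stores every pyramid x-mer's gapped form: the pyramid itself is the
sparse sample (same-level neighbors are shifted by roughly half their
span), and at the package's target scale the denser storage maximizes seed
recovery. Reference pyramids are built to a default maximum span of 512 bp
(longer seeds are useless for short reads); levels above the initially
built ones are added lazily when a query requests them, with lazy and eager
builds producing identical tables (tested).

## Query search

The query's own pyramid is walked adaptively from (level 0, position 0): a
seed whose bin is saturated (match count at the cap) pushes the path up to
longer seeds at the same position; otherwise the matches are recorded and
the path returns down-right. Matches are grouped by (reference, strand,
offset) with a tolerance equal to the global maximum-gap bound, since seeds
on opposite sides of an indel disagree by its length; the representative
offset of a cluster is its modal value. Offsets with fewer than two
distinct supporting seeds are withheld (singletons are often hash
collisions). Candidates are visited in discovery order (earlier discovery =
fewer leading mismatched seeds), ties broken by higher support then lower
offset; the optimistic strict-majority candidate, when one exists, is
checked first.

The optimality certificate lower-bounds every alternative offset by
(number of nonoverlapping recorded seeds with no match there) ×
`snp_penalty`, using only seeds from unsaturated bins (complete match
lists). For offsets where contig-edge clipping is possible, the count is
discounted by two, because a seed straddling a clip boundary can be broken
at below-snp cost. The search stops when the certificate holds, when no
candidate can satisfy the maximum penalty, or when the path reaches the
query end.

## Extension

Per candidate, in order:

1. **Ungapped check.** Final iff its penalty is below one 1 bp gap
   (`open + extend`).
2. **Piece bound.** Pieces of length `floor(log4(3L+1) + 1)` are taken
   greedily from the query; each piece absent from the region around the
   candidate implies ≥1 mutated base in any alignment there. The offset is
   rejected when `min_mutations * snp > budget`; otherwise the longest
   possible gap is `floor((budget − (min_mutations−1)·snp − open)/ext)`
   (one mutation may be the gap itself), 0 meaning ungapped-only. The
   budget is `min(max_penalty·L, best_so_far + max_penalty_span)`.
   This bound follows the per-piece-one-mutation reading; a short insertion
   straddling a piece boundary can in principle cost less than snp per
   broken piece, so the bound is exact for point mutations and short
   scattered indels (the regime the generator produces) rather than
   universally admissible — a deliberate fidelity-to-the-method choice.
3. **Split and join.** The two query halves are scanned ungapped within the
   gap cap; best placements a shift apart are joined with one bridging gap
   (penalty = sum of halves + open + |shift|·ext). The joined alignment is
   used as a branch-and-bound incumbent, not as the final answer: the exact
   search always follows, so a suboptimal join can never surface. (The
   specified recursion of the split is therefore unnecessary and omitted.)
4. **A\* over the lazy grid.** States are (query consumed, window consumed,
   lane ∈ {match, insertion, deletion, leading-clip}, gap-run); x-moves
   consume query bases, y-moves reference bases; unused window ends are
   free; soft clips are allowed only against contig ends. The heuristic is
   the suffix piece count times the cheapest per-mutation cost —
   min(snp, extend[, ambiguity if the window has codes][, clip if clipping
   is possible]) — which, unlike snp alone, is admissible, so the returned
   penalty equals the full-DP optimum exactly (fuzz-verified on 1000+
   instances against an independent DP). Gap runs longer than the cap are
   pruned; run-tracking is skipped when the cap exceeds both extents (it
   can never bind). Before searching, a cheap vectorized scan of ungapped
   and one-gap split placements supplies a valid-alignment upper bound used
   as the initial incumbent; pruning at `f > incumbent` keeps all optimal
   paths since the bound is achievable.

Equal-penalty alignments are ordered by (reference id, position, strand).
Paired-end mates are aligned independently; `combined_pair_score` adds a
spacing term proportional to the point-mutation penalty per 100 bp of
insert-size deviation — a documented stand-in, excluded from any
quantitative claim. MAPQ is emitted as 255 (unavailable).

## Synthetic data

`simulate_reference` draws an i.i.d. uniform genome and optionally embeds
(non-overlapping) duplications of one unit at a controllable identity and
annotates variant-dense windows (elevated SNP rate for reads overlapping
them). `simulate_reads` samples positions and strands uniformly and applies
per-base point mutations and indels, emitting an exact truth record (offset,
strand, event list, penalty). Defaults are the study conditions used by the
acceptance tests: 150 bp reads, SNP rate 2e-2, indel rate 2e-3 per base
with geometric(0.5) lengths truncated at 10 bp, 100 kb genome, 1000 reads.
Indels are kept out of the first/last 5 bp of a read so the truth offset is
unambiguous; consecutive indel events are scored as separate gaps, so the
truth penalty is an upper bound and the aligner may legitimately report a
cheaper arrangement. Not emulated: base-quality error profiles, GC bias,
real repeat families and mobile elements, and sequencing chimeras — so
passing tests demonstrate algorithmic correctness at the stated mutation
densities, not performance on any real library.

`inject_divergence` substitutes bases at a given density (each mutation
guaranteed to change the base), covering the divergent-reference scenarios
(5e-4 through 5e-2).

## Evaluation

Penalties of any run are recomputed from CIGAR + position against the
reference; tags are never trusted. Alignments above 10% divergence
(penalty > snp · 0.10 · read length, mirroring the per-base bound) are
excluded. A read's minimum recomputed penalty across runs defines optimal;
suboptimal alignments classify as failed-to-align / wrong site (>100 bp away
or another contig) / close site (≤100 bp) / same site with higher penalty.
Consistency against a superset reference holds when the simple-reference
optimum is reproduced or strictly beaten. Effective abundance drops genomes
under 5% coverage from each read's target set and splits the read's unit
weight evenly among the survivors; "coverage" is breadth (fraction of
positions covered ≥1×), the simplest reading consistent with the filter's
purpose, and is flagged as such in the API docs.

## Problem sizes and oracles

The test oracles are independent implementations: a row-by-row affine DP
(numpy, prefix-min trick for in-row deletions) for alignment penalties and
a base-by-base CIGAR walker for rescoring. The acceptance suite runs the
A*-vs-DP fuzz at 1000 instances (reads up to 200 bp), the end-to-end
recovery at the study conditions above with the DP oracle applied to a
±400 bp window around the truth locus (the genome is repeat-free, so the
windowed optimum is the global one), and the certificate-soundness check on
a 3 kb genome × 500 reads with a full-genome, both-strand DP oracle. These
sizes were chosen as the smallest at which the statistics are stable.

## Known limitations

Memory and speed are not tuned for large (e.g. mammalian) references; the
index stores every qualifying gapped x-mer. Long reads and intron-spanning
alignment are out of scope. The walk records one path, so a query whose
informative seeds all sit in saturated bins can go unaligned even when a
within-budget alignment exists; the ≥2-seed support rule likewise trades a
small amount of sensitivity for robustness against hash collisions.
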