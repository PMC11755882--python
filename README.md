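# xmeralign

Short-read alignment with **gapped variable-length seeds**. Fixed-size
k-mer seeding faces a dilemma on real genomes: any k is simultaneously too
long for variant-dense regions (every k-mer overlaps a mutation and matches
nowhere) and too short for duplicated regions (every k-mer matches dozens of
copies). `xmeralign` indexes the reference through a content-driven *pyramid
of x-mers* — seeds of every length from 1 bp up, built by deterministic
merging of adjacent seeds — and expands each informative x-mer into a
*gapped x-mer*: the seed, an ignored gap of about half its length, and a
post-gap extension, hashed over the non-gap contents only so that a seed can
skip straight over a cluster of mutations. Reads are then aligned end to end
with an exact, penalty-minimizing extension stage (A\* over a lazy
Needleman–Wunsch grid), so the reported penalty equals the dynamic-
programming optimum at the reported site.

The package is aimed at readers and tool builders in microbial genomics who
want a transparent, exactly-scoring reference aligner: every stage (seeding,
candidate search, penalty bounds, extension) is an importable, separately
tested function. It also ships the surrounding evaluation machinery
(cross-run optimality comparison with CIGAR rescoring, suboptimal-cause
classification, simple-vs-complex-reference consistency, effective
abundance) and a deterministic synthetic-data generator, so the whole
pipeline runs at desk scale with no downloads.

## The model

An alignment is scored by an additive penalty (lower is better):

- point mutation: `snp_penalty` per mismatched base,
- gap: `new_indel_penalty + len * extend_indel_penalty`
  (the extension applies to **every** gap base, including the first),
- ambiguous-base match (e.g. read `A` vs reference `N`):
  `ambiguity_penalty` per base,
- soft clip (only where a read overhangs a contig end): 1 per clipped base.

A read of length *L* is reportable iff its penalty is at most
`max_penalty * L`; with the package's default setting
(`--max-penalty 1.00 --snp-penalty 10`) that is 10 point mutations per
100 bp. Four named presets (`setting1`..`setting4`) reproduce the default
scoring of the common short-read aligners for like-for-like comparisons.

Seeding statistics: each pyramid level keeps roughly 3/4 of the previous
level's adjacent pairs, so the whole pyramid holds fewer than about 4× the
sequence length in x-mers; hash bins are capped at `used_bp` positions so
repeats cannot flood the table; seeds expected to match more than ~16 places
in a random reference are never generated.

## Worked example

```python
from xmeralign import (PRESETS, SimConfig, align_read, build_index,
                       score_events, simulate_reference)

s1 = PRESETS["setting1"]          # snp 6, gap open 5, extend 3, clip 1
print(score_events([("insertion", 5), ("mismatch", 2), ("insertion", 2),
                    ("deletion", 2), ("mismatch", 2)], s1))   # -> 66
print(score_events([("mismatch", 1), ("insertion", 9),
                    ("insertion", 5), ("mismatch", 2)], s1))  # -> 70

refs, _ = simulate_reference(SimConfig(genome_length=20_000, seed=7))
index = build_index(refs)
genome = refs[0][1]
read = genome[8000:8100] + genome[8104:8150]    # 4 bp deletion
for a in align_read(read, index, s1):
    print(a.pos, a.strand, a.penalty, a.cigar)
# -> 8000 + 17 100M4D46M
```

The two `score_events` calls score two disagreeing arrangements of the same
read: 66 (5 bp insertion + 2 mismatches + 2 bp insertion + 2 bp deletion +
2 mismatches) beats 70, so the first arrangement is the optimal one. The
aligned read reports penalty 17 = gap open 5 + 4 × extend 3, exactly the
cost of the simulated 4 bp deletion.

The `examples/` directory has one short narrative script per capability
(scoring, indexing/alignment, simulation + evaluation, abundance and
consistency); each prints the numbers it computes and what they mean. A thin
command-line interface (`xmeralign align|simulate-reference|simulate-reads|
inject-divergence|compare-runs`) exposes the same functionality with the
penalty flags named `--max-penalty`, `--snp-penalty`, `--new-indel-penalty`,
`--extend-indel-penalty`, `--ambiguity-penalty`, `--max-penalty-span`, plus
the seeding ablations `--no-gapmers` and `--block-length k`.

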