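"""Score alignment arrangements under the four penalty presets.

Two aligners can place the same read at the same locus with different
arrangements of matches, mismatches, gaps and clips; the additive penalty
model decides which arrangement is better. This example scores the two
arrangements of one read (an indel-rich arrangement vs a longer-gap one)
and prints the acceptance bound for a 100 bp read under each preset.
"""

from xmeralign import PRESETS, max_allowed_penalty, score_cigar, score_events

best = [("insertion", 5), ("mismatch", 2), ("insertion", 2),
        ("deletion", 2), ("mismatch", 2)]
worse = [("mismatch", 1), ("insertion", 9), ("insertion", 5), ("mismatch", 2)]

s1 = PRESETS["setting1"]
print("arrangement A penalty (setting1):", score_events(best, s1))    # 66
print("arrangement B penalty (setting1):", score_events(worse, s1))   # 70
print("-> A is the better (lower-penalty) arrangement of the same read")

for name in sorted(PRESETS):
    cfg = PRESETS[name]
    print(f"{name}: max allowed penalty for a 100 bp read ="
          f" {max_allowed_penalty(100, cfg)}")

# rescoring from a CIGAR string against the reference
ref = "ACGTACGTACGTACGT"
read = "ACGTACGAACGT"
events, penalty = score_cigar("12M", read, ref, 0, s1)
print("CIGAR 12M with one mismatch rescored:", penalty, events)
# penalty 6: one point mutation at setting1's snp penalty
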