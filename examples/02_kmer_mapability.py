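"""Classify k-mer mapability and query probe-grade uniqueness.

A repeat tract embedded in random sequence shows up as REPETITIVE;
positions whose 20-mer is unique and has no second site within one
mismatch are UNIQUE_D1 — the class probe anchors must come from.
"""

from osseq.kmer import classify_positions, is_unique_with_margin
from osseq.simulate import simulate_genome

genome, repeats = simulate_genome(
    4000, seed=5, repeat_fraction=0.08, repeat_tract_len=300
)
track = classify_positions(genome, k=20, margin_mismatches=1)

print("classification counts:", track.counts())
print("repeat tracts implanted:", repeats)

seq = genome["chr1"].seq
kmer = seq[100:120]
print(
    f"20-mer at position 100 unique with 1-mismatch margin: "
    f"{is_unique_with_margin(kmer, genome, 1)}"
)
rep_kmer = seq[repeats[0][1] + 50 : repeats[0][1] + 70]
print(
    f"20-mer inside the repeat tract unique: "
    f"{is_unique_with_margin(rep_kmer, genome, 1)}"
)
print(
    "UNIQUE_D1 positions admit probes; the tract is rejected both as a "
    "probe terminus and as adjacent sequence."
)
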