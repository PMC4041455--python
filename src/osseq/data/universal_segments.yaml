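# Default universal oligo segments appended 3' of the target-specific
# 40-mer.  `universal_mid` is the read-2 sequencing-primer region (37 nt)
# and `p7_complement` is the flow-cell P7-lawn complement (24 nt); the two
# must sum to 61 nt so the assembled probe oligo is exactly 101 nt.
# Both are configurable: pass an alternative file to load_universal_segments.
universal_mid: AGATCGGAAGAGCGGTTCAGCAGGAATGCCGAGACCG
p7_complement: ATCTCGTATGCCGTCTTCTGCTTG
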