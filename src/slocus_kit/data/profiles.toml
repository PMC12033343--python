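# Domain-motif profiles for the candidate S-gene screen.
#
# Each motif is a residue-class pattern in bracket syntax; a window scores
# as the fraction of positions whose residue falls in its class, and every
# occurrence scoring >= min_score is reported.  These defaults are
# conservative placeholders (RNase T2 active-site boxes and an F-box
# consensus), not reproductions of curated HMM libraries — edit freely.

[[profile]]
name = "RNase_T2"
motifs = ["[FY]T[IVL]HG[LI]WP", "[KR]HG[ST]C"]
min_score = 0.8

[[profile]]
name = "F-box"
motifs = ["[LIVM]P[DE][DE][LIVM][LIVM]", "W[KR][DE][LIVM][PS]"]
min_score = 0.8
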