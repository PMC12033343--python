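# Signature-classification criteria for functional S-RNases.
#
# pattern4 carries its published residue-class definition and is searched
# only between the pattern-2 match and the C3 domain.  pattern1 and
# pattern2 are PLACEHOLDERS matching the synthetic templates; for analyses
# of real sequences they must be replaced with the curated motif
# definitions from the primary literature.

max_introns = 2
pi_min = 8.0
pi_max = 10.0
required_domains = ["C1", "C2", "C3", "C4", "C5", "RHV"]
require_c3_lysine = false
require_style_expression = true

[[pattern]]
name = "pattern1"
classes = "[FY]T[IVL]HG[LI]WP"
window = "whole_protein"

[[pattern]]
name = "pattern2"
classes = "[KR]HG[ST]C"
window = "whole_protein"

[[pattern]]
name = "pattern4"
classes = "[CG]P[QLRSTIK][DGIKNPSTVY][ADEIMNPSTV][DGKNQST]"
window = "between_pattern2_and_C3"
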