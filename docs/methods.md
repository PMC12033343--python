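# Methods

`slocus-kit` implements the desk-scale analyses used to decide whether a
candidate genomic region behaves like a functional S-RNase-based
gametophytic self-incompatibility (GSI) locus. This note records the models,
the tunable parameters that matter, what the synthetic-data generator does
and does not emulate, and the numerical choices made where the design was
genuinely open.

## The biological question

In Rosaceae GSI, the pistil determinant is an S-RNase (a style-expressed
T2-family ribonuclease) and the pollen determinant is one or more F-box
proteins. Two locus architectures exist: a Prunus-type locus with a single
S-RNase and a single SFB (self-recognition), and a Maleae-type locus with
multiple S-RNases and multiple SFBB paralogs (nonself-recognition). Deciding
which architecture is functional in a given genome combines several weak
signals — gene structure, protein motifs, charge, expression, polymorphism,
selective pressure, duplication history — and this package makes each of
those signals a tested, reusable operation.

## Signature classification

A candidate qualifies as a functional S-RNase only if all configured
criteria hold simultaneously:

* **Gene structure** — at most 2 introns (intron count = exon count − 1,
  taken from the transcript with the most exons when several exist: the
  conservative, worst-case reading).
* **Full-length CDS** — in frame, ATG-initiated, stop-terminated, no
  internal stop.
* **Motifs** — patterns 1 and 2 present, S-lineage pattern 4 absent.
  Pattern 4 ships with its published residue-class string
  `[CG]P[QLRSTIK][DGIKNPSTVY][ADEIMNPSTV][DGKNQST]` and is searched only
  between the pattern-2 match and the C3 domain. Patterns 1 and 2 are
  **placeholders** (active-site-box-like motifs matching the synthetic
  templates); their published definitions are distributed in the primary
  motif literature, not reproduced here, and must be supplied in the config
  for real analyses.
* **Basic isoelectric point** — 8 ≤ pI ≤ 10. pI is the bisection root of
  the Henderson–Hasselbalch net charge on pH ∈ [0, 14] (tolerance 1e-3),
  with the EMBOSS pKa set (N-term 8.6, K 10.8, R 12.5, H 6.5, D 3.9,
  E 4.1, C 8.5, Y 10.1, C-term 3.6). The table is replaceable; the 8–10
  window is robust to the choice.
* **Domains** — C1–C5 and the Rosaceae hypervariable region (RHV) are
  located by globally aligning the candidate to an annotated reference and
  projecting the reference's domain intervals; a domain counts as found
  when ≥ 50% of its reference columns align to candidate residues.
* **Expression** — style/stigma-specific profile (below).

The conserved C3 active-site lysine is reported (intact / substituted /
unalignable via the same projection) but does **not** veto the verdict by
default: K→T substitutions occur in otherwise functional S-RNases, so the
observation is informative rather than disqualifying.

Every criterion is evaluated independently, so a failing candidate is
annotated with exactly the criteria it fails — the property the truth-
recovery tests assert.

## Homology screen

The genome screen stands in for a BLAST + conserved-domain search with two
self-contained components: optimal Smith–Waterman alignment (BLOSUM62, X
scores 0, gap open 11 / extend 1) of candidate proteins against classed
reference sets, and residue-class motif profiles (RNase T2 active-site
boxes; an F-box consensus) scored by match fraction (default threshold
0.8). Instead of an e-value, a hit needs score ≥ 50, identity ≥ 35% and
≥ 50 aligned columns — deterministic and configurable. Unannotated sequence
is translated in six frames and must carry both a domain hit and a passing
reference alignment. Hits sharing > 50% reciprocal overlap are merged (best
score; ties to the leftmost start, then lexicographic reference id).

## Expression

Counts → TPM (`rate = count/length`, scaled to 1e6 per sample; gene length
is the union exon length). Tissue calls use mean TPMs with thresholds
τ_on = 1 and τ_high = 10 TPM (conventional detection limits; no published
threshold exists for this criterion, and raw means are always reported so
the calls are auditable): style-specific requires style ≥ τ_high with both
male tissues < τ_on; male-specific is symmetric; everything below τ_on is
silent; the rest is broad. Fold differences use a 0.5 pseudocount. Tukey
HSD letters are computed on log2(TPM+1) (variance stabilisation) with a
pooled error term and the studentised-range distribution; letters are
assigned by the insert-and-absorb algorithm with groups ordered by
descending mean, so output is independent of input order.

## Polymorphism

Pairwise identity = identical columns / alignment columns after excluding
terminal overhangs (alleles recovered from transcripts differ in UTR
extent), with internal gaps counting as differences; nucleotide scoring
+1/−1/−2, protein BLOSUM62 with open 10 / extend 1. SNP density counts
alignment columns with ≥ 2 distinct non-gap bases (multi-allelic columns
once), binned by reference coordinate; the last partial window is kept.

## Selection

The codon model family is the standard 61-sense-codon Markov chain:
`q_ij = π_j · {1, κ, ω, κω}` for synonymous/nonsynonymous
transversions/transitions between single-nucleotide neighbours, scaled to
one expected substitution per codon per unit branch length. Implemented
models: M0 (one ω), a two-ratio branch model (foreground branches marked
`#1` in the Newick), and branch-site model A with site classes 0, 1, 2a, 2b
(proportions p0, p1, p2a = (1−p0−p1)p0/(p0+p1), p2b analogous) with ω2
fixed at 1 (null) or free ≥ 1 (alternative).

Numerics: transition matrices via eigendecomposition of the π-symmetrised
generator (reversibility gives a real spectrum); Felsenstein pruning with
per-node rescaling and site-pattern compression; codon frequencies equal or
F3x4 (positional nucleotide frequencies renormalised over sense codons).
Fitting maximises the likelihood by L-BFGS-B on log-transformed κ and ω
and nested-logistic proportions, with multi-start (default 3) and fixed
seeds. Branch lengths are fixed to the input tree: re-estimating them per
model is out of scope at desk scale, and the recovery experiments show the
ω contrast is insensitive to this at the simulated divergences. LRTs use
χ²₁ for both the branch test and the branch-site A test (the common
practice of the reference tooling; the boundary-mixture refinement is a
documented non-goal). The simulator draws root codons from π and evolves
sites with the same matrices, so stop codons can never appear.

## F-box lineage assignment

Queries and labelled references (SFB / SFBB / SLFL) enter one progressive
multiple alignment (biotite); pairwise distances are Kimura-corrected
p-distances (−ln(1 − p − 0.2p²), saturation-capped) — a deliberate
lightweight substitute for full ML protein models, adequate for clade
membership; trees are neighbor-joining (scikit-bio). A query takes the
lineage of the smallest bipartition side containing it and ≥ 1 reference
with all references of one lineage; support is the fraction of 100
column-bootstrap replicates reproducing the call, with calls below 0.7 (or
size-ties between lineages) reported as outgroup. References with no
cohesion to their own lineage mates, and queries whose nearest reference
distance exceeds 1.5, are treated as uninformative/unalignable.

## Synteny and segmental duplications

Exact k-mer anchors (default k = 15) on both strands are grouped into
(anti-)diagonal runs, chained colinearly with gaps ≤ 1 kb — a gap is only
bridged when its own aligned identity passes the filter, so unrelated
colinear segments are never fused — trimmed at the ends (small terminal
anchor clusters across long sub-threshold gaps are chance matches in
diverged flanks such as border repeats), and extended by ungapped X-drop
(match +1, mismatch −4, drop 10). Block identity combines exact anchor
columns with alignments of the inter-anchor gaps. Default filters are
min length 300 bp and min identity 78% for cross-sequence synteny (the
dot-plot connector defaults; per-figure variants are flags) and 5 kb / 90%
for the self-vs-self duplication search, which removes the trivial
diagonal, merges mirrored hits, and annotates whether 1 kb flanking windows
match a supplied border-repeat library (local alignment score ≥ 0.4 ×
repeat length).

## Synthetic data: what it emulates, and what a green test establishes

The generator states the world the tests live in:

* **Architectures** — Prunus-type (1 functional S-RNase + 1 SFB + 4 SLFL)
  and Maleae-type (5 S-RNases each carrying exactly one defect —
  truncation, acidic pI, pattern-4 insertion, 3 introns, male-tissue
  expression — plus 3 near-identical SFBB, one at 94% identity, and one
  20 kb / 98% duplication with 500 bp border repeats at 80% identity to
  their family consensus). Defects are planted surgically (e.g. the
  truncating stop sits immediately before the terminal stop; acidic
  substitutions avoid motif and domain spans) so each defect falsifies
  exactly one criterion.
* **Templates** — the S-RNase and F-box template proteins are synthetic
  stand-ins constructed to carry the classifier's motifs, domain layout,
  an active-site lysine and a basic pI (≈ 9.4); they are not natural
  sequences. Back-translation uses a fixed preferred-codon table
  (deterministic, frame-safe); introns are GT…AG, 80–300 bp.
* **Expression** — negative-binomial counts with variance μ + αμ² (α is
  the RNA-seq dispersion; α = 0 gives the Poisson limit), three tissues ×
  3 replicates, over a 1000-gene broad background transcriptome so that
  TPM magnitudes are realistic. Style means encode the 30× contrast
  between the functional and the Maleae-type S-RNase.
* **Alleles** — mutated back-translations whose realised pairwise
  identities are corrected iteratively until the whole set measures inside
  the requested band *by the diversity module itself* (closing the loop
  between generator and measurement); divergent (64–72%) vs conserved
  (99–100%) series mirror the Prunus-like vs Maleae-like contrast.
* **Codon alignments** — simulated under the selection module's own
  transition matrices.

Not emulated: read-level sequencing noise, alternative splicing, TE
landscapes beyond border repeats, individual-level expression effects, and
indel polymorphism in allele series. A green truth-recovery test therefore
establishes that the analysis operations are correct and internally
consistent on clean, structurally realistic inputs — not that their
thresholds are calibrated for any particular real genome.

## Degenerate inputs and tie-breaks

Zero-length branches short-circuit to exact identity matrices (so
contradictory data yields an explicit error, not a rounding artefact);
all-zero expression samples warn and stay zero; saturated protein distances
are capped; equal-support lineage ties go to outgroup; duplicate mirror
blocks keep the copy whose first interval starts leftmost.

## Known limitations

Pattern-1/2 defaults are placeholders (above). The screen's thresholds are
bit-score heuristics, not calibrated e-values. Branch lengths are not
re-estimated per codon model. The NJ-based lineage assignment has no ML
tree search. The synteny chainer targets locus-scale (≤ a few hundred kb)
sequences, not chromosome-scale whole-genome alignment.
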