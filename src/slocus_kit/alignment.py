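"""Thin wrappers around Bio.Align pairwise aligners with the package's
default scoring schemes, plus identity computation from alignments.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


def _blosum62_x_zero():
    m = _BLOSUM62.copy()
    alpha = m.alphabet
    xi = alpha.index("X")
    for j in range(len(alpha)):
        m[xi, j] = 0.0
        m[j, xi] = 0.0
    return m


BLOSUM62_X0 = _blosum62_x_zero()


def validate_protein(seq: str, *, allow_x: bool = True) -> str:
    s = seq.upper()
    allowed = PROTEIN_ALPHABET | ({"X"} if allow_x else set())
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"non-residue characters in protein: {sorted(bad)}")
    return s


def protein_local_aligner(gap_open: float = 11, gap_extend: float = 1) -> PairwiseAligner:
    """Smith-Waterman, BLOSUM62 (X scores 0), affine gaps.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.
    """
    return PairwiseAligner(
        mode="local",
        substitution_matrix=BLOSUM62_X0,
        open_gap_score=-gap_open,
        extend_gap_score=-gap_extend,
    )


def protein_global_aligner(gap_open: float = 10, gap_extend: float = 1) -> PairwiseAligner:
    return PairwiseAligner(
        mode="global",
        substitution_matrix=BLOSUM62_X0,
        open_gap_score=-gap_open,
        extend_gap_score=-gap_extend,
    )


def nucleotide_global_aligner(match: float = 1, mismatch: float = -1, gap: float = -2) -> PairwiseAligner:
    return PairwiseAligner(
        mode="global",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=gap,
        extend_gap_score=gap,
    )


def nucleotide_local_aligner(match: float = 1, mismatch: float = -1, gap: float = -2) -> PairwiseAligner:
    return PairwiseAligner(
        mode="local",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=gap,
        extend_gap_score=gap,
    )


@dataclass
class AlignedPair:
    """A pairwise alignment flattened to gapped strings with coordinates."""

    score: float
    a_gapped: str
    b_gapped: str
    a_span: tuple[int, int]  # 0-based half-open span of a covered by the alignment
    b_span: tuple[int, int]

    @property
    def columns(self) -> int:
        return len(self.a_gapped)

    @property
    def identical(self) -> int:
        return sum(
            1 for x, y in zip(self.a_gapped, self.b_gapped) if x == y and x != "-"
        )


def flatten(alignment) -> AlignedPair:
    """Convert a Bio.Align.Alignment to gapped strings + spans."""
    blocks_a, blocks_b = alignment.aligned
    a = str(alignment.sequences[0])
    b = str(alignment.sequences[1])
    if len(blocks_a) == 0:
        return AlignedPair(alignment.score, "", "", (0, 0), (0, 0))
    ga: list[str] = []
    gb: list[str] = []
    prev_a, prev_b = blocks_a[0][0], blocks_b[0][0]
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        ga.append(a[prev_a:a0] + "-" * (b0 - prev_b))
        gb.append("-" * (a0 - prev_a) + b[prev_b:b0])
        ga.append(a[a0:a1])
        gb.append(b[b0:b1])
        prev_a, prev_b = a1, b1
    return AlignedPair(
        alignment.score,
        "".join(ga),
        "".join(gb),
        (int(blocks_a[0][0]), int(blocks_a[-1][1])),
        (int(blocks_b[0][0]), int(blocks_b[-1][1])),
    )


def identity_percent(pair: AlignedPair) -> float:
    """Identical columns over alignment columns, as a percentage.

    Terminal overhangs are already excluded for local alignments; for global
    alignments trim leading/trailing columns that are gaps in either row
    before counting (sequence-end overhangs are not evidence of divergence).
    """
    a, b = pair.a_gapped, pair.b_gapped
    i, j = 0, len(a)
    while i < j and (a[i] == "-" or b[i] == "-"):
        i += 1
    while j > i and (a[j - 1] == "-" or b[j - 1] == "-"):
        j -= 1
    cols = j - i
    if cols == 0:
        return 0.0
    ident = sum(1 for x, y in zip(a[i:j], b[i:j]) if x == y and x != "-")
    return 100.0 * ident / cols
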