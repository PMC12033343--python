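"""Genetic-code tables shared by the codon-model and simulation modules.

Universal (standard) code only.  The 61 sense codons are kept in a fixed
lexicographic order; every module that exchanges codon-state indices relies
on that order.
"""

from __future__ import annotations

import itertools

NUCLEOTIDES = "TCAG"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_CODE_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)

#: codon -> amino acid (one letter, '*' for stop) under the universal code
GENETIC_CODE: dict[str, str] = {
    a + b + c: _CODE_AA[i]
    for i, (a, b, c) in enumerate(itertools.product(NUCLEOTIDES, repeat=3))
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")

#: the 61 sense codons in lexicographic (ACGT) order — the canonical state order
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)  # 61

# Most-used codon per amino acid (human-like usage; any fixed choice works —
# back-translation only needs determinism and a valid reading frame).
PREFERRED_CODON: dict[str, str] = {
    "A": "GCC", "R": "AGA", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAG", "E": "GAG", "G": "GGC", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAG", "M": "ATG", "F": "TTC", "P": "CCA",
    "S": "TCC", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTG",
    "*": "TAA",
}

_COMPLEMENT = str.maketrans("ACGTRYKMacgtrykmNn", "TGCAYRMKtgcayrmkNn")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case (soft masking)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str, *, to_stop: bool = False) -> str:
    """Translate a coding sequence; trailing partial codon is ignored.

    Unknown or ambiguous codons translate to ``X``.
    """
    cds = cds.upper()
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = GENETIC_CODE.get(cds[i : i + 3], "X")
        if aa == "*" and to_stop:
            break
        out.append(aa)
    return "".join(out)


def back_translate(protein: str, *, stop: bool = True) -> str:
    """Deterministic back-translation using the preferred-codon table."""
    cds = "".join(PREFERRED_CODON[aa] for aa in protein.upper())
    return cds + (PREFERRED_CODON["*"] if stop else "")


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a<->b is a transition."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)
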