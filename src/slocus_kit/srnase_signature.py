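"""Molecular-signature classification of candidate S-RNases.

A functional pistil-side S-RNase is expected to show, simultaneously:

* a full-length coding sequence (ATG ... stop, no internal stop),
* at most two introns,
* amino-acid patterns 1 and 2 present and S-lineage pattern 4 absent
  (pattern 4 searched only between the pattern-2 match and the C3 domain),
* a basic isoelectric point (8 <= pI <= 10),
* the conserved C1-C5 domains and the Rosaceae hypervariable region (RHV),
* style/stigma-specific expression.

The classifier evaluates each criterion independently and reports the full
outcome matrix, so a failing candidate is annotated with exactly the
criteria it fails.  The conserved active-site lysine in C3 is reported
(intact / substituted / unalignable) but does not veto the verdict by
default: naturally occurring K->T substitutions are known in otherwise
functional S-RNases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .alignment import flatten, protein_global_aligner
from .gene_screen import parse_residue_classes
from .io_formats import GeneModel

# EMBOSS pKa values; the pI criterion window (8-10) is robust to the choice
# of table, and the table is replaceable.
EMBOSS_PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}

_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


@dataclass
class PatternSpec:
    """A residue-class pattern and where to search for it."""

    name: str
    classes: str  # bracket syntax, e.g. "[CG]P[QLRSTIK]..."
    window: str = "whole_protein"  # or "between_pattern2_and_C3"

    def __post_init__(self) -> None:
        self._parsed = parse_residue_classes(self.classes, self.name)

    def __len__(self) -> int:
        return len(self._parsed)


# Pattern 4 is the S-lineage diagnostic; its residue classes are published.
# Patterns 1 and 2 are placeholders standing in for the published motifs
# (distributed separately from the figure they appear in) and MUST be
# overridden with curated definitions for real analyses.
PATTERN4 = PatternSpec(
    "pattern4",
    "[CG]P[QLRSTIK][DGIKNPSTVY][ADEIMNPSTV][DGKNQST]",
    window="between_pattern2_and_C3",
)
DEFAULT_PATTERNS = [
    PatternSpec("pattern1", "[FY]T[IVL]HG[LI]WP"),
    PatternSpec("pattern2", "[KR]HG[ST]C"),
    PATTERN4,
]


@dataclass
class ReferenceSRnase:
    """An annotated reference used to project domain locations by homology."""

    ref_id: str
    protein: str
    domains: dict[str, tuple[int, int]]  # 0-based half-open in the reference
    active_site: int  # 0-based index of the conserved C3 lysine


@dataclass
class SignatureConfig:
    max_introns: int = 2
    pi_min: float = 8.0
    pi_max: float = 10.0
    patterns: list[PatternSpec] = field(default_factory=lambda: list(DEFAULT_PATTERNS))
    required_domains: frozenset[str] = frozenset({"C1", "C2", "C3", "C4", "C5", "RHV"})
    domain_min_coverage: float = 0.5
    pka_table: dict[str, float] = field(default_factory=lambda: dict(EMBOSS_PKA))
    reference: ReferenceSRnase | None = None
    require_c3_lysine: bool = False
    require_style_expression: bool = True
    expected_profile: str = "style_specific"


def load_signature_config(
    path: str | None = None, reference: "ReferenceSRnase | None" = None
) -> "SignatureConfig":
    """Build a :class:`SignatureConfig` from a TOML criteria file (the
    packaged defaults when no path is given)."""
    import tomllib

    if path is None:
        from importlib import resources

        raw = tomllib.loads(
            resources.files("slocus_kit").joinpath("data/criteria.toml").read_text()
        )
    else:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    patterns = [
        PatternSpec(p["name"], p["classes"], p.get("window", "whole_protein"))
        for p in raw.get("pattern", [])
    ] or list(DEFAULT_PATTERNS)
    return SignatureConfig(
        max_introns=int(raw.get("max_introns", 2)),
        pi_min=float(raw.get("pi_min", 8.0)),
        pi_max=float(raw.get("pi_max", 10.0)),
        patterns=patterns,
        required_domains=frozenset(raw.get("required_domains", ["C1", "C2", "C3", "C4", "C5", "RHV"])),
        reference=reference,
        require_c3_lysine=bool(raw.get("require_c3_lysine", False)),
        require_style_expression=bool(raw.get("require_style_expression", True)),
    )


@dataclass
class SignatureReport:
    gene_id: str
    protein_length: int
    full_length: bool
    full_length_reason: str
    intron_count: int
    pattern1_present: bool
    pattern2_present: bool
    pattern4_absent: bool
    pI: float
    pI_basic: bool
    domains_found: list[str]
    c3_lysine: str  # intact / substituted:<res> / unalignable / not_evaluated
    expression_profile: str
    verdict: str  # "functional_candidate" or "fails"
    failed_criteria: list[str]


# ---------------------------------------------------------------------------


def count_introns(model: GeneModel) -> int:
    """Intron count = exon count - 1; strand-independent."""
    if not model.exons:
        raise ValueError(f"gene model {model.gene_id} has zero exons")
    return model.n_introns


def is_full_length(cds: str) -> tuple[bool, str]:
    """A CDS is full-length iff in frame, ATG-initiated, stop-terminated,
    with no internal stop codon."""
    if not cds:
        raise ValueError("empty CDS")
    s = cds.upper()
    if len(s) % 3 != 0:
        return False, "length not divisible by 3"
    if not s.startswith("ATG"):
        return False, "does not start with ATG"
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    stops = {"TAA", "TAG", "TGA"}
    if codons[-1] not in stops:
        return False, "no terminal stop codon"
    if any(c in stops for c in codons[:-1]):
        return False, "internal stop codon"
    return True, "ok"


def find_patterns(
    protein: str,
    specs: list[PatternSpec],
    pattern2_end: int | None = None,
    c3_position: int | None = None,
) -> dict[str, dict]:
    """Locate each residue-class pattern; every match position is reported.

    A windowed pattern (pattern 4) is searched only between the end of the
    pattern-2 match and the start of C3; if either bound is unknown the
    search falls back to the whole protein with a warning.
    """
    prot = protein.upper()
    out: dict[str, dict] = {}
    for spec in specs:
        lo, hi = 0, len(prot)
        if spec.window == "between_pattern2_and_C3":
            if pattern2_end is None or c3_position is None:
                warnings.warn(
                    f"{spec.name}: pattern-2/C3 window unknown, searching whole protein"
                )
            else:
                lo, hi = pattern2_end, c3_position
        positions = [
            i
            for i in range(lo, max(lo, hi - len(spec) + 1))
            if all(r in c for r, c in zip(prot[i : i + len(spec)], spec._parsed))
        ]
        out[spec.name] = {"present": bool(positions), "positions": positions}
    return out


def net_charge(protein: str, pH: float, pka: dict[str, float] | None = None) -> float:
    """Henderson-Hasselbalch net charge at a given pH (termini included)."""
    pka = pka or EMBOSS_PKA
    prot = protein.upper()
    q = 1.0 / (1.0 + 10 ** (pH - pka["Nterm"]))
    q -= 1.0 / (1.0 + 10 ** (pka["Cterm"] - pH))
    for aa in _POSITIVE:
        q += prot.count(aa) / (1.0 + 10 ** (pH - pka[aa]))
    for aa in _NEGATIVE:
        q -= prot.count(aa) / (1.0 + 10 ** (pka[aa] - pH))
    return q


def compute_pI(protein: str, pka_table: dict[str, float] | None = None, tol: float = 1e-3) -> float:
    """Isoelectric point by bisection of the net charge on pH in [0, 14]."""
    if not protein:
        raise ValueError("empty protein")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(protein, mid, pka_table) > 0:
            lo = mid
        else:
            hi = mid
    return round(0.5 * (lo + hi), 3)


def _global_alignment(query: str, ref: str):
    aligner = protein_global_aligner()
    return flatten(aligner.align(query.upper().replace("*", "X"), ref.upper())[0])


def _column_map(pair) -> list[int | None]:
    """For each reference index, the aligned query index (None for a gap)."""
    qi = ri = 0
    mapping: list[int | None] = []
    for qc, rc in zip(pair.a_gapped, pair.b_gapped):
        if rc != "-":
            mapping.append(qi if qc != "-" else None)
            ri += 1
        if qc != "-":
            qi += 1
    return mapping


def check_c3_lysine(protein: str, reference: ReferenceSRnase) -> str:
    """Report the query residue aligned to the reference's conserved C3
    lysine: ``intact``, ``substituted:<residue>`` or ``unalignable``."""
    pair = _global_alignment(protein, reference.protein)
    mapping = _column_map(pair)
    if reference.active_site >= len(mapping):
        return "unalignable"
    qpos = mapping[reference.active_site]
    if qpos is None:
        return "unalignable"
    res = protein.upper()[qpos]
    return "intact" if res == "K" else f"substituted:{res}"


def project_domains(
    protein: str, reference: ReferenceSRnase, min_coverage: float = 0.5
) -> tuple[list[str], int | None]:
    """Project reference domain intervals onto the query by global
    alignment.  A domain is found when at least ``min_coverage`` of its
    reference columns align to query residues.  Also returns the projected
    query position of the C3 domain start (for the pattern-4 window)."""
    pair = _global_alignment(protein, reference.protein)
    mapping = _column_map(pair)
    found: list[str] = []
    c3_start: int | None = None
    for name, (s, e) in sorted(reference.domains.items()):
        cols = [mapping[i] for i in range(s, min(e, len(mapping)))]
        aligned = [c for c in cols if c is not None]
        if len(cols) and len(aligned) / (e - s) >= min_coverage:
            found.append(name)
            if name == "C3":
                c3_start = aligned[0]
    return sorted(found), c3_start


# ---------------------------------------------------------------------------


def classify_srnase(
    model: GeneModel,
    protein: str,
    expression_profile: str | None = None,
    config: SignatureConfig | None = None,
) -> SignatureReport:
    """Evaluate all signature criteria for one candidate and aggregate the
    verdict.  The verdict is ``functional_candidate`` iff every configured
    criterion passes; otherwise every failing criterion is listed."""
    cfg = config or SignatureConfig()
    fails: list[str] = []

    introns = count_introns(model)
    if introns > cfg.max_introns:
        fails.append(f"more than {cfg.max_introns} introns")

    full, reason = is_full_length(model.cds)
    if not full:
        fails.append(f"not full length ({reason})")

    prot = protein.upper().split("*")[0] if "*" in protein else protein.upper()
    if not prot:
        prot = "X"

    domains_found: list[str] = []
    c3_start: int | None = None
    c3_status = "not_evaluated"
    if cfg.reference is not None:
        domains_found, c3_start = project_domains(prot, cfg.reference, cfg.domain_min_coverage)
        c3_status = check_c3_lysine(prot, cfg.reference)
        missing = cfg.required_domains - set(domains_found)
        if missing:
            fails.append("missing domains: " + ",".join(sorted(missing)))
        if cfg.require_c3_lysine and c3_status != "intact":
            fails.append("C3 active-site lysine not intact")

    specs = {s.name: s for s in cfg.patterns}
    base = find_patterns(prot, [s for s in specs.values() if s.window == "whole_protein"])
    p2 = base.get("pattern2", {"present": False, "positions": []})
    p2_end = p2["positions"][0] + len(specs["pattern2"]) if p2["present"] and "pattern2" in specs else None
    windowed = [s for s in specs.values() if s.window != "whole_protein"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        win = find_patterns(prot, windowed, pattern2_end=p2_end, c3_position=c3_start)
    results = {**base, **win}

    p1 = results.get("pattern1", {"present": False})["present"]
    p2p = results.get("pattern2", {"present": False})["present"]
    p4_absent = not results.get("pattern4", {"present": False})["present"]
    if not p1:
        fails.append("pattern1 absent")
    if not p2p:
        fails.append("pattern2 absent")
    if not p4_absent:
        fails.append("pattern4 present")

    pi = compute_pI(prot, cfg.pka_table)
    pi_basic = cfg.pi_min <= pi <= cfg.pi_max
    if not pi_basic:
        fails.append(f"isoelectric point {pi:.2f} outside [{cfg.pi_min}, {cfg.pi_max}]")

    expr = expression_profile if expression_profile is not None else "not_evaluated"
    if cfg.require_style_expression:
        if expression_profile is None:
            pass  # not evaluated; config says it does not block the verdict
        elif expression_profile != cfg.expected_profile:
            fails.append(f"expression profile {expression_profile} != {cfg.expected_profile}")

    return SignatureReport(
        gene_id=model.gene_id,
        protein_length=len(prot),
        full_length=full,
        full_length_reason=reason,
        intron_count=introns,
        pattern1_present=p1,
        pattern2_present=p2p,
        pattern4_absent=p4_absent,
        pI=pi,
        pI_basic=pi_basic,
        domains_found=domains_found,
        c3_lysine=c3_status,
        expression_profile=expr,
        verdict="functional_candidate" if not fails else "fails",
        failed_criteria=fails,
    )
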