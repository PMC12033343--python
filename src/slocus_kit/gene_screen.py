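"""Candidate S-gene detection: translated homology search plus domain-motif
scanning.

The screen emulates a BLAST + conserved-domain search step with a
self-contained Smith-Waterman aligner and editable residue-class motif
profiles.  An annotated gene model is a candidate when its protein aligns
to any reference above a bit-score/identity/length threshold; unannotated
sequence is scanned in all six reading frames and must additionally carry a
domain hit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .alignment import (
    AlignedPair,
    flatten,
    identity_percent,
    protein_local_aligner,
    validate_protein,
)
from .codons import revcomp, translate
from .io_formats import GeneModel, Interval, SeqRecord

# ---------------------------------------------------------------------------
# residue-class motif machinery (shared with the signature module)

_CLASS_RE = re.compile(r"\[([A-Z]+)\]|([A-Z])")


def parse_residue_classes(pattern: str, name: str = "pattern") -> list[frozenset[str]]:
    """Parse a bracket-syntax residue-class string like ``[CG]P[QLRSTIK]``.

    Returns one frozenset of allowed residues per position.  Raises
    ``ValueError`` naming the spec on malformed syntax.
    """
    pos = 0
    classes: list[frozenset[str]] = []
    while pos < len(pattern):
        m = _CLASS_RE.match(pattern, pos)
        if not m:
            raise ValueError(f"malformed residue-class syntax in {name!r} at offset {pos}")
        classes.append(frozenset(m.group(1) or m.group(2)))
        pos = m.end()
    if not classes:
        raise ValueError(f"empty residue-class pattern {name!r}")
    return classes


def match_fraction(window: str, classes: list[frozenset[str]]) -> float:
    """Fraction of positions whose residue falls in its class."""
    return sum(1 for r, c in zip(window, classes) if r in c) / len(classes)


@dataclass
class DomainProfile:
    """A named set of residue-class motifs with a match-fraction threshold."""

    name: str
    motifs: list[str]
    min_score: float = 0.8

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError(f"domain profile {self.name!r} has no motifs")
        self._classes = [parse_residue_classes(m, f"{self.name}:{m}") for m in self.motifs]


@dataclass
class DomainHit:
    profile: str
    motif: str
    position: int  # 0-based offset in the protein
    score: float


def scan_domains(protein: str, profiles: list[DomainProfile]) -> list[DomainHit]:
    """Report every motif occurrence scoring at or above its profile's
    ``min_score``; overlapping occurrences are all reported."""
    if not profiles:
        raise ValueError("empty profile list")
    prot = protein.upper()
    hits: list[DomainHit] = []
    for prof in profiles:
        for motif, classes in zip(prof.motifs, prof._classes):
            w = len(classes)
            for i in range(len(prot) - w + 1):
                s = match_fraction(prot[i : i + w], classes)
                if s >= prof.min_score:
                    hits.append(DomainHit(prof.name, motif, i, s))
    return hits


def load_profiles(path: str | None = None) -> list[DomainProfile]:
    """Load motif profiles from a TOML file (the packaged conservative
    defaults when no path is given — editable placeholders, not curated
    HMM reproductions)."""
    import tomllib

    if path is None:
        from importlib import resources

        raw = tomllib.loads(
            resources.files("slocus_kit").joinpath("data/profiles.toml").read_text()
        )
    else:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    return [
        DomainProfile(p["name"], list(p["motifs"]), float(p.get("min_score", 0.8)))
        for p in raw.get("profile", [])
    ]


DEFAULT_PROFILES: list[DomainProfile] = load_profiles()


# ---------------------------------------------------------------------------
# pairwise homology search


def local_align_protein(query: str, target: str, gap_open: float = 11, gap_extend: float = 1) -> AlignedPair:
    """Optimal Smith-Waterman local alignment under BLOSUM62 (X scores 0)
    with affine gaps; returns score, gapped strings and spans into both
    inputs.  Raises on empty input or non-residue characters."""
    if not query or not target:
        raise ValueError("empty sequence in local alignment")
    q = validate_protein(query)
    t = validate_protein(target)
    aligner = protein_local_aligner(gap_open, gap_extend)
    score = aligner.score(q, t)
    if score <= 0:
        return AlignedPair(0.0, "", "", (0, 0), (0, 0))
    return flatten(aligner.align(q, t)[0])


# ---------------------------------------------------------------------------
# genome screen


@dataclass
class ScreenThresholds:
    min_score: float = 50.0
    min_identity: float = 35.0
    min_aln_len: int = 50


@dataclass
class CandidateHit:
    gene_id: str  # empty for unannotated six-frame hits
    seq_id: str
    interval: Interval  # genomic, forward strand
    frame: int  # 0 for annotated models, else -3..+3
    best_reference: str
    ref_class: str
    score: float
    identity_pct: float
    aln_len: int
    domain_hits: list[DomainHit] = field(default_factory=list)


def partition_references(references: list[SeqRecord]) -> dict[str, list[SeqRecord]]:
    """Partition reference proteins by a ``class=...`` description token."""
    out: dict[str, list[SeqRecord]] = {}
    for rec in references:
        m = re.search(r"class=(\S+)", rec.description)
        cls = m.group(1) if m else "unclassified"
        out.setdefault(cls, []).append(rec)
    return out


def six_frame_translations(seq: str) -> dict[int, str]:
    """Peptides for frames +1..+3 (forward offsets 0..2) and -1..-3
    (reverse-complement offsets 0..2)."""
    rc = revcomp(seq)
    frames: dict[int, str] = {}
    for off in range(3):
        frames[off + 1] = translate(seq[off:])
        frames[-(off + 1)] = translate(rc[off:])
    return frames


def _best_reference_hit(
    protein: str, refs_by_class: dict[str, list[SeqRecord]], thresholds: ScreenThresholds
) -> tuple[str, str, AlignedPair] | None:
    best: tuple[float, str, str, AlignedPair] | None = None
    for cls in sorted(refs_by_class):
        for ref in sorted(refs_by_class[cls], key=lambda r: r.id):
            pair = local_align_protein(protein, validate_protein(ref.seq))
            ident = identity_percent(pair)
            if (
                pair.score >= thresholds.min_score
                and ident >= thresholds.min_identity
                and pair.columns >= thresholds.min_aln_len
            ):
                key = (pair.score, ref.id, cls, pair)
                if best is None or key[0] > best[0]:
                    best = key
    if best is None:
        return None
    _, ref_id, cls, pair = best
    return ref_id, cls, pair


def _frame_to_genomic(frame: int, pep_span: tuple[int, int], seg_len: int) -> tuple[int, int]:
    """Map a peptide span in one reading frame back to segment coordinates."""
    off = abs(frame) - 1
    nt0 = off + 3 * pep_span[0]
    nt1 = off + 3 * pep_span[1]
    if frame > 0:
        return nt0, nt1
    return seg_len - nt1, seg_len - nt0


def _unannotated_segments(seq_len: int, models: list[GeneModel], pad: int = 0) -> list[Interval]:
    covered = sorted((m.span.start, m.span.end) for m in models)
    merged: list[list[int]] = []
    for s, e in covered:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out: list[Interval] = []
    prev = 0
    for s, e in merged:
        if s - prev > pad:
            out.append(Interval(prev, s))
        prev = e
    if seq_len - prev > pad:
        out.append(Interval(prev, seq_len))
    return out


def _dedup(hits: list[CandidateHit]) -> list[CandidateHit]:
    """Merge hits sharing >50% reciprocal interval overlap on one sequence;
    keep the best score, ties broken by leftmost start then reference id."""
    hits = sorted(
        hits, key=lambda h: (-h.score, h.interval.start, h.best_reference)
    )
    kept: list[CandidateHit] = []
    for h in hits:
        merged = False
        for k in kept:
            if k.seq_id != h.seq_id:
                continue
            ov = k.interval.overlap(h.interval)
            if ov > 0.5 * len(k.interval) and ov > 0.5 * len(h.interval):
                merged = True
                break
        if not merged:
            kept.append(h)
    kept.sort(key=lambda h: (h.seq_id, h.interval.start, h.gene_id))
    return kept


def find_candidate_sgenes(
    genome: list[SeqRecord],
    gene_models: list[GeneModel],
    references: list[SeqRecord],
    profiles: list[DomainProfile] | None = None,
    thresholds: ScreenThresholds | None = None,
    *,
    scan_unannotated: bool = True,
    min_segment: int = 200,
) -> list[CandidateHit]:
    """Screen annotated models and unannotated six-frame windows for
    homology to reference S-genes; deduplicate by interval overlap."""
    if not references:
        raise ValueError("empty reference set")
    profiles = DEFAULT_PROFILES if profiles is None else profiles
    thresholds = thresholds or ScreenThresholds()
    refs_by_class = partition_references(references)
    hits: list[CandidateHit] = []

    for model in gene_models:
        protein = translate(model.cds).replace("*", "X")
        if not protein:
            continue
        best = _best_reference_hit(protein, refs_by_class, thresholds)
        if best is None:
            continue
        ref_id, cls, pair = best
        hits.append(
            CandidateHit(
                gene_id=model.gene_id,
                seq_id=model.seq_id,
                interval=model.span,
                frame=0,
                best_reference=ref_id,
                ref_class=cls,
                score=pair.score,
                identity_pct=round(identity_percent(pair), 2),
                aln_len=pair.columns,
                domain_hits=scan_domains(protein, profiles),
            )
        )

    if scan_unannotated:
        by_seq: dict[str, list[GeneModel]] = {}
        for m in gene_models:
            by_seq.setdefault(m.seq_id, []).append(m)
        for rec in genome:
            for seg in _unannotated_segments(len(rec.seq), by_seq.get(rec.id, []), pad=min_segment):
                segment = rec.seq[seg.start : seg.end]
                for frame, pep in six_frame_translations(segment).items():
                    pep = pep.replace("*", "X")
                    if len(pep) < thresholds.min_aln_len:
                        continue
                    dhits = scan_domains(pep, profiles)
                    if not dhits:
                        continue
                    best = _best_reference_hit(pep, refs_by_class, thresholds)
                    if best is None:
                        continue
                    ref_id, cls, pair = best
                    nt0, nt1 = _frame_to_genomic(frame, pair.a_span, len(segment))
                    hits.append(
                        CandidateHit(
                            gene_id="",
                            seq_id=rec.id,
                            interval=Interval(seg.start + nt0, seg.start + nt1),
                            frame=frame,
                            best_reference=ref_id,
                            ref_class=cls,
                            score=pair.score,
                            identity_pct=round(identity_percent(pair), 2),
                            aln_len=pair.columns,
                            domain_hits=dhits,
                        )
                    )

    return _dedup(hits)
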