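"""Synthetic S-locus generator with machine-readable ground truth.

Every downstream stage of the pipeline is exercised on data produced here:

* ``generate_locus`` builds a toy chromosome carrying gene cassettes in one
  of two architectures — a Prunus-type locus (single S-RNase, single SFB,
  several SLFL accessory F-boxes) or a Maleae-type locus (several S-RNases
  of which at least one is defective, up to three near-identical SFBB
  paralogs) — plus optional multi-kb segmental duplications bordered by a
  shared repeat family;
* ``generate_expression`` draws negative-binomial counts per gene x tissue
  x replicate emulating style-specific S-RNase and pollen/stamen-specific
  F-box expression;
* ``generate_allele_sets`` creates allele series of controlled pairwise
  nucleotide identity (divergent Prunus-like vs conserved Maleae-like);
* ``simulate_codon_alignment`` evolves codon alignments under the
  selection module's one-ratio / branch / branch-site models.

All generators are deterministic for a fixed seed.  The template proteins
below are synthetic stand-ins constructed to carry the motifs the
classifiers look for; they are not natural sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import selection
from .codons import back_translate, revcomp
from .diversity import pairwise_identity
from .expression import ExpressionMatrix
from .io_formats import GeneModel, Interval, SeqRecord
from .srnase_signature import ReferenceSRnase, compute_pI

# ---------------------------------------------------------------------------
# synthetic template proteins (fixed; see module docstring)

#: S-RNase-like template: pattern1 (C2) at 32, pattern2 at 50, C3 active-site
#: lysine at 75, basic pI (~9.4).  Synthetic stand-in, not a natural protein.
SRNASE_TEMPLATE = (
    "MGHDYPHPNIYGDFDYFQFVLQWPIRVPEMNGFTIHGLWPKRRIYLYTSEKHGTCPREGD"
    "SPVTTGFGLNQLNPLKEYTIQKRLTMRPFRHKIQQPIGLTSDIRGRTLPPMEGCNLVAWK"
    "YSDIVSPIKGENIQNTTT"
)
SRNASE_DOMAINS: dict[str, tuple[int, int]] = {
    "C1": (12, 24),
    "C2": (32, 40),  # == pattern1
    "C3": (69, 82),
    "RHV": (82, 96),
    "C4": (96, 108),
    "C5": (118, 130),
}
SRNASE_ACTIVE_SITE = 75  # K within C3
#: linker/hypervariable spans whose residues may be freely mutated without
#: touching a classification criterion other than pI
SRNASE_FREE_SPANS = [(24, 32), (40, 50), (55, 69), (82, 96), (108, 118), (130, 138)]
_SRNASE_MOTIF_SPANS = [(32, 40), (50, 55)] + list(SRNASE_DOMAINS.values())

#: F-box lineage templates (~55% mutually diverged around fixed F-box
#: motifs at 15-21 and 29-34).  Synthetic stand-ins.
SFB_TEMPLATE = (
    "MWDQVSSTFDYGVWNLPDELILTASLQCHWKDIPKFRGYTLMNVMYTMREHYLMECVGCC"
    "KRDMYLIRTPKWGWIIYDCEYQVWRNLHPRQEMGHTEVMTRPKSLLQWRPREQIPNDCAI"
    "NDCCIFWINYNHKPNPMFSRNWIHCWTYKQYFAQCHLCCTMGTTLHPWYNVDNEDHFNAI"
    "IFLPNAGDYKFRRATCNFTMLMKTCGFITFMDKHQQRKQKKYQQCNEQVI"
)
SFBB_TEMPLATE = (
    "MMPNVNHTFCVLVWILPDELILTDSNLTHWKDIPPGRHYSLHLYMYYGRPGTLFNSVETA"
    "KNDMYSTWTMKPGTIIYAFYYPITRCLAPTQTMYIVEMNTRQATLRGERQPVQTIKDHMA"
    "NCSHIHKYNCIHKPVQMMDENKIHCKTVKYRGAQFILGTQMNFVLDKWYIGDNGTKFSAN"
    "IVCQNNSIYKFFRPCWNYICLHKVCATITALGKGDMRKAQKVKKCWWTVD"
)
SLFL_TEMPLATE = (
    "MCFQVNCTFCGNVRALPDELIGDSSDWLHWKDIPVQRKEALMGFMYGSRDHVLYQEVPDF"
    "KWDAYLKTTPIFGQIFYFFSYQVFRRIYPDPEMSYVEWWTRWARLCFCRQPLQPCRDDKM"
    "NMHEIFGINYINKNKVMPYSNKIFCWHWKYRPAQIHLVCQMKCNLWPHYKGDNNHAFLAI"
    "ILRPNNLIYKFFRMHVNLTNLVASCARITWWDKYEHRGCMKARHCCDLVI"
)
_FBOX_MOTIF_SPANS = [(15, 21), (29, 34)]

TEMPLATES = {
    "srnase": SRNASE_TEMPLATE,
    "sfb": SFB_TEMPLATE,
    "sfbb": SFBB_TEMPLATE,
    "slfl": SLFL_TEMPLATE,
}

_AA = "ACDEFGHIKLMNPQRSTVWY"


def reference_srnase() -> ReferenceSRnase:
    """The template as an annotated classification reference."""
    return ReferenceSRnase(
        ref_id="synthetic_srnase_ref",
        protein=SRNASE_TEMPLATE,
        domains=dict(SRNASE_DOMAINS),
        active_site=SRNASE_ACTIVE_SITE,
    )


def screen_references() -> list[SeqRecord]:
    """Reference protein set for the homology screen, class-labelled."""
    return [
        SeqRecord("ref_srnase", SRNASE_TEMPLATE, "class=S-RNase"),
        SeqRecord("ref_sfb", SFB_TEMPLATE, "class=F-box"),
        SeqRecord("ref_sfbb", SFBB_TEMPLATE, "class=F-box"),
        SeqRecord("ref_slfl", SLFL_TEMPLATE, "class=F-box"),
    ]


def _mutate_protein(
    protein: str,
    identity_pct: float,
    rng: np.random.Generator,
    keep_spans: list[tuple[int, int]],
) -> str:
    keep = {i for s, e in keep_spans for i in range(s, e)}
    keep.add(0)
    p = list(protein)
    free = [i for i in range(len(p)) if i not in keep]
    n_mut = round(len(protein) * (1.0 - identity_pct / 100.0))
    if n_mut > len(free):
        raise ValueError("identity target needs more mutable positions than available")
    for i in rng.choice(free, size=n_mut, replace=False) if n_mut else []:
        p[i] = rng.choice([a for a in _AA if a != p[i]])
    return "".join(p)


def lineage_references(n_per_lineage: int = 2, seed: int = 42) -> list[SeqRecord]:
    """Reference F-box proteins with lineage labels, mildly diverged copies
    of each lineage template."""
    rng = np.random.default_rng(seed)
    out: list[SeqRecord] = []
    for lineage, tpl in (("SFB", SFB_TEMPLATE), ("SFBB", SFBB_TEMPLATE), ("SLFL", SLFL_TEMPLATE)):
        for i in range(n_per_lineage):
            prot = _mutate_protein(tpl, 92.0, rng, _FBOX_MOTIF_SPANS)
            out.append(SeqRecord(f"ref_{lineage}_{i+1}", prot, f"lineage={lineage}"))
    return out


# ---------------------------------------------------------------------------
# locus design


DEFECTS = ("truncation", "acidic_pi", "pattern4", "extra_introns", "male_expression")

#: defect -> category of the single signature criterion it must fail
DEFECT_CRITERION = {
    "truncation": "full_length",
    "acidic_pi": "pI",
    "pattern4": "pattern4",
    "extra_introns": "introns",
    "male_expression": "expression",
}


@dataclass
class CassetteSpec:
    gene_id: str
    template: str  # srnase | sfb | sfbb | slfl
    n_introns: int = 1
    defect: str | None = None
    expression_profile: str = ""  # filled from template if empty
    strand: str = "+"
    annotated: bool = True
    identity_to_template: float = 100.0

    def __post_init__(self) -> None:
        if self.template not in TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}")
        if self.defect is not None and self.defect not in DEFECTS:
            raise ValueError(f"unknown defect {self.defect!r}")
        if not self.expression_profile:
            if self.template == "srnase":
                self.expression_profile = (
                    "male" if self.defect == "male_expression" else "style_high"
                )
            else:
                self.expression_profile = "male"
        if self.defect == "extra_introns":
            self.n_introns = 3


@dataclass
class DuplicationSpec:
    length: int = 20000
    identity_pct: float = 98.0
    border_repeat_length: int = 500


@dataclass
class LocusDesign:
    name: str
    architecture: str  # pru_like | mal_like
    cassettes: list[CassetteSpec]
    duplications: list[DuplicationSpec] = field(default_factory=list)
    seed: int = 0
    gc: float = 0.38
    spacing: int = 3000

    def __post_init__(self) -> None:
        n = {"srnase": 0, "sfb": 0, "sfbb": 0, "slfl": 0}
        functional = 0
        for c in self.cassettes:
            n[c.template] += 1
            if c.template == "srnase" and c.defect is None:
                functional += 1
        if self.architecture == "pru_like":
            if not (functional == 1 and n["sfb"] == 1 and n["slfl"] >= 2):
                raise ValueError(
                    "pru_like requires exactly one functional S-RNase, one SFB, >=2 SLFL"
                )
        elif self.architecture == "mal_like":
            defective = n["srnase"] - functional
            if not (n["srnase"] >= 2 and defective >= 1 and 1 <= n["sfbb"] <= 3):
                raise ValueError(
                    "mal_like requires >=2 S-RNases (>=1 defective) and 1-3 SFBB"
                )
        else:
            raise ValueError(f"unknown architecture {self.architecture!r}")


def default_pru_design(seed: int = 0) -> LocusDesign:
    """Prunus-type locus: one functional S-RNase, one SFB, four SLFL."""
    return LocusDesign(
        name="chr_pru",
        architecture="pru_like",
        cassettes=[
            CassetteSpec("pru_srnase1", "srnase", n_introns=1),
            CassetteSpec("pru_sfb1", "sfb", n_introns=0, strand="-"),
            CassetteSpec("pru_slfl1", "slfl", n_introns=0, identity_to_template=92.0),
            CassetteSpec("pru_slfl2", "slfl", n_introns=0, strand="-", identity_to_template=90.0),
            CassetteSpec("pru_slfl3", "slfl", n_introns=0, identity_to_template=88.0),
            CassetteSpec("pru_slfl4", "slfl", n_introns=0, identity_to_template=86.0),
        ],
        seed=seed,
    )


def default_mal_design(seed: int = 0) -> LocusDesign:
    """Maleae-type locus: five defective S-RNases (one per defect class)
    and three near-identical SFBB paralogs, plus one segmental duplication."""
    return LocusDesign(
        name="chr_mal",
        architecture="mal_like",
        cassettes=[
            CassetteSpec("mal_srnase1", "srnase", defect="acidic_pi", expression_profile="style_low"),
            CassetteSpec("mal_srnase2", "srnase", defect="truncation", strand="-"),
            CassetteSpec("mal_srnase3", "srnase", defect="pattern4"),
            CassetteSpec("mal_srnase4", "srnase", defect="extra_introns"),
            CassetteSpec("mal_srnase5", "srnase", defect="male_expression", strand="-"),
            CassetteSpec("mal_sfbb1", "sfbb", n_introns=0),
            CassetteSpec("mal_sfbb2", "sfbb", n_introns=0),
            CassetteSpec("mal_sfbb3", "sfbb", n_introns=0, identity_to_template=94.0),
        ],
        duplications=[DuplicationSpec(20000, 98.0, 500)],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# truth table


@dataclass
class TruthRow:
    gene_id: str
    seq_id: str
    class_label: str  # S-RNase_functional / S-RNase_defective / SFB / SFBB / SLFL
    defect: str  # "" when none
    expected_failed_criterion: str  # category key, "" for functional
    start: int
    end: int
    strand: str
    n_introns: int
    expression_profile: str
    annotated: bool
    cds_len: int
    protein: str


@dataclass
class TruthDup:
    seq_id: str
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    length: int
    identity_pct: float
    border_repeat_length: int


@dataclass
class TruthTable:
    rows: list[TruthRow]
    duplications: list[TruthDup] = field(default_factory=list)
    border_repeats: list[SeqRecord] = field(default_factory=list)

    def row(self, gene_id: str) -> TruthRow:
        for r in self.rows:
            if r.gene_id == gene_id:
                return r
        raise KeyError(gene_id)


# ---------------------------------------------------------------------------
# cassette assembly


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    s = list(seq)
    for i in range(len(s)):
        if rng.random() < rate:
            s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
    return "".join(s)


def _apply_defect(protein: str, defect: str | None, rng: np.random.Generator) -> tuple[str, bool]:
    """Protein-level defects; returns (protein, truncate_flag)."""
    if defect in (None, "extra_introns", "male_expression", "truncation"):
        return protein, defect == "truncation"
    if defect == "pattern4":
        i = 60  # inside the pattern2..C3 window of the template
        return protein[:i] + "CPQDAD" + protein[i:], False
    if defect == "acidic_pi":
        p = list(protein)
        for s, e in SRNASE_FREE_SPANS:
            for i in range(s, min(e, len(p))):
                if p[i] in "KR":
                    p[i] = "E"
                    if compute_pI("".join(p)) < 7.2:
                        return "".join(p), False
        raise RuntimeError("could not reach acidic pI")
    raise ValueError(defect)


def _build_cds(spec: CassetteSpec, rng: np.random.Generator) -> tuple[str, str]:
    """Returns (cds with terminal stop, mature protein)."""
    tpl = TEMPLATES[spec.template]
    keep = _SRNASE_MOTIF_SPANS if spec.template == "srnase" else _FBOX_MOTIF_SPANS
    prot = _mutate_protein(tpl, spec.identity_to_template, rng, keep)
    prot, truncate = _apply_defect(prot, spec.defect, rng)
    cds = back_translate(prot, stop=True)
    if truncate:
        # internal stop replacing the codon before the terminal stop: the
        # predicted protein loses one residue, every other criterion holds
        n = len(cds)
        cds = cds[: n - 6] + "TAA" + cds[n - 3 :]
        prot = prot[:-1]
    return cds, prot


def _insert_introns(
    cds: str, n_introns: int, rng: np.random.Generator
) -> tuple[str, list[tuple[int, int]]]:
    """Returns (genomic cassette, exon intervals local to the cassette)."""
    if n_introns == 0:
        return cds, [(0, len(cds))]
    sites = sorted(rng.choice(np.arange(10, len(cds) - 10), size=n_introns, replace=False))
    parts: list[str] = []
    exons: list[tuple[int, int]] = []
    pos = 0
    prev = 0
    for site in list(sites) + [len(cds)]:
        exon = cds[prev:site]
        exons.append((pos, pos + len(exon)))
        parts.append(exon)
        pos += len(exon)
        if site != len(cds):
            ilen = int(rng.integers(80, 301))
            intron = "GT" + _random_dna(rng, ilen - 4, 0.35) + "AG"
            parts.append(intron)
            pos += len(intron)
        prev = site
    return "".join(parts), exons


def generate_locus(design: LocusDesign) -> tuple[SeqRecord, list[GeneModel], TruthTable]:
    """Build the chromosome, its annotation and the ground truth."""
    rng = np.random.default_rng(design.seed)
    pieces: list[str] = []
    pos = 0
    models: list[GeneModel] = []
    rows: list[TruthRow] = []

    def emit(seq: str) -> int:
        nonlocal pos
        pieces.append(seq)
        start = pos
        pos += len(seq)
        return start

    for spec in design.cassettes:
        emit(_random_dna(rng, design.spacing, design.gc))
        cds, prot = _build_cds(spec, rng)
        cassette, local_exons = _insert_introns(cds, spec.n_introns, rng)
        L = len(cassette)
        if spec.strand == "+":
            genomic = cassette
            exon_ivs = [Interval(s, e) for s, e in local_exons]
        else:
            genomic = revcomp(cassette)
            exon_ivs = sorted(Interval(L - e, L - s) for s, e in local_exons)
        start = emit(genomic)
        exon_ivs = [Interval(start + iv.start, start + iv.end) for iv in exon_ivs]
        model = GeneModel(
            gene_id=spec.gene_id,
            seq_id=design.name,
            strand=spec.strand,
            exons=exon_ivs,
            cds_exons=list(exon_ivs),
            cds=cds,
            parent=spec.gene_id + "_gene",
        )
        if spec.annotated:
            models.append(model)
        if spec.template == "srnase":
            label = "S-RNase_functional" if spec.defect is None else "S-RNase_defective"
        else:
            label = spec.template.upper()
        rows.append(
            TruthRow(
                gene_id=spec.gene_id,
                seq_id=design.name,
                class_label=label,
                defect=spec.defect or "",
                expected_failed_criterion=DEFECT_CRITERION.get(spec.defect or "", ""),
                start=start,
                end=start + L,
                strand=spec.strand,
                n_introns=spec.n_introns,
                expression_profile=spec.expression_profile,
                annotated=spec.annotated,
                cds_len=len(cds),
                protein=prot,
            )
        )

    dups: list[TruthDup] = []
    borders: list[SeqRecord] = []
    for di, dspec in enumerate(design.duplications):
        consensus = _random_dna(rng, dspec.border_repeat_length, 0.42)
        borders.append(SeqRecord(f"{design.name}_border{di+1}", consensus, "synthetic border-repeat family consensus"))
        source = _random_dna(rng, dspec.length, design.gc)
        copy = _mutate_dna(source, 1.0 - dspec.identity_pct / 100.0, rng)
        emit(_random_dna(rng, design.spacing, design.gc))
        emit(_mutate_dna(consensus, 0.2, rng))
        a_start = emit(source)
        emit(_mutate_dna(consensus, 0.2, rng))
        emit(_random_dna(rng, design.spacing, design.gc))
        emit(_mutate_dna(consensus, 0.2, rng))
        b_start = emit(copy)
        emit(_mutate_dna(consensus, 0.2, rng))
        dups.append(
            TruthDup(
                seq_id=design.name,
                start_a=a_start,
                end_a=a_start + dspec.length,
                start_b=b_start,
                end_b=b_start + dspec.length,
                length=dspec.length,
                identity_pct=dspec.identity_pct,
                border_repeat_length=dspec.border_repeat_length,
            )
        )
    emit(_random_dna(rng, design.spacing, design.gc))

    genome = SeqRecord(design.name, "".join(pieces), f"synthetic {design.architecture} locus")
    truth = TruthTable(rows=rows, duplications=dups, border_repeats=borders)
    return genome, models, truth


# ---------------------------------------------------------------------------
# expression counts

#: per-profile mean counts by tissue (style_stigma, stamen, pollen)
PROFILE_MEANS: dict[str, dict[str, float]] = {
    "style_high": {"style_stigma": 1200.0, "stamen": 0.0, "pollen": 0.0},
    "style_low": {"style_stigma": 40.0, "stamen": 0.0, "pollen": 0.0},
    "style_weak": {"style_stigma": 0.3, "stamen": 0.0, "pollen": 0.0},
    "male": {"style_stigma": 0.0, "stamen": 800.0, "pollen": 1000.0},
    "male_lowstyle": {"style_stigma": 2.0, "stamen": 800.0, "pollen": 1000.0},
    "silent": {"style_stigma": 0.0, "stamen": 0.0, "pollen": 0.0},
}

TISSUES = ("style_stigma", "stamen", "pollen")


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float | None, size: int) -> np.ndarray:
    """Counts with variance mean + dispersion * mean^2 (dispersion 0/None
    gives the Poisson limit)."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    if not dispersion:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def generate_expression(
    truth: TruthTable,
    profile_means: dict[str, dict[str, float]] | None = None,
    dispersion: float | None = 0.1,
    n_reps: int = 3,
    seed: int = 0,
    n_background: int = 1000,
    background_mean: float = 400.0,
    background_length: float = 1000.0,
) -> ExpressionMatrix:
    """Negative-binomial counts for planted genes plus a broad-expression
    background transcriptome (which makes TPM values realistic).

    ``dispersion`` is the RNA-seq dispersion alpha (variance = mu + alpha
    mu^2); 0 or None switches to Poisson.  Negative values are an error.
    """
    import pandas as pd

    if dispersion is not None and dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if not math.isfinite(dispersion or 0.0):
        raise ValueError("dispersion must be finite (use 0/None for Poisson)")
    if n_reps < 2:
        raise ValueError("need n_reps >= 2")
    means = profile_means or PROFILE_MEANS
    rng = np.random.default_rng(seed)
    samples = [f"{t}_rep{r+1}" for t in TISSUES for r in range(n_reps)]
    tissue_of = {s: s.rsplit("_rep", 1)[0] for s in samples}

    gene_ids = [r.gene_id for r in truth.rows]
    lengths = {r.gene_id: float(r.cds_len) for r in truth.rows}
    data: dict[str, np.ndarray] = {}
    for r in truth.rows:
        prof = means[r.expression_profile]
        row = []
        for t in TISSUES:
            row.append(_nb_draw(rng, prof[t], dispersion, n_reps))
        data[r.gene_id] = np.concatenate(row)
    bg_base = rng.lognormal(mean=np.log(background_mean), sigma=0.5, size=n_background)
    for i in range(n_background):
        gid = f"bg{i+1:04d}"
        gene_ids.append(gid)
        lengths[gid] = background_length
        data[gid] = np.concatenate(
            [_nb_draw(rng, bg_base[i], dispersion, n_reps) for _ in TISSUES]
        )
    counts = pd.DataFrame(
        np.vstack([data[g] for g in gene_ids]), index=gene_ids, columns=samples
    )
    return ExpressionMatrix(counts=counts, tissue=tissue_of, lengths=lengths)


# ---------------------------------------------------------------------------
# allele sets


def generate_allele_sets(
    base_protein: str = SRNASE_TEMPLATE,
    n_individuals: int = 3,
    target_identity_range: tuple[float, float] = (64.0, 72.0),
    seed: int = 0,
    alleles_per_individual: int = 2,
    max_rounds: int = 400,
) -> list[SeqRecord]:
    """Allele coding sequences whose realised pairwise nucleotide
    identities (as measured by the diversity module) fall inside the target
    band.  Alleles are mutated copies of the back-translated base protein;
    an iterative correction loop adds or reverts substitutions until every
    pair is in band."""
    lo, hi = target_identity_range
    if not (0 < lo <= hi <= 100):
        raise ValueError("identity bounds must satisfy 0 < lo <= hi <= 100")
    cds = back_translate(base_protein, stop=False)
    L = len(cds)
    if lo < 40.0:
        raise ValueError("identity targets below 40% are unreachable by substitution")
    if L < 60:
        raise ValueError(f"base sequence too short ({L} nt) for a controlled identity target")
    rng = np.random.default_rng(seed)
    n_alleles = n_individuals * alleles_per_individual
    mid = (lo + hi) / 2.0
    per_allele_rate = (1.0 - mid / 100.0) / 2.0
    alleles = [list(_mutate_dna(cds, per_allele_rate, rng)) for _ in range(n_alleles)]
    ids = [
        f"ind{i+1}_allele{a+1}"
        for i in range(n_individuals)
        for a in range(alleles_per_individual)
    ]

    def ident(i: int, j: int) -> float:
        return pairwise_identity(
            SeqRecord(ids[i], "".join(alleles[i])),
            SeqRecord(ids[j], "".join(alleles[j])),
            "nucleotide",
        ).identity_pct

    for _ in range(max_rounds):
        worst: tuple[float, int, int] | None = None
        for i in range(n_alleles):
            for j in range(i + 1, n_alleles):
                v = ident(i, j)
                dev = max(lo - v, v - hi, 0.0)
                if dev > 0 and (worst is None or dev > worst[0]):
                    worst = (dev, i, j)
        if worst is None:
            break
        _, i, j = worst
        target = alleles[j]
        n_fix = max(1, int(L * worst[0] / 100.0 / 2.0) + 1)
        v = ident(i, j)
        if v < lo:  # too divergent: revert mutated positions toward base
            diffs = [k for k in range(L) if target[k] != cds[k]]
            for k in rng.choice(diffs, size=min(n_fix, len(diffs)), replace=False):
                target[k] = cds[k]
        else:  # too similar: add substitutions
            same = [k for k in range(L) if target[k] == alleles[i][k]]
            for k in rng.choice(same, size=min(n_fix, len(same)), replace=False):
                target[k] = rng.choice([b for b in "ACGT" if b != target[k]])
    else:
        raise RuntimeError("identity target not reached; band may be too narrow")
    return [SeqRecord(ids[k], "".join(alleles[k]), "synthetic allele") for k in range(n_alleles)]


# ---------------------------------------------------------------------------
# codon alignments


def simulate_codon_alignment(
    tree_newick: str,
    model: str,
    params: dict,
    n_codons: int,
    seed: int,
    codon_freqs=None,
) -> selection.CodonAlignment:
    """Evolve a codon alignment along a Newick tree (foreground branches
    marked with a ``#1`` label suffix) under M0 / branch / branch-site
    models; stop codons can never appear."""
    tree = selection.LabeledTree.from_newick(tree_newick)
    spec = selection.CodonModelSpec(model)
    return selection.simulate_codon_alignment(
        tree, spec, params, n_codons, seed, codon_freqs
    )
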