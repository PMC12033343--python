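"""Reading/writing of FASTA, GFF3 and TSV tables, and coordinate conventions.

All intervals inside the package are 0-based half-open on the forward
strand; GFF3 on disk is 1-based inclusive.  Minus-strand gene models carry a
strand-corrected (5'->3') coding sequence, so protein-level code never needs
to know about strand.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .codons import revcomp


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"degenerate interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def to_gff(self) -> tuple[int, int]:
        """1-based inclusive coordinates as written in GFF3."""
        return self.start + 1, self.end

    @classmethod
    def from_gff(cls, start1: int, end1: int) -> "Interval":
        return cls(start1 - 1, end1)


@dataclass
class SeqRecord:
    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """One transcript model: exon structure plus strand-corrected CDS."""

    gene_id: str
    seq_id: str
    strand: str  # '+' or '-'
    exons: list[Interval]
    cds_exons: list[Interval] = field(default_factory=list)
    cds: str = ""
    parent: str = ""  # gene id when the model is one of several transcripts

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        self.exons = sorted(self.exons)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping exons in {self.gene_id}")

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


def parse_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read a FASTA file into records, preserving case (soft masking).

    Raises ``ValueError`` on duplicate ids or an empty file.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(SeqRecord(rec.id, str(rec.seq), desc))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def parse_gff3(path: str | os.PathLike, genome: Sequence[SeqRecord]) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS rows into :class:`GeneModel` objects.

    One model per mRNA.  Coordinates are converted to internal 0-based
    half-open; minus-strand CDS is reverse-complemented and exon order kept
    sorted by forward-strand start, so ``cds`` always reads 5'->3'.
    """
    import gffutils

    seqs = {r.id: r.seq for r in genome}
    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        mid = mrna.id
        if mrna.seqid not in seqs:
            raise ValueError(f"mRNA {mid} references unknown sequence {mrna.seqid}")
        exons: list[Interval] = []
        cds_exons: list[Interval] = []
        for ftype, store in (("exon", exons), ("CDS", cds_exons)):
            for feat in db.children(mrna, featuretype=ftype, order_by="start"):
                iv = Interval.from_gff(feat.start, feat.end)
                if iv.end > len(seqs[feat.seqid]) or iv.start < 0:
                    raise ValueError(
                        f"{ftype} of {mid} outside bounds of {feat.seqid} "
                        f"({iv.start}-{iv.end} vs length {len(seqs[feat.seqid])})"
                    )
                store.append(iv)
        if not exons:
            exons = list(cds_exons)
        if not exons:
            raise ValueError(f"mRNA {mid} has no exon or CDS features")
        cds = "".join(seqs[mrna.seqid][iv.start : iv.end] for iv in sorted(cds_exons))
        if mrna.strand == "-":
            cds = revcomp(cds)
        models.append(
            GeneModel(
                gene_id=mid,
                seq_id=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_exons=sorted(cds_exons),
                cds=cds,
                parent=(mrna.attributes.get("Parent") or [""])[0],
            )
        )
    models.sort(key=lambda m: (m.seq_id, m.span.start, m.gene_id))
    return models


def write_gff3(models: Iterable[GeneModel], path: str | os.PathLike, source: str = "slocus_kit") -> None:
    """Emit gene/mRNA/exon/CDS rows (1-based inclusive) for each model."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gene_id = m.parent or m.gene_id + "_gene"
            s1, e1 = m.span.to_gff()
            base = f"{m.seq_id}\t{source}"
            fh.write(f"{base}\tgene\t{s1}\t{e1}\t.\t{m.strand}\t.\tID={gene_id}\n")
            fh.write(
                f"{base}\tmRNA\t{s1}\t{e1}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id};Parent={gene_id}\n"
            )
            for iv in m.exons:
                a, b = iv.to_gff()
                fh.write(f"{base}\texon\t{a}\t{b}\t.\t{m.strand}\t.\tParent={m.gene_id}\n")
            for iv in m.cds_exons:
                a, b = iv.to_gff()
                fh.write(f"{base}\tCDS\t{a}\t{b}\t.\t{m.strand}\t0\tParent={m.gene_id}\n")


def _to_row(record) -> dict:
    if dataclasses.is_dataclass(record) and not isinstance(record, type):
        return dataclasses.asdict(record)
    if isinstance(record, dict):
        return dict(record)
    raise TypeError(f"cannot serialize {type(record).__name__} as a table row")


def write_table(records: Sequence, path: str | os.PathLike, columns: Sequence[str] | None = None) -> None:
    """Write records (dataclasses or dicts) as a TSV with a header row.

    Column order is the field order of the first record (or ``columns``);
    floats are rendered with 6 significant digits.  An empty record list
    still produces a header-only file when ``columns`` is given.
    """
    rows = [_to_row(r) for r in records]
    if columns is None:
        if not rows:
            raise ValueError("empty record list needs explicit columns")
        columns = list(rows[0].keys())
    df = pd.DataFrame(rows, columns=list(columns))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
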