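"""Genome records and plain-text IO (FASTA, GFF3, TSV helpers)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .grammar import revcomp


@dataclass
class Gene:
    """An annotated gene in 0-based half-open coordinates."""

    start: int
    end: int
    strand: str = "+"
    frame: int = 0
    product_label: str = "hypothetical protein"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad gene interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class GenomeRecord:
    """A named DNA sequence with optional gene annotations."""

    id: str
    sequence: str
    genes: list[Gene] = field(default_factory=list)
    organism: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"non-DNA characters in {self.id}: {sorted(bad)}")
        self.sequence = self.sequence.upper()
        for g in self.genes:
            if g.end > len(self.sequence):
                raise ValueError(f"gene [{g.start},{g.end}) beyond sequence of {self.id}")

    def __len__(self) -> int:
        return len(self.sequence)


def flip_record(record: GenomeRecord) -> GenomeRecord:
    """Reverse-complement a record, remapping gene coordinates and strands."""
    n = len(record.sequence)
    genes = [
        Gene(n - g.end, n - g.start, "-" if g.strand == "+" else "+", g.frame, g.product_label)
        for g in record.genes
    ]
    genes.sort(key=lambda g: g.start)
    return GenomeRecord(record.id, revcomp(record.sequence), genes, record.organism)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeRecord]:
    return [GenomeRecord(r.id, str(r.seq), [], None) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.organism or "") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

@dataclass
class Gff3Feature:
    """One GFF3 row; start/end are 0-based half-open and converted on write."""

    seqid: str
    ftype: str
    start: int
    end: int
    strand: str = "+"
    source: str = "istronkit"
    score: str = "."
    phase: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes.items()) or "."
        return "\t".join(
            [
                self.seqid,
                self.source,
                self.ftype,
                str(self.start + 1),
                str(self.end),
                self.score,
                self.strand,
                self.phase,
                attrs,
            ]
        )


def write_gff3(features: Sequence[Gff3Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            fh.write(feat.line() + "\n")


def write_genes_gff3(records: Iterable[GenomeRecord], path: str | Path) -> None:
    feats = [
        Gff3Feature(r.id, "gene", g.start, g.end, g.strand,
                    attributes={"product": g.product_label})
        for r in records
        for g in r.genes
    ]
    write_gff3(feats, path)


def read_genes_gff3(path: str | Path) -> dict[str, list[Gene]]:
    """Gene annotations per seqid from a GFF3 file (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True
    )
    out: dict[str, list[Gene]] = {}
    for f in db.features_of_type("gene"):
        label = (f.attributes.get("product") or ["hypothetical protein"])[0]
        out.setdefault(f.seqid, []).append(
            Gene(f.start - 1, f.end, f.strand if f.strand in "+-" else "+", 0, label)
        )
    for genes in out.values():
        genes.sort(key=lambda g: g.start)
    return out


def dataclass_to_row(obj) -> dict:
    """Flatten a dataclass into a TSV-friendly dict (tuples become strings)."""
    row = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        row[f.name] = ",".join(map(str, v)) if isinstance(v, (tuple, list)) else v
    return row
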