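"""Shared sequence / annotation I/O and coordinate conventions.

Internally all coordinates are 0-based, half-open intervals on the forward
strand.  GFF3 is written and read as 1-based inclusive, per the format.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTRYKMBVDHSWN", "TGCAYRMKVBHDSWN")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: 0-based half-open [start, end) on ``chrom``."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class ChromosomeInfo:
    name: str
    length: int


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]], path, descriptions=None):
    items = records.items() if isinstance(records, Mapping) else records
    descriptions = descriptions or {}
    recs = [
        SeqRecord(Seq(seq), id=name, description=descriptions.get(name, ""))
        for name, seq in items
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_gff3(genes: Iterable[GeneModel], path, source: str = "motifrecruit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};Name={g.gene_id}\n"
            )


def read_gff3(path) -> list[GeneModel]:
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene"):
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_chromosome_table(chromosomes: Iterable[ChromosomeInfo], path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tlength\n")
        for c in chromosomes:
            fh.write(f"{c.name}\t{c.length}\n")


def read_chromosome_table(path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("chromosome")
        for line in fh:
            name, length = line.rstrip("\n").split("\t")
            out[name] = int(length)
    return out
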