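"""Per-strain gene records: the universal input unit of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class GeneRecord:
    """A single protein-coding gene: CDS nucleotides and their translation."""

    gene_id: str
    protein: str
    cds: str | None = None

    def __post_init__(self):
        if self.cds is not None:
            if len(self.cds) % 3 != 0:
                raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
            expected = str(Seq(self.cds).translate())
            if expected.rstrip("*") != self.protein.rstrip("*"):
                raise ValueError(f"{self.gene_id}: protein is not the CDS translation")


@dataclass
class StrainProteome:
    """All annotated genes of one strain."""

    strain_id: str
    records: dict[str, GeneRecord] = field(default_factory=dict)

    @classmethod
    def from_records(cls, strain_id: str, records: Iterable[GeneRecord]) -> "StrainProteome":
        out = cls(strain_id)
        for rec in records:
            if rec.gene_id in out.records:
                raise ValueError(f"duplicate gene id {rec.gene_id} in {strain_id}")
            out.records[rec.gene_id] = rec
        return out

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records.values())

    @property
    def gene_ids(self) -> list[str]:
        return list(self.records)

    def total_residues(self) -> int:
        return sum(len(r.protein) for r in self.records.values())

    @classmethod
    def from_fasta(
        cls, strain_id: str, protein_fasta: str | Path, cds_fasta: str | Path | None = None
    ) -> "StrainProteome":
        """Load a proteome (and optionally matching CDS) from FASTA files."""
        cds: dict[str, str] = {}
        if cds_fasta is not None:
            cds = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(cds_fasta), "fasta")}
        records = []
        for rec in SeqIO.parse(str(protein_fasta), "fasta"):
            records.append(GeneRecord(rec.id, str(rec.seq).upper(), cds.get(rec.id)))
        return cls.from_records(strain_id, records)

    def write_fasta(self, protein_fasta: str | Path, cds_fasta: str | Path | None = None) -> None:
        prot = [SeqRecord(Seq(r.protein), id=r.gene_id, description="") for r in self]
        SeqIO.write(prot, str(protein_fasta), "fasta")
        if cds_fasta is not None:
            nts = [
                SeqRecord(Seq(r.cds), id=r.gene_id, description="")
                for r in self
                if r.cds is not None
            ]
            SeqIO.write(nts, str(cds_fasta), "fasta")
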