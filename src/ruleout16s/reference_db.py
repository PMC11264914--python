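"""Type-strain reference databases and query read sets in FASTA.

A reference database holds one record per species type strain: the
accession, the binomial species name parsed from the FASTA header, and
the full-length 16S gene sequence. Multiple type strains may share a
species name (subspecies, replacement strains); they are all retained
and indexed under the same name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .iupac import encode, normalize


@dataclass(frozen=True)
class TypeStrainRecord:
    """One species type strain's full-length 16S sequence.

    ``len(record.sequence)`` is the full gene length L used when
    extrapolating mismatches beyond the sequenced region.
    """

    accession: str
    species_name: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.accession!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class QueryRead:
    """An amplicon read or ASV to be evaluated against the database."""

    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


class ReferenceDatabase:
    """Ordered collection of type-strain records with a species index."""

    def __init__(self, records: Iterable[TypeStrainRecord] = ()):
        self.records: list[TypeStrainRecord] = []
        self.species_index: dict[str, list[TypeStrainRecord]] = {}
        self._accessions: set[str] = set()
        for record in records:
            self.add(record)

    def add(self, record: TypeStrainRecord) -> None:
        if record.accession in self._accessions:
            raise ValueError(f"duplicate accession {record.accession!r}")
        self._accessions.add(record.accession)
        self.records.append(record)
        self.species_index.setdefault(record.species_name, []).append(record)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TypeStrainRecord]:
        return iter(self.records)

    @property
    def species_names(self) -> list[str]:
        return list(self.species_index)


def _parse_species(description: str, header_dialect: str) -> str:
    """Species name from the post-accession part of a FASTA header.

    ``ltp`` takes the first two whitespace tokens (the binomial name,
    dropping strain designations); ``plain`` keeps the whole description.
    """
    if header_dialect == "plain":
        return description.strip()
    if header_dialect == "ltp":
        tokens = description.split()
        return " ".join(tokens[:2])
    raise ValueError(f"unknown header dialect {header_dialect!r}")


def read_type_strain_fasta(path, header_dialect: str = "ltp") -> ReferenceDatabase:
    """Load a type-strain FASTA into a :class:`ReferenceDatabase`.

    Headers are ``>accession description`` where the species name is
    parsed from the description per ``header_dialect``. Sequences are
    uppercased with U mapped to T. An empty file yields an empty
    database; a duplicate accession or an empty/invalid sequence raises
    ``ValueError`` naming the record.
    """
    db = ReferenceDatabase()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize(str(rec.seq))
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        encode(seq, context=f"record {rec.id!r}")
        description = rec.description[len(rec.id):].strip()
        db.add(
            TypeStrainRecord(
                accession=rec.id,
                species_name=_parse_species(description, header_dialect),
                sequence=seq,
                description=description,
            )
        )
    return db


def write_type_strain_fasta(db: ReferenceDatabase, path) -> None:
    """Write ``>accession species_name`` FASTA, one unwrapped line each."""
    with open(path, "w") as handle:
        for record in db:
            handle.write(f">{record.accession} {record.species_name}\n")
            handle.write(record.sequence + "\n")


def read_query_fasta(path) -> list[QueryRead]:
    """Load query reads, preserving file order.

    Read IDs are the first whitespace-delimited header token; duplicates
    raise ``ValueError``.
    """
    reads: list[QueryRead] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate read ID {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = normalize(str(rec.seq))
        if not seq:
            raise ValueError(f"read {rec.id!r} in {path} has an empty sequence")
        reads.append(QueryRead(read_id=rec.id, sequence=seq))
    return reads


def write_query_fasta(reads: Iterable[QueryRead], path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f">{read.read_id}\n{read.sequence}\n")
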