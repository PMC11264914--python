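"""Primer-based variable-region extraction and indistinguishable species.

Primers are matched ungapped (Hamming distance under IUPAC set
semantics, 1 mismatch allowed by default) at every offset of the
full-length gene; the region between the forward primer's end and the
reverse primer's reverse-complemented site is the amplified insert.
Species whose trimmed (or full) sequences align with at most one
mismatch are indistinguishable by marker-gene sequencing in that
region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .alignment import AlignmentParams, semiglobal_align
from .iupac import encode, reverse_complement
from .reference_db import QueryRead, ReferenceDatabase

# primer pairs in common use for the V1-V2, V1-V3 and V4 regions
F27 = "AGAGTTTGATCCTGGCTCAG"
R228 = "TGCTGCCTCCCGTAGGAGT"
R534 = "ATTACCGCGGCTGCTGG"
F515 = "GTGYCAGCMGCCGCGGTAA"
R806 = "GGACTACNVGGGTWTCTAAT"


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, reverse in published orientation."""

    forward: str
    reverse: str
    name: str = ""

    def __post_init__(self) -> None:
        for label, primer in (("forward", self.forward), ("reverse", self.reverse)):
            if not primer:
                raise ValueError(f"{label} primer is empty")
            encode(primer, context=f"{label} primer")


STANDARD_PAIRS = {
    "V1-V2": PrimerPair(F27, R228, name="V1-V2"),
    "V1-V3": PrimerPair(F27, R534, name="V1-V3"),
    "V4": PrimerPair(F515, R806, name="V4"),
}


class PrimerHit(NamedTuple):
    start: int
    mismatches: int


def primer_match(
    sequence: str, primer: str, max_mismatches: int = 1
) -> Optional[PrimerHit]:
    """Leftmost best ungapped primer site with at most max_mismatches.

    A position matches when the IUPAC base sets of primer and sequence
    intersect. Returns None when no offset qualifies (including a
    primer longer than the sequence).
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be non-negative")
    pm = encode(primer, context="primer")
    sm = encode(sequence)
    k = pm.size
    if k > sm.size:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(sm, k)
    mismatch_counts = ((windows & pm[None, :]) == 0).sum(axis=1)
    best = int(mismatch_counts.min())
    if best > max_mismatches:
        return None
    return PrimerHit(start=int(np.argmin(mismatch_counts)), mismatches=best)


def extract_region(
    sequence: str, pair: PrimerPair, max_mismatches: int = 1
) -> Optional[str]:
    """Bases strictly between the primer sites, or None.

    The reverse primer is reverse-complemented before searching the
    forward strand; primer bases are excluded from the insert. Returns
    None when either primer is absent or the reverse site does not
    follow the forward site.
    """
    fwd = primer_match(sequence, pair.forward, max_mismatches)
    if fwd is None:
        return None
    rev = primer_match(sequence, reverse_complement(pair.reverse), max_mismatches)
    if rev is None:
        return None
    insert_start = fwd.start + len(pair.forward)
    if rev.start < insert_start:
        return None
    return sequence[insert_start : rev.start]


def trim_database(
    db: ReferenceDatabase, pair: PrimerPair, max_mismatches: int = 1
) -> tuple[ReferenceDatabase, list[str]]:
    """Trim every record to the primer-delimited region.

    Records where extraction fails (missing or empty insert) are
    dropped; their accessions are returned alongside the trimmed
    database.
    """
    from .reference_db import TypeStrainRecord

    trimmed = ReferenceDatabase()
    dropped = []
    for record in db:
        insert = extract_region(record.sequence, pair, max_mismatches)
        if not insert:
            dropped.append(record.accession)
            continue
        trimmed.add(
            TypeStrainRecord(
                accession=record.accession,
                species_name=record.species_name,
                sequence=insert,
                description=record.description,
            )
        )
    return trimmed, dropped


class IndistinguishablePair(NamedTuple):
    species_a: str
    species_b: str
    mismatches: int


def indistinguishable_pairs(
    db: ReferenceDatabase,
    max_mismatches: int = 1,
    params: Optional[AlignmentParams] = None,
) -> tuple[list[IndistinguishablePair], set[str]]:
    """Species pairs whose sequences differ by at most max_mismatches.

    All-vs-all semi-global alignment (free terminal gaps) across
    records of different species; a pair is flagged when any record
    pair across the two species aligns with <= max_mismatches
    differences. Also returns the set of species having at least one
    indistinguishable neighbor.
    """
    if len(db) == 0:
        raise ValueError("database is empty")
    params = params or AlignmentParams()
    best: dict[tuple[str, str], int] = {}
    records = list(db)
    for i, rec_a in enumerate(records):
        pseudo_read = QueryRead(read_id=rec_a.accession, sequence=rec_a.sequence)
        for rec_b in records[i + 1 :]:
            if rec_a.species_name == rec_b.species_name:
                continue
            aln = semiglobal_align(pseudo_read, rec_b, params)
            key = tuple(sorted((rec_a.species_name, rec_b.species_name)))
            if key not in best or aln.mismatches < best[key]:
                best[key] = aln.mismatches
    pairs = [
        IndistinguishablePair(a, b, mm)
        for (a, b), mm in sorted(best.items())
        if mm <= max_mismatches
    ]
    flagged = {p.species_a for p in pairs} | {p.species_b for p in pairs}
    return pairs, flagged


def write_pairs_tsv(pairs, path) -> None:
    with open(path, "w") as handle:
        handle.write("species_a\tspecies_b\tmismatches\n")
        for pair in pairs:
            handle.write(f"{pair.species_a}\t{pair.species_b}\t{pair.mismatches}\n")
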