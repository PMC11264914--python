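"""Synthetic type-strain databases, reads, and rate profiles.

The generator mirrors the assumptions of the mismatch model: species
differ by independent per-site substitutions, and reads are slices of a
variable region with independent per-site errors, so the true mismatch
counts behind every read are known exactly. Substituted sites draw
uniformly from the three other bases; no indels are introduced. All
outputs are byte-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .mismatch_model import RegionRateProfile
from .reference_db import QueryRead, ReferenceDatabase, TypeStrainRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic fixtures.

    Defaults emulate a V1-V2-style amplicon survey: 10 species whose
    full-length genes (1500 nt) diverge by 10% substitutions, with
    error-free 322 nt reads taken from positions [27, 349) of the gene.
    inside_rate / outside_rate are the per-position mismatch
    probabilities inside and outside the sequenced region (inside_rate
    drives read errors; both drive rate-profile fixtures).
    """

    n_species: int = 10
    gene_length: int = 1500
    between_species_divergence: float = 0.10
    region_start: int = 27
    region_end: int = 349
    inside_rate: float = 0.0
    outside_rate: float = 0.0
    n_reads: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be at least 1")
        for name in ("between_species_divergence", "inside_rate", "outside_rate"):
            rate = getattr(self, name)
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.region_start < self.region_end <= self.gene_length:
            raise ValueError("need 0 <= region_start < region_end <= gene_length")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")


class ReadTruth(NamedTuple):
    """Ground truth for one simulated read."""

    read_id: str
    species_name: str
    mismatches: int


def _mutate(indices: np.ndarray, rate: float, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Substitute each site independently at ``rate``; uniform other base."""
    hit = rng.random(indices.size) < rate
    offsets = rng.integers(1, 4, size=indices.size)
    out = np.where(hit, (indices + offsets) % 4, indices)
    return out, int(hit.sum())


def simulate_database(config: SimulationConfig) -> ReferenceDatabase:
    """Synthetic type-strain database.

    Species 0 is a uniform-random gene; every other species substitutes
    each position independently with probability
    between_species_divergence (a star phylogeny, which is all the
    pairwise mismatch model sees).
    """
    rng = np.random.default_rng([config.seed, 0])
    base = rng.integers(0, 4, size=config.gene_length)
    db = ReferenceDatabase()
    for i in range(config.n_species):
        if i == 0:
            indices = base
        else:
            indices, _ = _mutate(base, config.between_species_divergence, rng)
        sequence = _BASES[indices].tobytes().decode("ascii")
        db.add(
            TypeStrainRecord(
                accession=f"SYN{i:04d}",
                species_name=f"Synthbacter species{i:03d}",
                sequence=sequence,
                description=f"Synthbacter species{i:03d} synthetic type strain",
            )
        )
    return db


def simulate_reads(
    db: ReferenceDatabase, config: SimulationConfig
) -> tuple[list[QueryRead], list[ReadTruth]]:
    """Amplicon reads from the region slice, with exact mismatch truth.

    Source species cycle round-robin through the database; each read is
    the source gene's [region_start, region_end) slice with independent
    substitutions at inside_rate. The truth table records the exact
    number of introduced mismatches.
    """
    rng = np.random.default_rng([config.seed, 1])
    encoded = {
        record.accession: np.frombuffer(
            record.sequence.encode("ascii"), dtype=np.uint8
        )
        for record in db
    }
    lookup = np.full(256, -1, dtype=np.int64)
    lookup[_BASES] = np.arange(4)
    reads: list[QueryRead] = []
    truth: list[ReadTruth] = []
    records = list(db)
    for i in range(config.n_reads):
        record = records[i % len(records)]
        gene = lookup[encoded[record.accession]]
        if (gene < 0).any():
            raise ValueError(
                f"record {record.accession!r} contains degenerate bases; "
                "read simulation needs plain A/C/G/T references"
            )
        window = gene[config.region_start : config.region_end]
        mutated, n_mismatches = _mutate(window, config.inside_rate, rng)
        read_id = f"read{i:05d}"
        reads.append(
            QueryRead(read_id=read_id, sequence=_BASES[mutated].tobytes().decode("ascii"))
        )
        truth.append(ReadTruth(read_id, record.species_name, n_mismatches))
    return reads, truth


def simulate_rate_profile(
    gene_length: int,
    inside_rate: float,
    outside_rate: float,
    region: tuple[int, int],
) -> RegionRateProfile:
    """Step profile: inside_rate on the region, outside_rate elsewhere."""
    start, end = region
    if not 0 <= start < end <= gene_length:
        raise ValueError("region must lie inside the gene")
    for name, rate in (("inside_rate", inside_rate), ("outside_rate", outside_rate)):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    rates = np.full(gene_length, outside_rate, dtype=float)
    rates[start:end] = inside_rate
    return RegionRateProfile(rates=rates)


def write_truth_tsv(truth: list[ReadTruth], path) -> None:
    with open(path, "w") as handle:
        handle.write("read_id\tspecies\tmismatches\n")
        for row in truth:
            handle.write(f"{row.read_id}\t{row.species_name}\t{row.mismatches}\n")
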