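"""End-to-end pipeline: reads -> candidates -> rule-out -> calls.

For each read, every type strain whose alignment identity exceeds the
candidate threshold gets a rule-out probability; a read with no
candidate at all is reported with a sentinel row (empty species,
probability 1.0) so that every input read appears in the output. A
species is compatible when its probability falls below the cutoff
(0.5 by default), and the per-read call is the compatible species with
the lowest rule-out probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

from .alignment import AlignmentParams, search_candidates
from .mismatch_model import (
    RegionRateProfile,
    adjust_posterior,
    posterior_from_observation,
    rate_log_ratio,
    total_mismatch_distribution,
)
from .reference_db import QueryRead, ReferenceDatabase
from .ruleout import RuleoutConfig, hard_ruleout_probability, soft_ruleout_probability

logger = logging.getLogger(__name__)


@dataclass
class RuleoutRow:
    """One (read, candidate species) result.

    A sentinel row (no candidate found) has empty species_name and
    accession, None bookkeeping fields, and probability 1.0.
    """

    read_id: str
    species_name: str
    accession: str
    mismatches: Optional[int]
    n_columns: Optional[int]
    subject_length: Optional[int]
    observed_identity: Optional[float]
    ruleout_probability: float
    compatible: bool
    threshold_mode: str
    rate_mode: str


class SpeciesCall(NamedTuple):
    """Best compatible species for one read (species_name None if none)."""

    read_id: str
    species_name: Optional[str]
    ruleout_probability: Optional[float]


def _candidate_probability(aln, config: RuleoutConfig, profile) -> tuple[float, str]:
    """Rule-out probability for one candidate; returns (p, rate mode used)."""
    posterior = posterior_from_observation(aln.mismatches, aln.n_columns)
    rate_mode = "constant"
    if config.rate_mode == "variable":
        if profile is None:
            logger.warning(
                "no rate profile for %s; falling back to constant rate for read %s",
                aln.accession, aln.read_id,
            )
        else:
            try:
                ratio = rate_log_ratio(profile, (aln.subject_start, aln.subject_end))
                posterior = adjust_posterior(posterior, ratio.ratio)
                rate_mode = "variable"
            except ValueError as exc:
                logger.warning(
                    "rate profile unusable for %s (%s); falling back to constant",
                    aln.accession, exc,
                )
    dist = total_mismatch_distribution(
        aln.mismatches, aln.n_columns, aln.subject_length, posterior=posterior
    )
    if config.threshold_mode == "hard":
        p = hard_ruleout_probability(dist, aln.subject_length, config.threshold_identity)
    else:
        p = soft_ruleout_probability(dist, aln.subject_length, config.soft_half_max)
    return p, rate_mode


def unassign(
    reads: Sequence[QueryRead],
    db: ReferenceDatabase,
    ruleout_config: Optional[RuleoutConfig] = None,
    alignment_params: Optional[AlignmentParams] = None,
    rate_profiles: Optional[dict[str, RegionRateProfile]] = None,
) -> list[RuleoutRow]:
    """Rule-out probabilities for every read against every candidate species.

    Rows for each read are sorted by ascending rule-out probability,
    ties broken by species name; reads appear in input order.
    """
    config = ruleout_config or RuleoutConfig()
    params = alignment_params or AlignmentParams()
    profiles = rate_profiles or {}
    if config.rate_mode == "variable" and not profiles:
        logger.warning("variable rate mode requested but no profiles supplied")
    rows: list[RuleoutRow] = []
    for read in reads:
        candidates = search_candidates(read, db, params)
        logger.info("read %s: %d candidate(s)", read.read_id, len(candidates))
        if not candidates:
            rows.append(
                RuleoutRow(
                    read_id=read.read_id,
                    species_name="",
                    accession="",
                    mismatches=None,
                    n_columns=None,
                    subject_length=None,
                    observed_identity=None,
                    ruleout_probability=1.0,
                    compatible=False,
                    threshold_mode=config.threshold_mode,
                    rate_mode=config.rate_mode,
                )
            )
            continue
        read_rows = []
        for aln in candidates:
            p, rate_mode = _candidate_probability(aln, config, profiles.get(aln.accession))
            read_rows.append(
                RuleoutRow(
                    read_id=read.read_id,
                    species_name=aln.species_name,
                    accession=aln.accession,
                    mismatches=aln.mismatches,
                    n_columns=aln.n_columns,
                    subject_length=aln.subject_length,
                    observed_identity=aln.identity,
                    ruleout_probability=p,
                    compatible=p < config.compatibility_cutoff,
                    threshold_mode=config.threshold_mode,
                    rate_mode=rate_mode,
                )
            )
        read_rows.sort(key=lambda r: (r.ruleout_probability, r.species_name))
        rows.extend(read_rows)
    return rows


def best_species_call(rows: Sequence[RuleoutRow], cutoff: float = 0.5) -> SpeciesCall:
    """Lowest-probability compatible species for one read, or none.

    Ties resolve to the lexicographically smallest species name.
    """
    read_ids = {row.read_id for row in rows}
    if len(read_ids) != 1:
        raise ValueError("best_species_call expects rows for exactly one read")
    read_id = read_ids.pop()
    compatible = [
        r for r in rows if r.species_name and r.ruleout_probability < cutoff
    ]
    if not compatible:
        return SpeciesCall(read_id, None, None)
    best = min(compatible, key=lambda r: (r.ruleout_probability, r.species_name))
    return SpeciesCall(read_id, best.species_name, best.ruleout_probability)


def calls_for_reads(rows: Sequence[RuleoutRow], cutoff: float = 0.5) -> list[SpeciesCall]:
    """Per-read best calls, in first-appearance order of read_id."""
    by_read: dict[str, list[RuleoutRow]] = {}
    for row in rows:
        by_read.setdefault(row.read_id, []).append(row)
    return [best_species_call(group, cutoff) for group in by_read.values()]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


RESULT_COLUMNS = (
    "read_id", "species_name", "accession", "mismatches", "n_columns",
    "subject_length", "observed_identity", "ruleout_probability",
    "compatible", "threshold_mode", "rate_mode",
)


def write_results_tsv(rows: Sequence[RuleoutRow], path) -> None:
    """Full per-candidate table; probabilities at 6 significant digits."""
    with open(path, "w") as handle:
        handle.write("\t".join(RESULT_COLUMNS) + "\n")
        for row in rows:
            handle.write(
                "\t".join(_fmt(getattr(row, col)) for col in RESULT_COLUMNS) + "\n"
            )


def write_calls_tsv(calls: Sequence[SpeciesCall], path) -> None:
    with open(path, "w") as handle:
        handle.write("read_id\tspecies_name\truleout_probability\n")
        for call in calls:
            handle.write(
                f"{call.read_id}\t{_fmt(call.species_name)}\t"
                f"{_fmt(call.ruleout_probability)}\n"
            )
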