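"""Semi-global pairwise alignment with free end gaps.

A short amplicon read is aligned against a full-length 16S gene so that
gaps at either end of either sequence carry no penalty; the read floats
to its best position within the gene. Terminal-gap columns are excluded
from the observed region, so the alignment yields the pair (x, n): the
number of mismatches x (substitutions plus internal gap columns) within
the n aligned columns. Candidate species are those whose alignment
identity (n - x)/n exceeds a minimum, 90% by default.

The aligner is a straightforward dynamic program with linear gap costs.
The intra-row gap recurrence is rewritten as a running maximum so each
row fills with vectorized numpy operations; traceback recovers the
column-by-column path used for mismatch bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .iupac import encode
from .reference_db import QueryRead, ReferenceDatabase, TypeStrainRecord

_TOL = 1e-9


@dataclass
class AlignmentParams:
    """Scoring and candidate-search settings.

    min_identity is a strict lower bound: a candidate is kept when its
    identity exceeds it. Gap costs are linear per gap column.
    """

    min_identity: float = 0.90
    max_candidates: Optional[int] = None
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_score: float = -2.0

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass
class PairwiseAlignment:
    """A read aligned to one type strain, with mismatch bookkeeping.

    ``columns`` is the traced alignment path excluding terminal gaps:
    tuples ``(query_pos, subject_pos, is_mismatch)`` where exactly one
    position is None in a gap column. ``n_columns`` is the observed
    region size n; ``mismatches`` is x; ``subject_length`` is the full
    gene length L of the reference record.
    """

    read_id: str
    accession: str
    species_name: str
    n_columns: int
    mismatches: int
    subject_start: int
    subject_end: int
    subject_length: int
    score: float = 0.0
    columns: list = field(default_factory=list, repr=False)

    @property
    def identity(self) -> float:
        if self.n_columns == 0:
            return 0.0
        return (self.n_columns - self.mismatches) / self.n_columns


def _dp_matrix(qm: np.ndarray, sm: np.ndarray, params: AlignmentParams) -> np.ndarray:
    """Fill the (|q|+1, |s|+1) semi-global score matrix, free end gaps."""
    nq, ns = qm.size, sm.size
    g = params.gap_score
    is_match = (qm[:, None] & sm[None, :]) != 0
    sub = np.where(is_match, params.match_score, params.mismatch_score)
    H = np.zeros((nq + 1, ns + 1))
    j = np.arange(1, ns + 1)
    gj = g * j
    for i in range(1, nq + 1):
        # best of diagonal and up moves, then propagate left-gap chains
        # via a running maximum of (candidate - g*j); the seeded 0.0 is
        # the j'=0 origin, a free leading gap in the query
        a = np.maximum(H[i - 1, :-1] + sub[i - 1], H[i - 1, 1:] + g)
        H[i, 1:] = gj + np.maximum.accumulate(np.concatenate(([0.0], a - gj)))[1:]
    return H


def _best_endpoint(H: np.ndarray) -> tuple[int, int]:
    """Max-scoring cell on the last row or last column (trailing gaps free).

    Ties resolve to the largest subject coordinate, then the largest
    query coordinate, so results are deterministic.
    """
    nq = H.shape[0] - 1
    ns = H.shape[1] - 1
    best = max(H[nq, :].max(), H[:, ns].max())
    candidates = [(j, nq) for j in np.flatnonzero(H[nq, :] >= best - _TOL)]
    candidates += [(ns, i) for i in np.flatnonzero(H[:, ns] >= best - _TOL)]
    j, i = max(candidates)
    return int(i), int(j)


def semiglobal_align(
    read: QueryRead, ref: TypeStrainRecord, params: Optional[AlignmentParams] = None
) -> PairwiseAlignment:
    """Align a read to a type strain with zero-cost terminal gaps.

    Internal gap columns count as mismatches; terminal gap columns are
    excluded from both n_columns and mismatches. A reference position
    with a degenerate IUPAC code matches any base it denotes.
    """
    if params is None:
        params = AlignmentParams()
    qm = encode(read.sequence, context=f"read {read.read_id!r}")
    sm = encode(ref.sequence, context=f"record {ref.accession!r}")
    H = _dp_matrix(qm, sm, params)
    g = params.gap_score
    i, j = _best_endpoint(H)
    score = float(H[i, j])
    subject_end = j

    columns: list[tuple[Optional[int], Optional[int], bool]] = []
    while i > 0 and j > 0:
        here = H[i, j]
        match = (qm[i - 1] & sm[j - 1]) != 0
        sub = params.match_score if match else params.mismatch_score
        if abs(here - (H[i - 1, j - 1] + sub)) < _TOL:
            columns.append((i - 1, j - 1, not match))
            i -= 1
            j -= 1
        elif abs(here - (H[i - 1, j] + g)) < _TOL:
            columns.append((i - 1, None, True))  # gap in subject
            i -= 1
        else:
            columns.append((None, j - 1, True))  # gap in query
            j -= 1
    columns.reverse()

    subject_positions = [c[1] for c in columns if c[1] is not None]
    subject_start = subject_positions[0] if subject_positions else subject_end
    if subject_positions:
        subject_end = subject_positions[-1] + 1
    mismatches = sum(1 for c in columns if c[2])
    return PairwiseAlignment(
        read_id=read.read_id,
        accession=ref.accession,
        species_name=ref.species_name,
        n_columns=len(columns),
        mismatches=mismatches,
        subject_start=subject_start,
        subject_end=subject_end,
        subject_length=len(ref.sequence),
        score=score,
        columns=columns,
    )


def semiglobal_score(seq_a: str, seq_b: str, params: Optional[AlignmentParams] = None) -> float:
    """Optimal semi-global score only (no traceback)."""
    if params is None:
        params = AlignmentParams()
    H = _dp_matrix(encode(seq_a), encode(seq_b), params)
    i, j = _best_endpoint(H)
    return float(H[i, j])


def search_candidates(
    read: QueryRead, db: ReferenceDatabase, params: Optional[AlignmentParams] = None
) -> list[PairwiseAlignment]:
    """Alignments against every record whose identity exceeds min_identity.

    Sorted by descending identity, ties broken by ascending accession;
    an empty list is a legal result.
    """
    if params is None:
        params = AlignmentParams()
    hits = []
    for record in db:
        aln = semiglobal_align(read, record, params)
        if aln.identity > params.min_identity:
            hits.append(aln)
    hits.sort(key=lambda a: (-a.identity, a.accession))
    if params.max_candidates is not None:
        hits = hits[: params.max_candidates]
    return hits


def write_alignments_tsv(alignments, path) -> None:
    """BLAST-like tabular dump of alignments."""
    header = "read_id\taccession\tspecies_name\tpct_identity\tn_columns\tmismatches\tsubject_start\tsubject_end\n"
    with open(path, "w") as handle:
        handle.write(header)
        for a in alignments:
            handle.write(
                f"{a.read_id}\t{a.accession}\t{a.species_name}\t"
                f"{100 * a.identity:.6g}\t{a.n_columns}\t{a.mismatches}\t"
                f"{a.subject_start}\t{a.subject_end}\n"
            )
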