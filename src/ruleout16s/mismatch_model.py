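"""Beta-binomial extrapolation of mismatches to the full 16S gene.

Observing x mismatches in n aligned columns, the per-position mismatch
rate gets a Beta posterior under the Jeffreys prior Beta(0.5, 0.5):
alpha = x + 0.5, beta = (n - x) + 0.5. The number of additional
mismatches k in the m = L - n unobserved positions of the full-length
gene is then beta-binomially distributed, giving a probability
distribution over total mismatches x + k.

The variable-mismatch-rate algorithm corrects for the sequenced region
being more or less variable than the rest of the gene: from a
per-position mismatch-rate profile of the type strain, the log ratio of
the mean rate outside versus inside the aligned region rescales the
posterior mean while preserving its concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence, Union

import numpy as np
from scipy.special import betaln, gammaln


@dataclass(frozen=True)
class MismatchPosterior:
    """Beta(alpha, beta) posterior over the per-position mismatch rate."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("posterior parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class RegionRateProfile:
    """Per-position mismatch probabilities along one type strain's gene."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        if rates.ndim != 1 or rates.size == 0:
            raise ValueError("rates must be a non-empty 1-D array")
        if (rates < 0).any() or (rates > 1).any():
            raise ValueError("rates must lie in [0, 1]")
        object.__setattr__(self, "rates", rates)

    def __len__(self) -> int:
        return self.rates.size


@dataclass(frozen=True)
class TotalMismatchDistribution:
    """Distribution over mismatches in the unobserved gene remainder.

    ``probabilities[k]`` is P(k extra mismatches among the m unobserved
    positions); total full-gene mismatches are x + k.
    """

    x: int
    m: int
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.size != self.m + 1:
            raise ValueError("probabilities must have length m + 1")
        if (p < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        object.__setattr__(self, "probabilities", p)

    @property
    def support(self) -> np.ndarray:
        """Total mismatch counts x + k for k = 0..m."""
        return self.x + np.arange(self.m + 1)

    @property
    def mean_extra(self) -> float:
        return float(np.arange(self.m + 1) @ self.probabilities)


def posterior_from_observation(x: int, n: int) -> MismatchPosterior:
    """Jeffreys-prior Beta posterior after x mismatches in n columns."""
    if x < 0 or n < 0 or x > n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    return MismatchPosterior(alpha=x + 0.5, beta=(n - x) + 0.5)


def beta_binomial_logpmf(
    k: Union[int, np.ndarray], m: int, alpha: float, beta: float
) -> np.ndarray:
    """log P(k successes in m trials), success rate ~ Beta(alpha, beta)."""
    k = np.asarray(k)
    return (
        gammaln(m + 1)
        - gammaln(k + 1)
        - gammaln(m - k + 1)
        + betaln(k + alpha, m - k + beta)
        - betaln(alpha, beta)
    )


def beta_binomial_pmf(k: int, m: int, posterior: MismatchPosterior) -> float:
    """Beta-binomial pmf C(m,k) B(k+a, m-k+b) / B(a, b), log-space."""
    if k < 0 or k > m:
        raise ValueError(f"need 0 <= k <= m, got k={k}, m={m}")
    if m == 0:
        return 1.0
    return float(np.exp(beta_binomial_logpmf(k, m, posterior.alpha, posterior.beta)))


def total_mismatch_distribution(
    x: int, n: int, L: int, posterior: MismatchPosterior | None = None
) -> TotalMismatchDistribution:
    """Distribution of extra mismatches over the m = L - n unobserved positions.

    ``posterior`` defaults to the Jeffreys update of (x, n); pass an
    adjusted posterior for the variable-mismatch-rate algorithm.
    """
    if n > L:
        raise ValueError(f"observed columns n={n} exceed gene length L={L}")
    if posterior is None:
        posterior = posterior_from_observation(x, n)
    m = L - n
    if m == 0:
        probs = np.ones(1)
    else:
        k = np.arange(m + 1)
        probs = np.exp(beta_binomial_logpmf(k, m, posterior.alpha, posterior.beta))
        probs /= probs.sum()
    return TotalMismatchDistribution(x=x, m=m, probabilities=probs)


def estimate_position_rates(alignments: Sequence) -> RegionRateProfile:
    """Per-position mismatch rates for one type strain from aligned variants.

    Input alignments must all be against the same subject and carry
    their column paths. The rate at subject position i is the
    pseudocount-regularized frequency (mismatching + 0.5) / (covering + 1);
    uncovered positions receive the mean of the covered rates, so the
    downstream log ratio is always finite.
    """
    alignments = list(alignments)
    if not alignments:
        raise ValueError("need at least one alignment to estimate rates")
    L = alignments[0].subject_length
    if any(a.subject_length != L for a in alignments):
        raise ValueError("alignments span subjects of different lengths")
    covering = np.zeros(L)
    mismatching = np.zeros(L)
    for aln in alignments:
        for _, spos, is_mismatch in aln.columns:
            if spos is None:
                continue  # insertion in the variant: no subject position
            covering[spos] += 1
            if is_mismatch:
                mismatching[spos] += 1
    rates = (mismatching + 0.5) / (covering + 1)
    covered = covering > 0
    if not covered.any():
        raise ValueError("no subject position is covered by any alignment")
    rates[~covered] = rates[covered].mean()
    return RegionRateProfile(rates=rates)


class RateRatio(NamedTuple):
    """Mean mismatch-rate ratio, unobserved over observed region."""

    log_ratio: float
    ratio: float


def rate_log_ratio(profile: RegionRateProfile, region: tuple[int, int]) -> RateRatio:
    """log(mean rate outside region) - log(mean rate inside region).

    ``region`` is the 0-based half-open subject interval covered by the
    read's alignment. A ratio above 1 means the rest of the gene is more
    variable than the sequenced region.
    """
    start, end = region
    L = len(profile)
    if not (0 <= start < end <= L):
        raise ValueError(f"region [{start}, {end}) not inside [0, {L})")
    outside = np.concatenate([profile.rates[:start], profile.rates[end:]])
    if outside.size == 0:
        raise ValueError("region covers the whole gene: no outside positions")
    inside_mean = profile.rates[start:end].mean()
    if inside_mean == 0:
        raise ValueError("mean rate inside the region is zero")
    log_ratio = float(np.log(outside.mean()) - np.log(inside_mean))
    return RateRatio(log_ratio=log_ratio, ratio=float(np.exp(log_ratio)))


def adjust_posterior(posterior: MismatchPosterior, ratio: float) -> MismatchPosterior:
    """Rescale the posterior mean by ``ratio``, preserving concentration.

    alpha' = min(ratio * alpha, alpha + beta - eps) and beta' keeps
    alpha' + beta' = alpha + beta, so the mean scales by the rate ratio
    but stays strictly below 1. ratio = 1 leaves the posterior unchanged.
    """
    if ratio <= 0:
        raise ValueError("rate ratio must be positive")
    eps = 1e-6
    total = posterior.alpha + posterior.beta
    alpha = min(ratio * posterior.alpha, total - eps)
    return MismatchPosterior(alpha=alpha, beta=total - alpha)


def write_rate_profiles_tsv(profiles: dict[str, RegionRateProfile], path) -> None:
    """Sidecar TSV: accession, 0-based position, rate."""
    with open(path, "w") as handle:
        handle.write("accession\tposition\trate\n")
        for accession in sorted(profiles):
            for pos, rate in enumerate(profiles[accession].rates):
                handle.write(f"{accession}\t{pos}\t{rate:.6g}\n")


def read_rate_profiles_tsv(path) -> dict[str, RegionRateProfile]:
    """Read the per-strain rate-profile sidecar written above."""
    per_accession: dict[str, dict[int, float]] = {}
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("accession"):
            raise ValueError(f"{path}: expected header starting with 'accession'")
        for line_no, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            try:
                accession, pos, rate = line.rstrip("\n").split("\t")
                per_accession.setdefault(accession, {})[int(pos)] = float(rate)
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: malformed profile row") from exc
    profiles = {}
    for accession, entries in per_accession.items():
        L = max(entries) + 1
        rates = np.full(L, np.nan)
        for pos, rate in entries.items():
            rates[pos] = rate
        missing = np.isnan(rates)
        if missing.all():
            raise ValueError(f"profile for {accession} has no positions")
        rates[missing] = rates[~missing].mean()
        profiles[accession] = RegionRateProfile(rates=rates)
    return profiles
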