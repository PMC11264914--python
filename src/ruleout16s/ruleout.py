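"""Species rule-out criteria: hard identity threshold and soft curve.

The hard-threshold criterion rules a species out when the full-gene
identity falls below a fixed threshold (97.5% by default, the
conventional bound below which a strain cannot belong to an existing
species). The rule-out probability is the beta-binomial tail
probability that total mismatches exceed the gene's mismatch budget
(1 - threshold) * L.

The soft-threshold criterion replaces the step function with an
exponential curve for the probability that two genomes share
species-level average nucleotide identity given their 16S identity d:

    f(d) = 2 ** (-(1 - d) / (1 - d_half))

which equals 1 at d = 1 and 0.5 at the half-maximum point d_half
(99.1% by default). The rule-out probability is one minus the
expectation of f under the total-mismatch distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .mismatch_model import TotalMismatchDistribution

_CLIP = 1e-12


@dataclass
class RuleoutConfig:
    """Settings for the rule-out computation.

    threshold_mode selects hard (fixed identity threshold) or soft
    (exponential species-probability curve); rate_mode selects the
    constant- or variable-mismatch-rate extrapolation. A species is
    called compatible when its rule-out probability is below
    compatibility_cutoff.
    """

    threshold_identity: float = 0.975
    soft_half_max: float = 0.991
    threshold_mode: str = "hard"
    rate_mode: str = "constant"
    compatibility_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.threshold_identity < 1:
            raise ValueError("threshold_identity must be in (0, 1)")
        if not 0 < self.soft_half_max < 1:
            raise ValueError("soft_half_max must be in (0, 1)")
        if self.threshold_mode not in ("hard", "soft"):
            raise ValueError("threshold_mode must be 'hard' or 'soft'")
        if self.rate_mode not in ("constant", "variable"):
            raise ValueError("rate_mode must be 'constant' or 'variable'")
        if not 0 <= self.compatibility_cutoff <= 1:
            raise ValueError("compatibility_cutoff must be in [0, 1]")


def hard_ruleout_probability(
    dist: TotalMismatchDistribution, L: int, threshold_identity: float = 0.975
) -> float:
    """P(total mismatches > (1 - threshold) * L), strict, real-valued bound.

    Computed as one minus the lower tail so that when the observed
    mismatches alone exceed the budget the result is exactly 1.0.
    """
    budget = (1.0 - threshold_identity) * L
    # totals x + k <= budget  <=>  k <= budget - x
    kmax = int(np.floor(budget - dist.x))
    if kmax < 0:
        return 1.0
    lower = dist.probabilities[: min(kmax, dist.m) + 1].sum()
    return float(min(max(1.0 - lower, 0.0), 1.0))


def species_probability_curve(d, d_half: float = 0.991):
    """Probability of species-level genome identity at 16S identity d.

    Exponential in the mismatch fraction with half-maximum at d_half;
    monotone increasing, f(1) = 1, f(d_half) = 0.5.
    """
    if d_half >= 1:
        raise ValueError("d_half must be below 1")
    d = np.asarray(d, dtype=float)
    out = np.power(2.0, -(1.0 - d) / (1.0 - d_half))
    return float(out) if out.ndim == 0 else out


def soft_ruleout_probability(
    dist: TotalMismatchDistribution, L: int, d_half: float = 0.991
) -> float:
    """1 - E[f(full-gene identity)] under the total-mismatch distribution.

    Full-gene identity for k extra mismatches is (L - x - k) / L.
    """
    totals = dist.support
    identities = (L - totals) / L
    p_species = species_probability_curve(identities, d_half)
    value = 1.0 - float(dist.probabilities @ p_species)
    return min(max(value, 0.0), 1.0)


def fit_half_max(identities, labels) -> float:
    """Maximum-likelihood half-max point of the species-probability curve.

    ``identities`` are 16S identities of genome pairs in [0, 1];
    ``labels`` mark pairs with species-level whole-genome identity.
    Fits d_half in the Bernoulli model P(label=1 | d) = f(d) by
    one-dimensional bounded optimization of the log likelihood.
    """
    d = np.asarray(identities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("identities and labels must be 1-D and equal length")
    if y.min() == y.max():
        raise ValueError("labels are degenerate: both classes are required")
    if np.unique(d).size < 2:
        raise ValueError("need at least two distinct identity values")

    def nll(d_half: float) -> float:
        f = np.clip(species_probability_curve(d, d_half), _CLIP, 1 - _CLIP)
        return -float(y @ np.log(f) + (1 - y) @ np.log1p(-f))

    result = minimize_scalar(
        nll, bounds=(1e-6, 1 - 1e-6), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(result.x)
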