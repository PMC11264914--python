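# Methods

## Problem and model

Marker-gene surveys sequence a few hundred bases of the ~1,500 nt 16S
rRNA gene, but the convention for delimiting bacterial species is
stated in terms of the *full-length* gene: a strain whose 16S identity
to an existing species' type strain is below 97.5% cannot belong to
that species. `ruleout16s` bridges the gap probabilistically. Instead
of assigning a species, it computes for each (read, species) pair a
**rule-out probability**: the probability that the full-gene identity
falls below the species criterion, given only the sequenced region.

The computation has three steps.

**1. Candidate search.** The read is aligned semi-globally (terminal
gaps on either sequence are free) to every type-strain gene. The
observed region contributes `n` alignment columns (terminal gaps
excluded) and `x` mismatches, where substitutions and *internal* gap
columns both count as mismatches and a degenerate IUPAC reference code
matches any base it denotes. Species with identity `(n - x)/n`
strictly above 90% are candidates; everything else is ruled out
outright at this step.

**2. Mismatch extrapolation.** Assume mismatches arise independently
per position at an unknown rate `p`. Under the Jeffreys prior
Beta(0.5, 0.5), observing `x` of `n` gives the posterior
Beta(x + 0.5, n − x + 0.5). The number of additional mismatches `k`
among the `m = L − n` unobserved positions of the full gene
(gene length `L` = the reference record's length) is then
beta-binomial:

```
P(k | m, α, β) = C(m, k) · B(k + α, m − k + β) / B(α, β)
```

computed in log space with `gammaln`/`betaln`. Total full-gene
mismatches are `x + k`.

The **variable-mismatch-rate** variant corrects for the sequenced
region being systematically more or less variable than the rest of the
gene. From a per-position mismatch-rate profile of the type strain
(estimated from user-supplied full-length variants with +0.5/+1
pseudocounts, so no rate is ever zero), the statistic is the log ratio
of the mean rate outside versus inside the aligned region,
`ρ = mean(outside)/mean(inside)`. The posterior mean is rescaled by
`ρ` while preserving the concentration:
`α' = min(ρα, α + β − 1e-6)`, `β' = (α + β) − α'`. At `ρ = 1` this is
exactly the constant-rate algorithm. The functional form of this
adjustment is a design choice of this package: only the log-ratio
statistic itself is canonical, and any form used here must reduce to
the constant-rate model for a flat profile, which this one does by
construction. The clamp keeps the mean strictly below 1 for extreme
profiles.

**3. Rule-out criterion.** With threshold identity θ (default 0.975),
the **hard** criterion reports the tail probability
`P(x + k > (1 − θ)·L)`. The bound is kept real-valued and the
inequality strict — no rounding of `(1 − θ)·L` — so results are
bit-reproducible and unambiguous when the budget is an integer. The
tail is evaluated as one minus the lower sum, so when `x` alone
exceeds the budget the result is exactly 1.0.

The **soft** criterion replaces the step with an exponential curve for
the probability that two genomes share species-level average
nucleotide identity given 16S identity `d`:

```
f(d) = 2^(−(1 − d) / (1 − d_half))
```

with half-maximum `d_half = 0.991` by default; base 2 is the natural
way to express a half-maximum, and any exponential with the same
half-max point is identical. The rule-out probability integrates the
curve over the mismatch distribution,
`1 − Σ_k P(k) · f((L − x − k)/L)`, rather than evaluating it at a
point estimate; full-gene identity uses the same denominator `L` as
the hard criterion. `fit_half_max` re-estimates `d_half` from labeled
(identity, same-species) pairs by bounded one-dimensional
maximum-likelihood (Bernoulli model, `minimize_scalar`, probabilities
clipped to (1e-12, 1 − 1e-12) so separable data cannot produce
infinite log-likelihoods).

A species is **compatible** with a read when its rule-out probability
is below 0.5; the per-read call is the compatible species with the
lowest probability, ties broken alphabetically. Reads with no
candidate at all are reported with a sentinel row (empty species,
probability 1.0).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_identity` | 0.90 | strict candidate-search identity cutoff |
| `threshold_identity` θ | 0.975 | hard-criterion full-gene identity threshold |
| `soft_half_max` | 0.991 | identity at which the soft curve crosses 0.5 |
| `compatibility_cutoff` | 0.5 | rule-out probability below which a species is compatible |
| match / mismatch / gap | +1 / −1 / −2 | linear alignment scores; gaps are discouraged relative to substitutions, matching the mismatch-counting semantics |

The Jeffreys prior is fixed, not configurable: the posterior update
`(x + 0.5, n − x + 0.5)` is part of the model definition.

## Alignment details

The dynamic program scores global alignments with zero-cost terminal
gaps on both sequences (first row and column zero; optimum taken over
the last row and column). Each row of the matrix is filled with
vectorized numpy by rewriting the within-row gap recurrence as a
running maximum, which keeps a 322 × 1,500 alignment at a few
milliseconds without compiled extensions. Traceback prefers diagonal
over gap-in-subject over gap-in-query at score ties, and endpoint ties
resolve to the largest subject then query coordinate, so outputs are
deterministic. The aligner is validated against an independent
exhaustive-recursion oracle on short random pairs. `m` is defined as
`L − n_columns`; the alternative `L` minus the aligned subject span
differs only when internal gaps exist and was rejected for bookkeeping
simplicity.

## Synthetic data

The fixture generator mirrors the model's generative assumptions so
ground truth is exact. A database is a star phylogeny: species 0 is a
uniform-random gene; every other species substitutes each position
independently with the between-species divergence, drawing uniformly
from the three other bases (so a substituted site always mismatches
and pairwise divergence to the ancestor is exactly the nominal rate).
Reads are slices of a fixed region with independent per-site
substitutions at `inside_rate`; the truth table records exact
introduced mismatch counts. Defaults emulate a V1-V2-style survey:
10 species, 1,500 nt genes, 10% divergence, error-free 322 nt reads
from positions [27, 349), 200 reads. All outputs are byte-identical
under a fixed seed.

What the generator deliberately omits — and what passing tests
therefore do not demonstrate about real data: indels and sequencing
indel errors, chimeras, quality-score structure, non-uniform
substitution processes (real variable regions are hypervariable,
which is exactly why the variable-rate algorithm exists), tree-shaped
rather than star-shaped phylogenies, and multiple type strains per
species. The rate-profile fixture is a two-level step function, so it
validates the log-ratio arithmetic, not the realism of profile
estimation from reference alignments.

## Numerical choices

- Beta-binomial pmf in log space; the assembled distribution is
  renormalized (the raw sum is already within 1e-12 of 1).
- Hard tail via the complement of the lower sum: exact 1.0 whenever
  the observed mismatches alone exceed the budget.
- Alignment score equality tests use a 1e-9 tolerance; with the
  default integer-valued scores all sums are exact in floating point.
- Degenerate inputs: an empty database yields a sentinel row per read;
  a region covering the whole gene, or an all-zero inside rate, raises
  in `rate_log_ratio`, and the pipeline falls back to the
  constant-rate algorithm for that candidate with a warning, as it
  does for a missing profile.
- Primer matching is ungapped Hamming with IUPAC set-intersection
  semantics, one mismatch allowed by default, leftmost best site on
  ties; the reverse primer is reverse-complemented before searching
  the forward strand and primer bases are excluded from the extracted
  region.

## Problem sizes

The test and reproduction workloads are desk-scale by design: the
end-to-end recovery study uses 10 species × 200 reads (2,000
alignments, tens of seconds), the Monte-Carlo pmf check uses 10^6
Beta/Binomial draws, the aligner oracle uses 200 random pairs of up to
30 nt, and the curve-fit recovery uses 10^4 labeled pairs. Database-
scale analyses (tens of thousands of type strains) would want the
pluggable alignment engine backed by a compiled aligner; the contract
in `alignment.py` is written to allow that substitution when it
reproduces the reference implementation on the test suite.

## Known limitations

- Sequencing error and biological divergence are conflated in the
  single mismatch rate; there is no per-base quality weighting.
- The mismatch model ignores indels; internal gap columns are simply
  counted as mismatches.
- Identity is computed against the full reference gene length; reads
  hanging off a truncated reference record shorten `L` accordingly.
- Reverse-strand reads are not searched; amplicons are assumed to be
  in primer orientation.
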