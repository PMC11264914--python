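import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ruleout16s import (
    MismatchPosterior,
    QueryRead,
    TypeStrainRecord,
    adjust_posterior,
    beta_binomial_pmf,
    estimate_position_rates,
    posterior_from_observation,
    rate_log_ratio,
    semiglobal_align,
    simulate_rate_profile,
    total_mismatch_distribution,
)
from ruleout16s.mismatch_model import read_rate_profiles_tsv, write_rate_profiles_tsv


class TestPosterior:
    @pytest.mark.parametrize(
        "x,n,alpha,beta",
        [(2, 322, 2.5, 320.5), (83, 322, 83.5, 239.5), (0, 0, 0.5, 0.5)],
    )
    def test_jeffreys_update(self, x, n, alpha, beta):
        posterior = posterior_from_observation(x, n)
        assert (posterior.alpha, posterior.beta) == (alpha, beta)

    def test_x_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            posterior_from_observation(5, 4)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            MismatchPosterior(0.0, 1.0)


class TestBetaBinomialPmf:
    def test_empty_support_is_certain(self):
        assert beta_binomial_pmf(0, 0, MismatchPosterior(2.5, 320.5)) == 1.0

    def test_symmetric_when_alpha_equals_beta(self):
        posterior = MismatchPosterior(3.0, 3.0)
        for m in (1, 5, 12):
            for k in range(m + 1):
                assert beta_binomial_pmf(k, m, posterior) == pytest.approx(
                    beta_binomial_pmf(m - k, m, posterior), abs=1e-12
                )

    def test_telescoping_product_oracle(self):
        # P(k=0 | m=3) = prod_{i=0..2} (beta + i) / (alpha + beta + i)
        value = beta_binomial_pmf(0, 3, MismatchPosterior(2.5, 320.5))
        oracle = (320.5 * 321.5 * 322.5) / (323 * 324 * 325)
        assert value == pytest.approx(oracle, rel=1e-10)

    def test_matches_scipy_betabinom(self):
        posterior = MismatchPosterior(2.5, 320.5)
        for m in (1, 10, 100):
            for k in range(0, m + 1, max(1, m // 7)):
                assert beta_binomial_pmf(k, m, posterior) == pytest.approx(
                    stats.betabinom.pmf(k, m, 2.5, 320.5), rel=1e-9
                )

    @given(
        m=st.integers(1, 200),
        alpha=st.floats(0.1, 50),
        beta=st.floats(0.1, 500),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pmf_normalizes(self, m, alpha, beta):
        posterior = MismatchPosterior(alpha, beta)
        total = sum(beta_binomial_pmf(k, m, posterior) for k in range(m + 1))
        assert abs(total - 1.0) < 1e-9

    def test_out_of_range_k_rejected(self):
        with pytest.raises(ValueError):
            beta_binomial_pmf(4, 3, MismatchPosterior(1, 1))


class TestTotalMismatchDistribution:
    def test_fully_observed_gene_is_point_mass(self):
        dist = total_mismatch_distribution(2, 322, 322)
        assert dist.m == 0
        assert dist.probabilities.tolist() == [1.0]

    def test_mean_matches_posterior_mean_times_m(self):
        dist = total_mismatch_distribution(2, 322, 1500)
        assert dist.mean_extra == pytest.approx(1178 * 2.5 / 323, rel=1e-9)

    def test_single_unobserved_position_closed_form(self):
        dist = total_mismatch_distribution(0, 322, 323)
        assert dist.probabilities[1] == pytest.approx(0.5 / 323, rel=1e-9)

    def test_monte_carlo_oracle_small_m(self):
        # theta ~ Beta(2.5, 320.5), k ~ Binomial(20, theta)
        rng = np.random.default_rng(12345)
        n_draws = 200_000
        theta = rng.beta(2.5, 320.5, size=n_draws)
        draws = rng.binomial(20, theta)
        dist = total_mismatch_distribution(2, 322, 342)
        for k in range(21):
            p = dist.probabilities[k]
            p_hat = np.mean(draws == k)
            se = np.sqrt(max(p * (1 - p), 1e-12) / n_draws)
            assert abs(p_hat - p) < 4 * se + 1e-9

    def test_stochastically_increasing_in_x(self):
        # higher observed mismatch count shifts total mismatches upward
        n, L = 322, 1500
        cdfs = []
        for x in (0, 2, 10, 30):
            dist = total_mismatch_distribution(x, n, L)
            totals = np.zeros(L + 1)
            totals[dist.support] = dist.probabilities
            cdfs.append(np.cumsum(totals))
        for lower, higher in zip(cdfs, cdfs[1:]):
            assert (higher <= lower + 1e-12).all()

    def test_observed_exceeding_gene_rejected(self):
        with pytest.raises(ValueError):
            total_mismatch_distribution(0, 500, 400)

    def test_posterior_mean_recovers_simulation_rate(self):
        from ruleout16s import SimulationConfig, simulate_database, simulate_reads

        rate = 0.01
        cfg = SimulationConfig(
            n_species=1, gene_length=1500, region_start=0, region_end=322,
            inside_rate=rate, n_reads=1000, seed=21,
        )
        db = simulate_database(cfg)
        _, truth = simulate_reads(db, cfg)
        means = [
            posterior_from_observation(t.mismatches, 322).mean for t in truth
        ]
        se = np.sqrt(rate * (1 - rate) / (322 * 1000))
        assert abs(np.mean(means) - rate) < 3 * se + 0.5 / 323


class TestPositionRates:
    def _align_all(self, subject, variants):
        ref = TypeStrainRecord("S", "Genus sp", subject)
        return [
            semiglobal_align(QueryRead(f"v{i}", seq), ref)
            for i, seq in enumerate(variants)
        ]

    def test_identical_variants_give_regularized_zero(self):
        subject = "ACGTACGTACGTACGTACGT"
        alignments = self._align_all(subject, [subject] * 10)
        profile = estimate_position_rates(alignments)
        assert profile.rates == pytest.approx(np.full(20, 0.5 / 11))

    def test_all_mismatching_variant_gives_regularized_extreme(self):
        # built directly: a free-end-gap aligner would align nothing for
        # a fully mismatching pair, but the rate arithmetic must still
        # handle a column set that mismatches at every position
        from ruleout16s.alignment import PairwiseAlignment

        aln = PairwiseAlignment(
            read_id="v0", accession="S", species_name="Genus sp",
            n_columns=10, mismatches=10, subject_start=0, subject_end=10,
            subject_length=10,
            columns=[(i, i, True) for i in range(10)],
        )
        profile = estimate_position_rates([aln])
        assert profile.rates == pytest.approx(np.full(10, 1.5 / 2))

    def test_recovers_simulated_inside_rate(self):
        rng = np.random.default_rng(31)
        L, n_variants, rate = 300, 200, 0.02
        subject = "".join(rng.choice(list("ACGT"), size=L))
        other = {"A": "C", "C": "G", "G": "T", "T": "A"}
        variants = []
        for _ in range(n_variants):
            seq = [other[b] if rng.random() < rate else b for b in subject]
            variants.append("".join(seq))
        profile = estimate_position_rates(self._align_all(subject, variants))
        se = np.sqrt(rate * (1 - rate) / n_variants)
        # positionwise estimates are noisy; the profile mean is tight
        assert abs(profile.rates.mean() - rate) < 3 * se / np.sqrt(L) + 0.5 / (n_variants + 1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_position_rates([])


class TestRateRatio:
    def test_uniform_profile_has_zero_log_ratio(self):
        profile = simulate_rate_profile(100, 0.02, 0.02, (10, 60))
        result = rate_log_ratio(profile, (10, 60))
        assert result.log_ratio == pytest.approx(0.0, abs=1e-12)
        assert result.ratio == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "inside,outside,expected", [(0.01, 0.02, 2.0), (0.02, 0.01, 0.5)]
    )
    def test_step_profile_ratio(self, inside, outside, expected):
        profile = simulate_rate_profile(1500, inside, outside, (100, 422))
        result = rate_log_ratio(profile, (100, 422))
        assert result.ratio == pytest.approx(expected, rel=1e-12)
        assert result.log_ratio == pytest.approx(np.log(expected), rel=1e-12)

    def test_region_covering_gene_rejected(self):
        profile = simulate_rate_profile(100, 0.01, 0.02, (0, 100))
        with pytest.raises(ValueError, match="outside"):
            rate_log_ratio(profile, (0, 100))


class TestAdjustPosterior:
    def test_unit_ratio_is_identity(self):
        posterior = MismatchPosterior(2.5, 320.5)
        adjusted = adjust_posterior(posterior, 1.0)
        assert (adjusted.alpha, adjusted.beta) == (2.5, 320.5)

    def test_mean_scales_and_concentration_is_preserved(self):
        adjusted = adjust_posterior(MismatchPosterior(2.5, 320.5), 2.0)
        assert (adjusted.alpha, adjusted.beta) == (5.0, 318.0)
        assert adjusted.mean == pytest.approx(2 * 2.5 / 323)

    def test_huge_ratio_clamps_mean_below_one(self):
        adjusted = adjust_posterior(MismatchPosterior(2.5, 320.5), 1e9)
        assert adjusted.mean < 1.0
        assert adjusted.alpha + adjusted.beta == pytest.approx(323.0)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            adjust_posterior(MismatchPosterior(1, 1), 0.0)


def test_rate_profile_tsv_round_trip(tmp_path):
    profiles = {
        "ACC1": simulate_rate_profile(50, 0.01, 0.02, (10, 30)),
        "ACC2": simulate_rate_profile(40, 0.05, 0.03, (5, 20)),
    }
    path = tmp_path / "profiles.tsv"
    write_rate_profiles_tsv(profiles, path)
    again = read_rate_profiles_tsv(path)
    assert set(again) == {"ACC1", "ACC2"}
    for acc in profiles:
        assert np.allclose(again[acc].rates, profiles[acc].rates, atol=1e-6)
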