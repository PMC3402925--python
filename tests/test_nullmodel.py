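"""The truncated-exponential log-distance null, its mixture, and the
two-sample / Monte-Carlo comparisons."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import breakprox as bp


class TestDensityAndCdf:
    def test_density_closed_form_values(self):
        assert bp.null_density(16.0, 16.0) == pytest.approx(1.0)
        assert bp.null_density(15.0, 16.0) == pytest.approx(math.exp(-1))
        assert bp.null_density(-0.5, 16.0) == 0.0
        assert bp.null_density(16.5, 16.0) == 0.0

    def test_density_integrates_to_one_minus_floor_mass(self):
        # the e^(-U) deficit is the probability of sub-nucleotide distances
        # under the un-floored model
        val, err = integrate.quad(lambda z: bp.null_density(z, 16.0), 0, 16)
        assert val == pytest.approx(1 - math.exp(-16), abs=1e-7)

    def test_nonpositive_truncation_errors(self):
        with pytest.raises(ValueError):
            bp.null_density(0.5, 0.0)
        with pytest.raises(ValueError):
            bp.null_cdf(0.5, -1.0)

    def test_cdf_boundaries_and_clamping(self):
        assert bp.null_cdf(0.0, 16.0) == 0.0
        assert bp.null_cdf(16.0, 16.0) == 1.0
        assert bp.null_cdf(-3.0, 16.0) == 0.0
        assert bp.null_cdf(20.0, 16.0) == 1.0

    def test_cdf_derivative_matches_density(self):
        U = 16.0
        grid = np.linspace(0.5, U - 0.5, 200)
        h = 1e-6
        num = (bp.null_cdf(grid + h, U) - bp.null_cdf(grid - h, U)) / (2 * h)
        assert np.max(np.abs(num - bp.null_density(grid, U))) < 1e-5


class TestSampler:
    def test_draws_match_closed_form_cdf(self):
        z = bp.sample_null(16.0, 100_000, seed=1)
        ks = stats.ks_1samp(z, lambda v: bp.null_cdf(v, 16.0))
        assert ks.statistic < 0.01

    def test_exp_of_draws_is_uniform_on_1_to_expU(self):
        U = 10.0
        n = 200_000
        x = np.exp(bp.sample_null(U, n, seed=2))
        lo, hi = 1.0, math.exp(U)
        mean, sd = (hi + lo) / 2, (hi - lo) / math.sqrt(12)
        assert abs(x.mean() - mean) < 3 * sd / math.sqrt(n)

    def test_reproducible_given_seed(self):
        a = bp.sample_null(16.0, 1000, seed=42)
        b = bp.sample_null(16.0, 1000, seed=42)
        np.testing.assert_array_equal(a, b)


class TestMixture:
    def test_equal_weight_parameterization_closed_form(self):
        mix = bp.MixtureNull(Us=np.array([15.0, 16.0, 17.0]),
                             weights=np.full(3, 1 / 3))
        expected = (1 + math.exp(-1) + math.exp(-2)) / 3
        assert mix.pdf(15.0) == pytest.approx(expected, abs=1e-9)

    def test_single_component_equals_plain_null(self):
        mix = bp.MixtureNull(Us=np.array([12.0]), weights=np.array([1.0]))
        grid = np.linspace(0, 12, 50)
        np.testing.assert_allclose(mix.pdf(grid), bp.null_density(grid, 12.0))

    def test_integrates_to_one_within_tolerance(self):
        mix = bp.MixtureNull(Us=np.array([15.0, 16.0, 17.0]),
                             weights=np.full(3, 1 / 3))
        val, err = integrate.quad(mix.pdf, 0, mix.max_U, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_built_from_flanking_intervals(self):
        flanks = [bp.FlankingInterval(a1=0.0, a2=2 * math.exp(k))
                  for k in (15, 16, 17)]
        mix = bp.mixture_from_genes(flanks)
        np.testing.assert_allclose(sorted(mix.Us), [15.0, 16.0, 17.0], atol=1e-12)
        assert mix.weights.sum() == pytest.approx(1.0)

    def test_degenerate_components_dropped_with_warning(self):
        flanks = [bp.FlankingInterval(a1=0.0, a2=2 * math.exp(16)),
                  bp.FlankingInterval(a1=5.0, a2=5.0, degenerate=True)]
        with pytest.warns(UserWarning, match="degenerate"):
            mix = bp.mixture_from_genes(flanks)
        assert len(mix.Us) == 1
        with pytest.raises(ValueError):
            bp.mixture_from_genes([bp.FlankingInterval(a1=1.0, a2=1.0)])


def brute_force_ks_statistic(a, b):
    """Max absolute ECDF difference by a double loop."""
    a, b = sorted(a), sorted(b)
    best = 0.0
    for t in a + b:
        fa = sum(v <= t for v in a) / len(a)
        fb = sum(v <= t for v in b) / len(b)
        best = max(best, abs(fa - fb))
    return best


class TestTwoSampleCompare:
    def test_identical_samples(self):
        z = list(np.linspace(1, 10, 50))
        res = bp.two_sample_compare(z, list(z))
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(5)
        z_rest = bp.sample_null(16.0, 10_000, seed=rng)
        z_de = np.clip(bp.sample_null(16.0, 250, seed=rng) - 5.0, 0, None)
        res = bp.two_sample_compare(z_de, z_rest)
        assert res.pvalue < 0.001

    def test_statistic_matches_brute_force_ecdf(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = rng.normal(size=rng.integers(5, 30)).tolist()
            b = rng.normal(size=rng.integers(5, 30)).tolist()
            res = bp.two_sample_compare(a, b)
            assert res.statistic == pytest.approx(brute_force_ks_statistic(a, b))

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="size < 5"):
            res = bp.two_sample_compare([1.0, 2.0], [1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.small_sample


class TestMonteCarlo:
    def _fixture(self, plant_at_zero=False):
        """A small genome: one chromosome, 3 regions, background genes plus
        5 DE genes, optionally planted touching a region boundary."""
        bprs = [bp.BreakpointRegion("chr1", s, s + 10_000, "macaque")
                for s in (5_000_000, 50_000_000, 95_000_000)]
        rng = np.random.default_rng(17)
        genes = []
        for i in range(200):
            s = int(rng.integers(0, 99_000_000))
            genes.append(bp.GeneRecord(f"BG{i:03d}", "chr1", s, s + 20_000))
        de_names = set()
        for k in range(5):
            name = f"DE{k}"
            de_names.add(name)
            if plant_at_zero:
                r = bprs[k % 3]
                # overlaps the region end; midpoint outside, so resampling
                # is free to move it away
                genes.append(bp.GeneRecord(name, "chr1", r.end - 1000, r.end + 30_000))
            else:
                s = int(rng.integers(0, 99_000_000))
                genes.append(bp.GeneRecord(name, "chr1", s, s + 20_000))
        return genes, bprs, de_names

    def test_all_de_at_zero_gives_minimal_p(self):
        genes, bprs, de_names = self._fixture(plant_at_zero=True)
        res = bp.monte_carlo_test(genes, de_names, bprs, n_sim=200, seed=3,
                                  chrom_lengths={"chr1": 100_000_000})
        assert res.observed_stat == 0.0
        assert res.pvalue == pytest.approx(1 / 201)

    def test_empty_de_set_errors(self):
        genes, bprs, _ = self._fixture()
        with pytest.raises(ValueError):
            bp.monte_carlo_test(genes, set(), bprs, n_sim=100, seed=1)

    def test_nsim_choice_consistent_within_monte_carlo_error(self):
        genes, bprs, de_names = self._fixture()
        p100 = bp.monte_carlo_test(genes, de_names, bprs, n_sim=100, seed=7,
                                   chrom_lengths={"chr1": 100_000_000}).pvalue
        p1000 = bp.monte_carlo_test(genes, de_names, bprs, n_sim=1000, seed=8,
                                    chrom_lengths={"chr1": 100_000_000}).pvalue
        se = math.sqrt(p1000 * (1 - p1000) / 100) + 0.02
        assert abs(p100 - p1000) < 4 * se

    def test_reproducible_given_seed(self):
        genes, bprs, de_names = self._fixture()
        r1 = bp.monte_carlo_test(genes, de_names, bprs, n_sim=150, seed=99)
        r2 = bp.monte_carlo_test(genes, de_names, bprs, n_sim=150, seed=99)
        assert r1.pvalue == r2.pvalue
        np.testing.assert_array_equal(r1.sim_stats, r2.sim_stats)

    def test_mean_statistic_available(self):
        genes, bprs, de_names = self._fixture()
        res = bp.monte_carlo_test(genes, de_names, bprs, n_sim=100, seed=5,
                                  statistic="mean")
        assert res.statistic == "mean"
        assert math.isfinite(res.observed_stat)
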