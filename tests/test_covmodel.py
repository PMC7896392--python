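"""Coverage-bias model: NB likelihood, fit selection, combination, bias sums."""

import numpy as np
import pytest
from scipy import stats as sps

from readsmith.covmodel import (
    BiasSum, CombinedBias, Dispersion, FlankParams, GCSpline, N_FLANK_POS,
    N_GC_BINS, N_KNOTS, all_sites, best_represented_bins, combine_fits,
    estimate_bias_sum, fit_gc_flank, fit_ref_len_bias, fits_per_sequence,
    gc_weights, interpolate_len_bias, l80, nb_loglik, renormalize_gc,
    sampled_lengths, select_fits, site_mu, weighted_median,
)
from readsmith.fixtures import TruthProfile, make_genome, simulate_site_counts
from readsmith.genome import Genome
from readsmith.stats import CountSummaries


class TestStructure:
    def test_flank_parameter_count(self):
        assert FlankParams().n_parameters == 120

    def test_free_parameters_per_fit(self):
        # 120 flank + 6 spline values + alpha + beta, normalisation absorbed
        assert FlankParams().n_parameters + N_KNOTS + 2 == 128

    def test_gc_bins_and_knots(self):
        assert N_GC_BINS == 101
        spline = GCSpline(np.array([0, 20, 40, 60, 80, 100]), np.zeros(6))
        assert len(spline.bias()) == 101
        assert len(spline.knots) == N_KNOTS == 6

    def test_spline_positive_and_constant_extrapolation(self):
        spline = GCSpline(np.array([10, 30, 50, 60, 80, 90]),
                          np.array([1.0, -2, 0.5, 0, 1, -1]))
        b = spline.bias()
        assert (b > 0).all()
        assert np.allclose(b[:11], b[0]) and np.allclose(b[90:], b[100])


class TestSiteMu:
    def test_neutral_biases(self):
        g = make_genome(0, [2000])
        sd = all_sites(g.codes("chr1"), 100, "chr1")
        mu = site_mu(sd, FlankParams(), np.ones(101), norm=3.0)
        np.testing.assert_allclose(mu, 3.0)

    def test_flank_sum_ln3_gives_1p5(self):
        g = make_genome(0, [2000])
        sd = all_sites(g.codes("chr1"), 100, "chr1")
        # give every (nucleotide, position 0) the same weight so any start
        # context sums to ln 3 at the first position and 0 elsewhere
        table = np.zeros((4, N_FLANK_POS))
        table[:, 0] = np.log(3)
        mu = site_mu(sd, FlankParams(table), np.ones(101), norm=1.0)
        # interior sites: both contexts contribute 2/(1 + e^{-ln 3}) = 1.5;
        # contexts running past the contig edge contribute neutrally
        np.testing.assert_allclose(mu[10:-10], 1.5 * 1.5)
        np.testing.assert_allclose(mu[0], 1.5)
        assert np.isclose(2 / (1 + np.exp(-np.log(3))), 1.5)

    def test_palindromic_context_start_equals_end(self):
        from readsmith.covmodel import flank_bias, site_features

        # a genome that is its own reverse complement around the fragment
        seq = "ACGT" * 500
        g = Genome.from_sequences([("s", seq)])
        starts = np.array([40])
        gc, fs, fe = site_features(g.codes("s"), 20, starts)
        rng = np.random.default_rng(1)
        flank = FlankParams(rng.normal(0, 0.5, size=(4, 30)))
        np.testing.assert_allclose(flank_bias(flank, fs), flank_bias(flank, fe))


class TestNbLoglik:
    def test_closed_form_pmf(self):
        # mu=2, alpha=1, beta=0 -> r=2, p=1/2, pmf(2) = 3 * 1/4 * 1/4
        ll = nb_loglik(np.array([2]), np.array([2.0]), 1.0, 0.0)
        assert np.isclose(np.exp(ll), 0.1875, atol=1e-12)

    def test_poisson_limit_zero_count(self):
        assert np.isclose(nb_loglik(np.array([0]), np.array([1.0]), 0, 0), -1.0)

    def test_poisson_limit_matches_scipy_to_1e10(self):
        rng = np.random.default_rng(0)
        mu = rng.uniform(0.1, 20, 200)
        k = rng.poisson(mu)
        ours = nb_loglik(k, mu, 0.0, 0.0)
        ref = sps.poisson.logpmf(k, mu).sum()
        assert abs(ours - ref) < 1e-10

    def test_matches_nbinom_oracle(self):
        rng = np.random.default_rng(1)
        mu = rng.uniform(0.5, 30, 100)
        k = rng.poisson(mu)
        alpha, beta = 0.7, 0.2
        r = mu / (alpha + beta * mu)
        ref = sps.nbinom.logpmf(k, r, r / (r + mu)).sum()
        assert abs(nb_loglik(k, mu, alpha, beta) - ref) < 1e-8

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            nb_loglik(np.array([1]), np.array([1.0]), -0.1, 0.0)

    def test_variance_relationship(self):
        d = Dispersion(0.5, 0.1)
        mu = np.array([1.0, 5.0, 20.0])
        np.testing.assert_allclose(d.variance(mu), mu + 0.5 * mu + 0.1 * mu**2)


def _genome_with_lengths(lengths):
    return make_genome(5, lengths)


class TestSelectFits:
    def _counts(self, genome, n_lengths=35):
        counts = {}
        for name in genome.names:
            for l in range(100, 100 + n_lengths):
                counts[(name, l)] = 100 - (l - 100)
        return counts

    def test_single_sequence_thirty_fits(self):
        g = _genome_with_lengths([50_000])
        plan = select_fits(g, self._counts(g))
        assert len(plan) == 30

    def test_seven_sequences_four_in_l80_sixty_fits(self):
        g = _genome_with_lengths([40_000, 39_000, 38_000, 37_000,
                                  2_000, 1_500, 1_000])
        assert len(l80(g)) == 4
        plan = select_fits(g, self._counts(g))
        assert len(plan) == 60

    def test_many_equal_sequences_five_each(self):
        # 25 equal sequences: the L80 needs the 20 longest, 5 fits apiece
        g = _genome_with_lengths([10_000] * 25)
        assert len(l80(g)) == 20
        plan = select_fits(g, self._counts(g))
        assert len(plan) == 100

    def test_schedule_anchors(self):
        assert fits_per_sequence(1) == 30
        assert fits_per_sequence(4) == 15
        assert fits_per_sequence(20) == 5
        assert fits_per_sequence(25) == 5

    def test_no_counts_raises(self):
        g = _genome_with_lengths([10_000])
        with pytest.raises(ValueError):
            select_fits(g, {})


class TestWeightedMedianAndCombine:
    def test_equal_weights_plain_median(self):
        assert weighted_median(np.array([1.0, 2.0, 9.0]), np.ones(3)) == 2.0

    def test_weighted_median_rule(self):
        # smallest value whose cumulative normalised weight reaches 0.5
        v = np.array([1.0, 2.0, 3.0])
        w = np.array([0.2, 0.3, 0.5])
        assert weighted_median(v, w) == 2.0

    def test_gc_weights_sum_to_one_and_decay(self):
        l_sites = np.zeros(101)
        l_sites[50] = 10_000
        w = gc_weights(l_sites)
        assert np.isclose(w.sum(), 1.0)
        assert w[50] > w[51] > w[52]
        assert np.isclose(w[51] / w[50], 0.1, rtol=1e-6)

    def _fit(self, gc_bias, alpha, beta, sites_per_gc=None):
        from readsmith.covmodel import FitResult

        return FitResult(
            "s", 100, FlankParams(), GCSpline(np.arange(6) * 20.0, np.zeros(6)),
            np.asarray(gc_bias, float), alpha, beta,
            np.ones(101) * 100 if sites_per_gc is None else sites_per_gc,
            True,
        )

    def test_single_fit_passthrough(self):
        fit = self._fit(np.linspace(0.5, 2, 101), 0.4, 0.1)
        combined = combine_fits([fit])
        np.testing.assert_allclose(combined.gc_bias, fit.gc_bias)
        assert combined.dispersion.alpha == 0.4

    def test_median_across_three_fits(self):
        fits = [self._fit(np.full(101, b), a, 0.0)
                for b, a in ((1.0, 0.1), (2.0, 0.2), (9.0, 0.9))]
        combined = combine_fits(fits)
        np.testing.assert_allclose(combined.gc_bias, 2.0)
        assert combined.dispersion.alpha == 0.2

    def test_no_converged_fits_raises(self):
        fit = self._fit(np.ones(101), 0, 0)
        fit.converged = False
        with pytest.raises(ValueError):
            combine_fits([fit])


class TestRenormalizeGC:
    def _fit(self, gc_bias, sites):
        from readsmith.covmodel import FitResult

        return FitResult("s", 100, FlankParams(),
                         GCSpline(np.arange(6) * 20.0, np.zeros(6)),
                         np.asarray(gc_bias, float), 0, 0,
                         np.asarray(sites, float), True)

    def test_single_populated_bin_becomes_one(self):
        sites = np.zeros(101)
        sites[40] = 100
        fit = renormalize_gc(self._fit(np.full(101, 7.0), sites))
        assert np.isclose(fit.gc_bias[40], 1.0)

    def test_two_equal_bins_divided_by_mean(self):
        sites = np.zeros(101)
        sites[[30, 60]] = 50
        bias = np.zeros(101)
        bias[30], bias[60] = 2.0, 4.0
        fit = renormalize_gc(self._fit(bias, sites))
        assert np.isclose(fit.gc_bias[30], 2 / 3)
        assert np.isclose(fit.gc_bias[60], 4 / 3)

    def test_idempotent(self):
        sites = np.ones(101) * 10
        fit = self._fit(np.linspace(0.5, 1.5, 101), sites)
        once = renormalize_gc(fit).gc_bias.copy()
        twice = renormalize_gc(fit).gc_bias
        np.testing.assert_allclose(once, twice)

    def test_best_represented_covers_80_percent(self):
        sites = np.arange(101, dtype=float)
        bins = best_represented_bins(sites)
        assert sites[bins].sum() >= 0.8 * sites.sum()
        # minimality: dropping the smallest selected bin goes below 80%
        smallest = bins[np.argmin(sites[bins])]
        rest = sites[bins].sum() - sites[smallest]
        assert rest < 0.8 * sites.sum()


class TestFitRecovery:
    """Parameter recovery on synthetic sites (reduced size; the acceptance
    suite runs the full-size multi-seed version)."""

    def test_planted_bias_recovery(self):
        g = make_genome(1, [60_000], gc=0.5)
        truth = TruthProfile.smooth(3, alpha=0.5, beta=0.1, norm=4.0)
        sd = simulate_site_counts(g, truth, 150, np.random.default_rng(5))
        fit = fit_gc_flank(sd, min_sites=5_000)
        assert fit is not None and fit.converged
        bins = best_represented_bins(fit.sites_per_gc)
        tg = truth.gc_bias() / truth.gc_bias()[bins].mean()
        mask = fit.sites_per_gc > 100
        corr = np.corrcoef(fit.gc_bias[mask], tg[mask])[0, 1]
        assert corr > 0.9
        rmse = np.sqrt(np.mean((fit.flank.table - truth.flank.table) ** 2))
        assert rmse < 0.1

    def test_too_few_sites_skipped(self):
        g = make_genome(1, [3_000])
        truth = TruthProfile(norm=2.0)
        sd = simulate_site_counts(g, truth, 150, np.random.default_rng(0))
        assert fit_gc_flank(sd, min_sites=100_000) is None

    def test_all_zero_counts_skipped(self):
        g = make_genome(1, [30_000])
        sd = all_sites(g.codes("chr1"), 150, "chr1", both_strands=True)
        assert fit_gc_flank(sd, min_sites=1_000) is None


class TestBiasSums:
    def test_neutral_sum_counts_sites_both_strands(self):
        g = make_genome(2, [5_000])
        combined = CombinedBias(FlankParams(), np.ones(101), Dispersion())
        from readsmith.covmodel import exact_bias_sum

        L, ell = 5_000, 200
        s, _mx = exact_bias_sum(g, combined, ell)["chr1"]
        assert np.isclose(s, 2 * (L - ell + 1))

    def test_sample_spacing_twenty(self):
        counts = {l: 5 for l in range(103, 400)}
        s = sampled_lengths(counts)
        assert s[0] == 103
        assert np.all(np.diff(s) == 20)

    def test_sampling_continues_past_zero_for_heavy_lengths(self):
        counts = {100: 50, 120: 0, 140: 50}
        s = sampled_lengths(counts)
        assert list(s) == [100, 120, 140]
        counts2 = {100: 50, 120: 0, 140: 5}
        assert list(sampled_lengths(counts2)) == [100]

    def test_spline_estimates_close_to_exact(self):
        g = make_genome(3, [20_000], gc=0.5)
        truth = TruthProfile.smooth(4, alpha=0, beta=0)
        combined = CombinedBias(truth.flank, truth.gc_bias(), Dispersion(),
                                {"chr1": 1.0}, {})
        counts = {l: 10 for l in range(100, 301)}
        combined.b_len = {l: 1.0 for l in range(100, 301)}
        bs = estimate_bias_sum(combined, g, counts, mode="simulation")
        from readsmith.covmodel import exact_bias_sum

        for l in (110, 175, 260):
            exact, _ = exact_bias_sum(g, combined, l)["chr1"]
            assert abs(bs.sum_by_len[l] - exact) / exact < 0.02


class TestRefLenBias:
    def _bias_sum(self, refs, lens, value):
        return BiasSum(np.array(lens),
                       {r: np.full(len(lens), value) for r in refs})

    def test_single_cell_closed_form(self):
        cs = CountSummaries({"s": 500.0}, {100: 500}, 500)
        bs = self._bias_sum(["s"], [100], 25.0)
        b_ref, b_len = fit_ref_len_bias(cs, bs)
        # product must satisfy c = b_ref * b_len * S; scale puts b_len at 1
        assert np.isclose(b_ref["s"] * b_len[100] * 25.0, 500.0)
        assert np.isclose(b_len[100], 1.0)

    def test_fixed_point_satisfies_both_equations(self):
        rng = np.random.default_rng(8)
        refs = ["a", "b", "c"]
        lens = [100, 120, 140, 160]
        S = {r: rng.uniform(10, 50, size=4) for r in refs}
        bs = BiasSum(np.array(lens), S)
        # compatible totals (sum of per-sequence counts equals the sum of
        # per-length counts), as produced by real pair counting
        c_len = {l: int(rng.integers(100, 700)) for l in lens}
        total = sum(c_len.values())
        split = rng.dirichlet(np.ones(3)) * total
        cs = CountSummaries({r: float(s) for r, s in zip(refs, split)},
                            c_len, total)
        b_ref, b_len = fit_ref_len_bias(cs, bs)
        bl = np.array([b_len[l] for l in lens])
        for r in refs:
            denom = float(np.sum(bl * S[r]))
            assert np.isclose(b_ref[r], cs.c_ref[r] / denom, rtol=1e-5)

    def test_zero_count_sequence_gets_zero_bias(self):
        cs = CountSummaries({"a": 400.0, "b": 0.0}, {100: 400}, 400)
        bs = self._bias_sum(["a", "b"], [100], 30.0)
        b_ref, _ = fit_ref_len_bias(cs, bs)
        assert b_ref["b"] == 0.0

    def test_interpolation_extends_sampled_biases(self):
        counts = {l: 100 for l in range(100, 200)}
        sampled = {l: 2.0 for l in range(100, 200, 20)}
        full = interpolate_len_bias(sampled, counts)
        assert set(full) == set(counts)
        for l, b in full.items():
            assert np.isclose(b, 2.0, rtol=1e-6)
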