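import numpy as np
import pytest

from sdsreg import (
    Grm,
    PhenotypePanel,
    ar1_grm,
    bin_pairs,
    binned_regression,
    bootstrap_ci,
    estimate_ritland_unbinned,
    estimate_sds1,
    estimate_sds2,
    pair_table,
)
from sdsreg.estimators import _ols
from sdsreg.similarity import PairSimilarityTable, vech_pair_indices


def _table_from_theta(theta_hat, values, index="s"):
    """Synthetic pair table with a prescribed index, bypassing phenotypes."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    npairs = theta_hat.size
    # n chosen so the pair count is at least npairs; bookkeeping fields only
    n = int(np.ceil((1 + np.sqrt(1 + 8 * npairs)) / 2))
    zeros = np.zeros(npairs)
    fields = dict(s=zeros, d=zeros, s_std=zeros)
    fields[index] = np.asarray(values, dtype=float)
    return PairSimilarityTable(
        i_idx=np.arange(npairs),
        j_idx=np.arange(npairs),
        theta_hat=theta_hat,
        s=fields["s"],
        d=fields["d"],
        s_std=fields["s_std"],
        sigma2_p=1.0,
        n=n,
    )


def _ols_oracle(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    return y.mean() - slope * x.mean(), slope


class TestBinPairs:
    def test_single_bin_holds_everything(self):
        t = _table_from_theta([0.1, 0.4, 0.9], [1.0, 2.0, 3.0])
        bins = bin_pairs(t, index="s", n_bins=1)
        assert bins.counts.tolist() == [3]
        assert bins.theta_mean[0] == pytest.approx(np.mean([0.1, 0.4, 0.9]))
        assert bins.index_mean[0] == pytest.approx(2.0)

    def test_interior_edge_tie_goes_up(self):
        # edges (0.1, 0.5, 0.9): the 0.5 value belongs to the upper bin
        t = _table_from_theta([0.1, 0.5, 0.9], [1.0, 2.0, 3.0])
        bins = bin_pairs(t, index="s", n_bins=2, range_mode="data")
        assert bins.counts.tolist() == [1, 2]
        assert bins.index_mean[1] == pytest.approx(2.5)

    def test_maximum_lands_in_last_bin(self):
        t = _table_from_theta([0.0, 1.0], [5.0, 7.0])
        bins = bin_pairs(t, index="s", n_bins=4, range_mode="unit")
        assert bins.counts[-1] == 1
        assert bins.index_mean[-1] == pytest.approx(7.0)

    def test_unit_range_clips_outliers_into_end_bins(self):
        # -0.3 clips into the first bin, 1.4 into the last; the interior
        # edge value 0.5 goes to the upper bin
        t = _table_from_theta([-0.3, 0.5, 1.4], [1.0, 2.0, 3.0])
        bins = bin_pairs(t, index="s", n_bins=2, range_mode="unit")
        assert bins.counts.tolist() == [1, 2]
        # means use the actual (unclipped) relatedness values
        assert bins.theta_mean[0] == pytest.approx(-0.3)
        assert bins.theta_mean[1] == pytest.approx((0.5 + 1.4) / 2)

    @pytest.mark.parametrize("n_bins", [1, 2, 7, 100])
    def test_counts_conserve_pairs(self, rng, n_bins):
        theta = rng.uniform(-0.2, 1.1, size=300)
        t = _table_from_theta(theta, rng.standard_normal(300))
        for mode in ("data", "unit"):
            bins = bin_pairs(t, index="s", n_bins=n_bins, range_mode=mode)
            assert bins.counts.sum() == 300

    def test_degenerate_constant_theta_errors(self):
        t = _table_from_theta([0.5, 0.5, 0.5], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="identical"):
            bin_pairs(t, index="s", n_bins=10, range_mode="data")


class TestBinnedRegression:
    def test_exact_linearity(self):
        t = _table_from_theta(np.linspace(0, 1, 50), 2.0 * np.linspace(0, 1, 50))
        bins = bin_pairs(t, index="s", n_bins=5)
        intercept, slope = binned_regression(bins)
        assert slope == pytest.approx(2.0, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_oracle(self, rng):
        theta = rng.uniform(0, 1, size=200)
        vals = rng.standard_normal(200)
        t = _table_from_theta(theta, vals)
        bins = bin_pairs(t, index="s", n_bins=5)
        occ = bins.occupied
        exp_int, exp_slope = _ols_oracle(bins.theta_mean[occ], bins.index_mean[occ])
        intercept, slope = binned_regression(bins)
        assert slope == pytest.approx(exp_slope, abs=1e-12)
        assert intercept == pytest.approx(exp_int, abs=1e-12)

    @pytest.mark.parametrize("n_bins", [2, 3, 10, 1000])
    @pytest.mark.parametrize("mode", ["data", "unit"])
    def test_affine_index_is_binning_invariant(self, rng, n_bins, mode):
        # index exactly affine in theta => every binning recovers the truth
        theta = rng.uniform(0.05, 0.95, size=400)
        t = _table_from_theta(theta, 0.7 * theta + 0.1)
        bins = bin_pairs(t, index="s", n_bins=n_bins, range_mode=mode)
        intercept, slope = binned_regression(bins)
        assert slope == pytest.approx(0.7, abs=1e-10)
        assert intercept == pytest.approx(0.1, abs=1e-10)


class TestSds2:
    def test_unbinned_matches_closed_form(self, aligned_panel_grm):
        panel, grm = aligned_panel_grm
        t = pair_table(panel, grm)
        exp_int, exp_slope = _ols_oracle(t.theta_hat, t.s)
        est = estimate_ritland_unbinned(panel, grm)
        assert est.sigma2_a == pytest.approx(exp_slope, abs=1e-12)
        assert est.intercept == pytest.approx(exp_int, abs=1e-12)
        assert est.h2 == pytest.approx(exp_slope / panel.y.var(ddof=1), abs=1e-10)

    def test_h2_routes_consistent(self, aligned_panel_grm):
        panel, grm = aligned_panel_grm
        est = estimate_sds2(panel, grm, n_bins=50)
        assert est.h2 == pytest.approx(est.sigma2_a / est.sigma2_p, abs=1e-10)
        assert est.method == "sds2_binned"

    def test_per_value_bins_reproduce_unbinned(self):
        # distinct well-separated relatedness values, one per fine bin:
        # the bin means ARE the raw points, so both fits coincide exactly
        n = 6
        i_idx, j_idx = vech_pair_indices(n)
        theta = np.eye(n)
        vals = np.round(np.linspace(0.05, 0.95, i_idx.size), 2)
        theta[i_idx, j_idx] = vals
        theta[j_idx, i_idx] = vals
        grm = Grm(theta=theta, sample_ids=[f"i{k}" for k in range(n)])
        rng = np.random.default_rng(3)
        panel = PhenotypePanel(y=rng.standard_normal(n), sample_ids=list(grm.sample_ids))
        binned = estimate_sds2(panel, grm, n_bins=100, range_mode="unit")
        unbinned = estimate_ritland_unbinned(panel, grm)
        assert binned.sigma2_a == pytest.approx(unbinned.sigma2_a, abs=1e-12)
        assert binned.h2 == pytest.approx(unbinned.h2, abs=1e-12)

    def test_constant_trait_rejected(self):
        grm = ar1_grm(5, 0.8)
        panel = PhenotypePanel(y=np.ones(5), sample_ids=list(grm.sample_ids))
        with pytest.raises(ValueError, match="variance"):
            estimate_sds2(panel, grm)

    def test_no_clamping_high_h2_small_n(self):
        # heritable trait, tiny sample: some replicate estimates must
        # exceed 1 and be reported unmodified
        from sdsreg import SimConfig, grm_from_genotypes, simulate

        above = 0
        for seed in range(40):
            out = simulate(SimConfig(n=60, m=100, h2=0.8, seed=seed))
            grm = grm_from_genotypes(out.genotypes)
            h2 = estimate_sds2(out.y, grm, n_bins=100).h2
            above += h2 > 1.0
        assert above > 0


class TestSds1:
    def test_constant_trait_zero_fit(self):
        grm = ar1_grm(5, 0.8)
        panel = PhenotypePanel(y=np.full(5, 2.0), sample_ids=list(grm.sample_ids))
        est = estimate_sds1(panel, grm, binned=False)
        assert est.sigma2_a == pytest.approx(0.0, abs=1e-15)
        assert est.intercept == pytest.approx(0.0, abs=1e-15)
        assert not est.h2_valid

    def test_sign_convention(self, aligned_panel_grm):
        panel, grm = aligned_panel_grm
        est = estimate_sds1(panel, grm, binned=False)
        t = pair_table(panel, grm)
        _, slope = _ols_oracle(t.theta_hat, t.d)
        assert est.sigma2_a == pytest.approx(-slope, abs=1e-12)
        assert est.sigma2_p == pytest.approx(est.intercept, abs=1e-15)

    def test_doubled_convention_doubles_intercept(self, aligned_panel_grm):
        # with the raw squared difference the regression intercept
        # estimates twice the phenotypic variance
        panel, grm = aligned_panel_grm
        t_half = pair_table(panel, grm, half_difference=True)
        t_raw = pair_table(panel, grm, half_difference=False)
        int_half, slope_half = _ols_oracle(t_half.theta_hat, t_half.d)
        int_raw, slope_raw = _ols_oracle(t_raw.theta_hat, t_raw.d)
        assert int_raw == pytest.approx(2 * int_half, abs=1e-10)
        assert slope_raw == pytest.approx(2 * slope_half, abs=1e-10)


class TestBootstrap:
    def test_constant_estimator_degenerates(self, aligned_panel_grm):
        panel, grm = aligned_panel_grm
        res = bootstrap_ci(panel, grm, B=10, estimator=lambda p, g: 0.42, seed=1)
        assert res.sd == pytest.approx(0.0, abs=1e-12)
        assert res.ci95[0] == pytest.approx(0.42)
        assert res.ci95[1] == pytest.approx(0.42)

    def test_resample_sizes_track_unique_fraction(self, rng):
        from conftest import random_grm

        n = 200
        grm = random_grm(n, rng)
        panel = PhenotypePanel(y=rng.standard_normal(n), sample_ids=list(grm.sample_ids))
        res = bootstrap_ci(panel, grm, B=30, estimator=lambda p, g: p.n, seed=1)
        sizes = np.array(res.resample_sizes)
        assert (sizes < n).all()  # duplicates virtually certain at n=200
        # expected unique fraction 1 - 1/e
        assert sizes.mean() / n == pytest.approx(1 - np.exp(-1), abs=0.02)

    def test_sds_estimates_not_truncated(self, rng):
        # a pure-noise trait yields negative resample estimates which must
        # survive into the CI untouched
        from conftest import random_grm

        n = 60
        grm = random_grm(n, rng)
        panel = PhenotypePanel(y=rng.standard_normal(n), sample_ids=list(grm.sample_ids))
        res = bootstrap_ci(panel, grm, B=50, estimator="ritland", seed=2)
        assert (res.estimates < 0).any()
        assert res.ci95[0] < 0

    def test_majority_failures_error(self, aligned_panel_grm):
        panel, grm = aligned_panel_grm

        def broken(p, g):
            raise ValueError("boom")

        with pytest.raises(RuntimeError, match="failed"):
            bootstrap_ci(panel, grm, B=8, estimator=broken, seed=1)


def test_ols_zero_variance_regressor_errors():
    with pytest.raises(ValueError, match="variance"):
        _ols(np.ones(5), np.arange(5.0))
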