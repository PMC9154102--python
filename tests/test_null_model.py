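"""Empirical null estimation: permutation, fits, adjustment, transforms."""

import numpy as np
import pytest
from scipy import stats

from cbea import (
    CompositionTable,
    SetCollection,
    build_null,
    cbea,
    closure,
    fit_mixture2,
    fit_normal,
    permute_taxa,
    replace_zeros,
    score_matrix,
    transform,
)
from cbea.core import InvalidInputError
from cbea.null_model import (
    DegenerateFitError,
    Mixture2Params,
    NormalParams,
    pooled_permutation_scores,
)


@pytest.fixture
def sim_table():
    """Medium global-null table of iid overdispersed counts, zero-free."""
    rng = np.random.default_rng(99)
    counts = rng.negative_binomial(2, 2 / 102, size=(60, 40)).astype(float) + 1.0
    t = CompositionTable(counts, tuple(f"s{i}" for i in range(60)),
                         tuple(f"t{j}" for j in range(40)))
    return closure(t)


@pytest.fixture
def sim_sets(sim_table):
    memb = np.zeros((40, 2), dtype=int)
    memb[:10, 0] = 1
    memb[10:25, 1] = 1
    return SetCollection(memb, ("a", "b"), sim_table.taxon_ids)


class TestPermuteTaxa:
    def test_identity_permutation_exists(self, toy_table):
        # some seed maps to the identity on 5 columns; find one and check no-op
        for seed in range(2000):
            if np.array_equal(np.random.default_rng(seed).permutation(5),
                              np.arange(5)):
                out = permute_taxa(toy_table, seed)
                np.testing.assert_array_equal(out.values, toy_table.values)
                return
        pytest.fail("no identity permutation found in seed range")

    def test_row_sums_preserved(self, toy_table):
        out = permute_taxa(toy_table, 123)
        np.testing.assert_allclose(out.values.sum(axis=1),
                                   toy_table.values.sum(axis=1), rtol=1e-12)

    def test_deterministic(self, toy_table):
        a = permute_taxa(toy_table, 7)
        b = permute_taxa(toy_table, 7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_fixed_set_on_permuted_equals_permuted_set_on_original(self):
        """5x6 toy check of the permutation/membership duality."""
        rng = np.random.default_rng(1)
        vals = rng.dirichlet(np.ones(6), size=5)
        t = CompositionTable(vals, tuple(f"s{i}" for i in range(5)),
                             tuple(f"t{j}" for j in range(6)))
        seed = 31
        perm = np.random.default_rng(seed).permutation(6)
        pt = permute_taxa(t, seed)
        idx = np.array([0, 2, 3])
        memb = np.zeros((6, 1), dtype=int)
        memb[idx, 0] = 1
        sets = SetCollection(memb, ("k",), t.taxon_ids)
        memb2 = np.zeros((6, 1), dtype=int)
        memb2[perm[idx], 0] = 1
        sets2 = SetCollection(memb2, ("k",), t.taxon_ids)
        np.testing.assert_allclose(score_matrix(pt, sets).values,
                                   score_matrix(t, sets2).values, rtol=1e-12)


class TestFitNormal:
    def test_forced_by_mle_formula(self):
        par = fit_normal([-1.0, 1.0])
        assert par.mu == pytest.approx(0.0, abs=1e-15)
        assert par.sigma == pytest.approx(1.0, rel=1e-12)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        a, b = fit_normal(x), fit_normal(x + 5.0)
        assert b.mu == pytest.approx(a.mu + 5.0, abs=1e-9)
        assert b.sigma == pytest.approx(a.sigma, rel=1e-12)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(3)
        n = 10_000
        x = rng.normal(2.0, 3.0, size=n)
        par = fit_normal(x)
        assert abs(par.mu - 2.0) < 3 * 3.0 / np.sqrt(n)
        assert abs(par.sigma - 3.0) < 3 * 3.0 / np.sqrt(2 * n)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_normal([1.0, 1.0, 1.0])


class TestFitMixture2:
    def test_single_gaussian_data(self):
        """On data from one Gaussian the mixture CDF hugs the true CDF."""
        rng = np.random.default_rng(4)
        x = rng.normal(1.0, 2.0, size=5000)
        fit = fit_mixture2(x, seed=0)
        grid = np.linspace(x.min(), x.max(), 512)
        sup = np.max(np.abs(fit.cdf(grid) - stats.norm.cdf(grid, 1.0, 2.0)))
        assert sup < 0.02

    def test_well_separated_recovery(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(-3, 1, 2500), rng.normal(3, 1, 2500)])
        fit = fit_mixture2(x, seed=0)
        assert fit.mu1 == pytest.approx(-3.0, abs=0.2)
        assert fit.mu2 == pytest.approx(3.0, abs=0.2)
        assert fit.w1 == pytest.approx(0.5, abs=0.05)

    def test_ordering_invariant_to_seed(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(-3, 1, 1000), rng.normal(3, 1, 1000)])
        fits = [fit_mixture2(x, seed=s) for s in (0, 1, 2)]
        for f in fits:
            assert f.mu1 <= f.mu2
            assert f.mu1 == pytest.approx(fits[0].mu1, abs=0.1)

    def test_loglik_at_least_single_normal(self):
        # nested model: the mixture MLE can never fall below the normal MLE
        rng = np.random.default_rng(7)
        x = rng.gamma(3.0, 1.0, size=3000)
        fit = fit_mixture2(x, seed=0)
        par = fit_normal(x)
        ll_norm = stats.norm.logpdf(x, par.mu, par.sigma).sum()
        assert fit.loglik >= ll_norm - 1e-6

    def test_matches_sklearn_em(self):
        """Independent EM implementation reaches the same optimum."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(-2, 0.5, 1500), rng.normal(1, 1.5, 1500)])
        ours = fit_mixture2(x, seed=0)
        gm = GaussianMixture(2, n_init=3, random_state=0, tol=1e-6,
                             max_iter=1000).fit(x.reshape(-1, 1))
        order = np.argsort(gm.means_.ravel())
        means = gm.means_.ravel()[order]
        weights = gm.weights_[order]
        assert ours.mu1 == pytest.approx(means[0], abs=0.05)
        assert ours.mu2 == pytest.approx(means[1], abs=0.05)
        assert ours.w1 == pytest.approx(weights[0], abs=0.02)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_mixture2([np.nan] * 20)


class TestBuildNull:
    def test_unadjusted_normal_is_pooled_fit(self, sim_table, sim_sets):
        null = build_null(sim_table, sim_sets, family="normal", adjust=False,
                          n_perm=5, seed=11)
        pooled = pooled_permutation_scores(sim_table, sim_sets, 5, 11)
        for k in range(2):
            ref = fit_normal(pooled[:, k])
            assert null.params[k].mu == pytest.approx(ref.mu, rel=1e-12)
            assert null.params[k].sigma == pytest.approx(ref.sigma, rel=1e-12)

    def test_independent_taxa_adjustment_is_neutral(self, sim_table, sim_sets):
        un = build_null(sim_table, sim_sets, family="normal", adjust=False,
                        n_perm=30, seed=12)
        ad = build_null(sim_table, sim_sets, family="normal", adjust=True,
                        n_perm=30, seed=12)
        for k in range(2):
            assert ad.params[k].mu == pytest.approx(un.params[k].mu, rel=1e-12)
            # spreads agree up to Monte-Carlo error when taxa are independent
            assert abs(np.log(ad.params[k].sigma / un.params[k].sigma)) < 0.35

    def test_deterministic_given_seed(self, sim_table, sim_sets):
        a = build_null(sim_table, sim_sets, family="normal", n_perm=3, seed=5)
        b = build_null(sim_table, sim_sets, family="normal", n_perm=3, seed=5)
        assert a.params == b.params

    def test_requires_positive_table(self, count_table, sim_sets):
        memb = np.zeros((8, 1), dtype=int)
        memb[:3, 0] = 1
        sets = SetCollection(memb, ("x",), count_table.taxon_ids)
        with pytest.raises(InvalidInputError):
            build_null(count_table, sets, family="normal", n_perm=2, seed=0)


class TestTransform:
    @pytest.fixture
    def raw_and_null(self, sim_table, sim_sets):
        raw = score_matrix(sim_table, sim_sets)
        null = build_null(sim_table, sim_sets, family="normal", n_perm=10, seed=21)
        return raw, null

    def test_raw_passthrough(self, raw_and_null):
        raw, _ = raw_and_null
        out = transform(raw, None, "raw")
        np.testing.assert_array_equal(out.values, raw.values)

    def test_score_at_null_mean(self, raw_and_null):
        raw, null = raw_and_null
        x = np.full_like(raw.values, np.nan)
        for k, par in enumerate(null.params):
            x[:, k] = par.mu
        from cbea import ScoreMatrix

        at_mu = ScoreMatrix(x, raw.sample_ids, raw.set_names)
        assert np.allclose(transform(at_mu, null, "cdf").values, 0.5, atol=1e-12)
        assert np.allclose(transform(at_mu, null, "zscore").values, 0.0, atol=1e-9)
        assert np.allclose(transform(at_mu, null, "pval").values, 0.5, atol=1e-12)

    def test_pval_is_one_minus_cdf(self, raw_and_null):
        raw, null = raw_and_null
        c = transform(raw, null, "cdf").values
        p = transform(raw, null, "pval").values
        np.testing.assert_allclose(p, 1.0 - c, atol=1e-12)

    def test_strictly_monotone_in_raw_score(self, sim_table, sim_sets):
        from cbea import ScoreMatrix

        null = build_null(sim_table, sim_sets, family="mixture2", n_perm=10, seed=22)
        rng = np.random.default_rng(0)
        a = np.sort(rng.normal(0, 3, size=(50, 2)), axis=0)
        sm = ScoreMatrix(a, tuple(f"s{i}" for i in range(50)), sim_sets.set_names)
        c = transform(sm, null, "cdf").values
        assert np.all(np.diff(c, axis=0) > 0)

    def test_output_types_agree_in_rank(self, sim_table, sim_sets):
        raw = score_matrix(sim_table, sim_sets)
        null = build_null(sim_table, sim_sets, family="mixture2", n_perm=10, seed=23)
        ranks = stats.rankdata(raw.values, axis=0)
        for ot in ("cdf", "zscore"):
            out = transform(raw, null, ot).values
            np.testing.assert_array_equal(stats.rankdata(out, axis=0), ranks)
        pv = transform(raw, null, "pval").values
        np.testing.assert_array_equal(stats.rankdata(-pv, axis=0), ranks)

    def test_missing_null_rejected(self, raw_and_null):
        raw, _ = raw_and_null
        with pytest.raises(InvalidInputError):
            transform(raw, None, "cdf")


class TestNullSelfConsistency:
    @pytest.mark.parametrize("par", [
        NormalParams(0.3, 1.7),
        Mixture2Params(0.4, -2.0, 0.8, 0.6, 1.0, 1.5),
    ], ids=["normal", "mixture2"])
    def test_cdf_of_own_samples_is_uniform(self, par):
        rng = np.random.default_rng(33)
        x = par.rvs(5000, rng)
        u = par.cdf(x)
        d = stats.kstest(u, "uniform").statistic
        assert d < 0.03


class TestEndToEnd:
    def test_raw_output_equals_score_matrix(self, count_table):
        memb = np.zeros((8, 2), dtype=int)
        memb[:3, 0] = 1
        memb[3:6, 1] = 1
        sets = SetCollection(memb, ("x", "y"), count_table.taxon_ids)
        res = cbea(count_table, sets, output_type="raw")
        ref = score_matrix(closure(replace_zeros(count_table)), sets)
        np.testing.assert_array_equal(res.values, ref.values)
        assert res.null_model is None

    def test_bit_identical_across_runs(self, count_table):
        memb = np.zeros((8, 1), dtype=int)
        memb[:4, 0] = 1
        sets = SetCollection(memb, ("x",), count_table.taxon_ids)
        a = cbea(count_table, sets, family="normal", output_type="pval",
                 n_perm=5, seed=9)
        b = cbea(count_table, sets, family="normal", output_type="pval",
                 n_perm=5, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_cdf_bounds(self, sim_table, sim_sets):
        res = cbea(sim_table, sim_sets, family="normal", output_type="cdf",
                   n_perm=5, seed=13)
        assert res.values.min() >= 0.0 and res.values.max() <= 1.0
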