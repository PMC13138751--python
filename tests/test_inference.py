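"""Sampler correctness against conjugate closed forms, phylogenetic signal,
Bayesian R^2, convergence diagnostics and species-level estimates."""

import numpy as np
import pandas as pd
import pytest

from phylohand.data import CovariateTransform, ModelFrame
from phylohand.diagnostics import ess, rhat
from phylohand.model import PhyloMetaModel
from phylohand.trees import PhyloCov


def make_frame(y, se, X=None, species=None, studies=None, colnames=None):
    K = len(y)
    y, se = np.asarray(y, float), np.asarray(se, float)
    X = np.ones((K, 1)) if X is None else np.asarray(X, float)
    species = species if species is not None else [f"S{i}" for i in range(K)]
    sp_unique = list(dict.fromkeys(species))
    sp_idx = np.array([sp_unique.index(s) for s in species])
    studies = studies if studies is not None else [f"st{i}" for i in range(K)]
    st_unique = list(dict.fromkeys(studies))
    st_idx = np.array([st_unique.index(s) for s in studies])
    # species design: first record's row per species
    sp_design = np.vstack([X[sp_idx == i][0] for i in range(len(sp_unique))])
    return ModelFrame(
        response="MHI", y=y, se=se, X=X,
        colnames=colnames or [f"c{j}" for j in range(X.shape[1])],
        species=sp_unique, species_idx=sp_idx,
        studies=st_unique, study_idx=st_idx,
        species_design=sp_design, transform=CovariateTransform(),
        records=pd.DataFrame({"species": species}),
    )


class TestConjugateOracles:
    def test_intercept_posterior_is_inverse_variance_weighted_mean(self):
        """With all variance components pinned at zero and a flat-ish prior,
        the intercept posterior is the closed-form precision-weighted Normal."""
        rng = np.random.default_rng(0)
        K = 15
        se = rng.uniform(0.05, 0.3, K)
        y = 0.3 + se * rng.standard_normal(K)
        frame = make_frame(y, se)
        m = PhyloMetaModel(frame, PhyloCov(frame.species, np.eye(K)),
                           prior_beta_sd=100.0)
        res = m.fit(chains=2, iterations=4000, warmup=500, seed=2,
                    fixed={"sigma_p": 0, "sigma_s": 0, "tau": 0})
        w = 1 / se**2
        post_prec = w.sum() + 1 / 100.0**2
        post_mean = (w * y).sum() / post_prec
        post_sd = 1 / np.sqrt(post_prec)
        b = res.beta[:, 0]
        # Gibbs draws here are iid, so MC error ~ sd/sqrt(n)
        mcse = post_sd / np.sqrt(len(b))
        assert abs(b.mean() - post_mean) < 3 * mcse
        assert b.std(ddof=1) == pytest.approx(post_sd, rel=0.05)

    def test_ridge_regression_closed_form(self):
        """Identity C, one precise record per species: posterior mean of beta
        matches the ridge (Gaussian prior) closed form."""
        rng = np.random.default_rng(1)
        K = 25
        X = np.column_stack([np.ones(K), rng.standard_normal(K)])
        beta_true = np.array([0.2, 0.4])
        se = np.full(K, 0.05)
        y = X @ beta_true + se * rng.standard_normal(K)
        frame = make_frame(y, se, X=X, colnames=["intercept", "x"])
        m = PhyloMetaModel(frame, PhyloCov(frame.species, np.eye(K)))
        res = m.fit(chains=2, iterations=4000, warmup=500, seed=3,
                    fixed={"sigma_p": 0, "sigma_s": 0, "tau": 0})
        W = np.diag(1 / se**2)
        prec = X.T @ W @ X + np.eye(2)
        closed = np.linalg.solve(prec, X.T @ W @ y)
        closed_sd = np.sqrt(np.diag(np.linalg.inv(prec)))
        mc = res.beta.mean(axis=0)
        mcse = closed_sd / np.sqrt(res.beta.shape[0])
        assert np.all(np.abs(mc - closed) < 3 * mcse)

    def test_inflating_se_does_not_shrink_uncertainty(self):
        rng = np.random.default_rng(4)
        K = 12
        se = rng.uniform(0.05, 0.2, K)
        y = 0.2 + se * rng.standard_normal(K)
        sds = []
        for factor in (1.0, 10.0):
            frame = make_frame(y, se * factor)
            m = PhyloMetaModel(frame, PhyloCov(frame.species, np.eye(K)))
            res = m.fit(chains=2, iterations=1500, warmup=500, seed=5,
                        fixed={"sigma_p": 0, "sigma_s": 0, "tau": 0})
            sds.append(res.beta[:, 0].std())
        assert sds[1] > sds[0]


class TestLynchH2:
    def test_equal_variances_give_one_third(self, fitted):
        res = fitted
        h2 = res.lynch_h2()
        # direct identity on the draws rather than a refit
        manual = res.sigma_p**2 / (res.sigma_p**2 + res.sigma_s**2 + res.tau**2)
        np.testing.assert_allclose(h2, manual)
        assert ((h2 >= 0) & (h2 <= 1)).all()

    def test_excluding_tau_option(self, fitted):
        h2a = fitted.lynch_h2(include_tau=True)
        h2b = fitted.lynch_h2(include_tau=False)
        assert (h2b >= h2a - 1e-12).all()

    def test_limits(self):
        # algebraic limits of the per-draw formula
        assert 1.0 / (1.0 + 1.0 + 1.0) == pytest.approx(1 / 3)


class TestBayesR2:
    def test_intercept_only_fixed_r2_zero(self, sim_world):
        cfg, tree, records, traits, truth = sim_world
        m = PhyloMetaModel.from_data(records, traits, tree, [], "MHI")
        res = m.fit(chains=2, iterations=800, warmup=300, seed=6)
        r2 = res.bayes_r2("fixed_only")
        assert np.all(r2 < 1e-10)

    def test_noiseless_conditional_r2_near_one(self):
        rng = np.random.default_rng(7)
        K = 20
        X = np.column_stack([np.ones(K), rng.standard_normal(K)])
        y = X @ np.array([0.1, 0.5])
        se = np.full(K, 1e-4)
        frame = make_frame(y, se, X=X, colnames=["intercept", "x"])
        m = PhyloMetaModel(frame, PhyloCov(frame.species, np.eye(K)))
        res = m.fit(chains=2, iterations=1000, warmup=300, seed=8,
                    fixed={"sigma_p": 0, "sigma_s": 0, "tau": 0})
        assert res.bayes_r2("conditional").mean() > 0.999

    def test_single_record_rejected(self):
        frame = make_frame([0.1], [0.1])
        m = PhyloMetaModel(frame, PhyloCov(frame.species, np.eye(1)))
        res = m.fit(chains=2, iterations=200, warmup=50, seed=9,
                    fixed={"sigma_p": 0, "sigma_s": 0, "tau": 0})
        with pytest.raises(ValueError, match="fewer than 2"):
            res.bayes_r2()


class TestDiagnostics:
    def test_identical_iid_chains_rhat_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((2, 4000))
        assert rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_offset_chains_rhat_large(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((2, 1000))
        chains[1] += 10
        assert rhat(chains) > 1.5

    def test_rhat_matches_direct_formula_oracle(self):
        """Dense re-implementation of rank-normalized split R-hat."""
        from scipy import stats

        rng = np.random.default_rng(2)
        draws = np.cumsum(rng.standard_normal((2, 500)), axis=1) * 0.05 + \
            rng.standard_normal((2, 500))

        def oracle(x):
            m, n = x.shape
            half = n // 2
            sp = np.vstack([x[:, :half], x[:, half:]])

            def basic(c):
                W = c.var(axis=1, ddof=1).mean()
                B = c.shape[1] * c.mean(axis=1).var(ddof=1)
                return np.sqrt(((c.shape[1] - 1) / c.shape[1] * W + B / c.shape[1]) / W)

            def rank_norm(c):
                r = stats.rankdata(c, method="average").reshape(c.shape)
                return stats.norm.ppf((r - 0.375) / (c.size + 0.25))

            bulk = basic(rank_norm(sp))
            folded = np.abs(x - np.median(x))
            fsp = np.vstack([folded[:, :half], folded[:, half:]])
            return max(bulk, basic(rank_norm(fsp)))

        assert rhat(draws) == pytest.approx(oracle(draws), abs=1e-8)

    def test_iid_ess_close_to_sample_size(self):
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((2, 2000))
        assert ess(chains, "bulk") == pytest.approx(4000, rel=0.15)

    def test_ar1_ess_matches_analytic(self):
        rho = 0.9
        rng = np.random.default_rng(4)
        n = 20000
        chains = np.empty((2, n))
        for c in range(2):
            e = rng.standard_normal(n)
            x = np.empty(n)
            x[0] = e[0]
            for t in range(1, n):
                x[t] = rho * x[t - 1] + np.sqrt(1 - rho**2) * e[t]
            chains[c] = x
        expected = 2 * n * (1 - rho) / (1 + rho)
        assert ess(chains, "bulk") == pytest.approx(expected, rel=0.25)

    def test_constant_sequence_sentinel(self):
        chains = np.ones((2, 100))
        assert np.isnan(rhat(chains))
        assert np.isnan(ess(chains, "bulk"))
        assert np.isnan(ess(chains, "tail"))

    def test_agrees_with_arviz(self):
        import arviz as az

        rng = np.random.default_rng(5)
        draws = np.cumsum(rng.standard_normal((2, 1500)), axis=1) * 0.02 + \
            rng.standard_normal((2, 1500))
        assert rhat(draws) == pytest.approx(float(az.rhat(draws)), abs=1e-6)
        assert ess(draws, "bulk") == pytest.approx(float(az.ess(draws)), rel=0.05)
        assert ess(draws, "tail") == pytest.approx(
            float(az.ess(draws, method="tail")), rel=0.1
        )


class TestSpeciesEstimates:
    def test_single_precise_study_shrinkage_free(self):
        frame = make_frame([0.4], [0.01], species=["A"])
        m = PhyloMetaModel(frame, PhyloCov(["A"], np.eye(1)))
        res = m.fit(chains=2, iterations=2000, warmup=500, seed=10)
        est = res.species_estimates().set_index("species")
        assert est.loc["A", "estimate"] == pytest.approx(0.4, abs=0.05)

    def test_sorted_and_flagged(self, fitted):
        est = fitted.species_estimates()
        assert est["estimate"].is_monotonic_increasing
        assert est["credible"].dtype == bool

    def test_h2_and_r2_invariant_to_record_permutation(self, sim_world):
        cfg, tree, records, traits, truth = sim_world
        perm = records.sample(frac=1.0, random_state=0).reset_index(drop=True)
        kw = dict(chains=2, iterations=800, warmup=300, seed=11)
        r1 = PhyloMetaModel.from_data(records, traits, tree, ["ECV"], "MHI").fit(**kw)
        r2 = PhyloMetaModel.from_data(perm, traits, tree, ["ECV"], "MHI").fit(**kw)
        assert r1.lynch_h2().mean() == pytest.approx(r2.lynch_h2().mean(), abs=0.05)
        assert r1.bayes_r2().mean() == pytest.approx(r2.bayes_r2().mean(), abs=0.05)


class TestFitBehaviour:
    def test_draw_count_and_positivity(self, fitted):
        ndraw = fitted.n_chains * fitted.n_kept
        assert fitted.n_kept == 1000
        assert fitted.beta.shape[0] == ndraw
        assert (fitted.sigma_p > 0).all()
        assert (fitted.sigma_s > 0).all()
        assert (fitted.tau > 0).all()

    def test_warmup_must_be_below_iterations(self, sim_world):
        cfg, tree, records, traits, truth = sim_world
        m = PhyloMetaModel.from_data(records, traits, tree, [], "MHI")
        with pytest.raises(ValueError, match="warmup"):
            m.fit(iterations=100, warmup=100)

    def test_seed_reproducibility(self, sim_world):
        cfg, tree, records, traits, truth = sim_world
        m = PhyloMetaModel.from_data(records, traits, tree, ["ECV"], "MHI")
        kw = dict(chains=2, iterations=300, warmup=100, seed=42)
        np.testing.assert_array_equal(m.fit(**kw).beta, m.fit(**kw).beta)

    def test_ppc_brackets_observed_moments(self, fitted):
        check = fitted.ppc_check(n_datasets=1000, seed=0)
        assert check["mean"]["inside"]
        assert check["sd"]["inside"]
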