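"""Phylogenetic outlier test and fossil prediction against dense
conditional-Gaussian oracles."""

import numpy as np
import pandas as pd
import pytest

from phylohand.model import PhyloMetaModel
from phylohand.predict import (
    PredictiveDistribution,
    phylo_outlier_test,
    pooled_human_se,
    predict_fossils,
)
from phylohand.predict import _conditional_kriging
from phylohand.synthetic import SimConfig, simulate_dataset, simulate_trees
from phylohand.trees import Phylogeny, graft, phylo_correlation


def attach_near(tree, focal, rel=0.01, depth_frac=1.0):
    """Graft a new tip 'NewTip' diverging from ``focal`` at fraction ``rel``
    of focal's divergence from its closest relative; the new tip's own depth
    is ``depth_frac`` of that split (``< 1`` makes it a fossil)."""
    pc = phylo_correlation(tree)
    i = pc.labels.index(focal)
    off = pc.C[i].copy()
    off[i] = -np.inf
    sister = pc.labels[int(np.argmax(off))]
    h = (1.0 - off.max()) * pc.max_depth
    f = focal.replace(" ", "_")
    s = sister.replace(" ", "_")
    addon = Phylogeny.from_newick(
        f"(({f}:{rel * h:.9f},NewTip:{depth_frac * rel * h:.9f})"
        f":{(1 - rel) * h:.9f},{s}:{h:.9f});"
    )
    return graft(tree, addon, [focal, sister]), sister


@pytest.fixture(scope="module")
def world():
    cfg = SimConfig(n_species=12, seed=17, covariates=("BM", "ECV"))
    tree = simulate_trees(cfg, 1)[0]
    records, traits, truth = simulate_dataset(cfg, tree)
    return cfg, tree, records, traits, truth


@pytest.fixture(scope="module")
def fit_without_target(world):
    cfg, tree, records, traits, truth = world
    target = sorted(tree.tips)[0]
    m = PhyloMetaModel.from_data(records, traits, tree, ["ECV"], "MHI",
                                 exclude_species=target)
    return target, m.fit(chains=2, iterations=1200, warmup=400, seed=19)


class TestKrigingOracle:
    @pytest.mark.parametrize("seed", range(3))
    def test_conditional_moments_match_dense_oracle(self, seed):
        """Kriging weights and conditional covariance equal brute-force
        conditioning of the joint MVN on a 6-tip tree, to 1e-8."""
        from conftest import random_tree

        rng = np.random.default_rng(seed)
        tree = random_tree(rng, 6)
        labels = sorted(tree.tips)
        obs, new = labels[:4], labels[4:]
        pc = phylo_correlation(tree, obs + new)
        C = pc.C

        class FakeFrame:
            species = obs

        class FakeModel:
            jitter = 0.0

        class FakeResults:
            frame = FakeFrame()
            model = FakeModel()

        K, cov = _conditional_kriging(FakeResults(), tree, new)
        C_oo, C_fo, C_ff = C[:4, :4], C[4:, :4], C[4:, 4:]
        K_exp = C_fo @ np.linalg.inv(C_oo)
        cov_exp = C_ff - C_fo @ np.linalg.inv(C_oo) @ C_fo.T
        np.testing.assert_allclose(K, K_exp, atol=1e-8)
        np.testing.assert_allclose(cov, cov_exp, atol=1e-8)

    def test_clone_tip_collapses_to_species_value(self, world):
        """A target splitting from an observed tip at (almost) zero depth,
        with se -> 0 and sigma_s -> 0, reproduces that tip's phylogenetic
        effect."""
        cfg, tree, records, traits, truth = world
        donor = sorted(tree.tips)[3]
        t2, _ = attach_near(tree, donor, rel=1e-6)
        m = PhyloMetaModel.from_data(records, traits, tree, [], "MHI")
        res = m.fit(chains=2, iterations=800, warmup=300, seed=23)
        clone_traits = traits.loc[[donor]].copy()
        clone_traits.index = ["NewTip"]
        pred = phylo_outlier_test(res, t2, "NewTip", clone_traits.iloc[0],
                                  se_target=1e-9, seed=5)
        a, u = res.species_effects
        di = res.frame.species.index(donor)
        donor_lat = res.beta[:, 0] + a[:, di]  # intercept + phylo effect
        # predictive mean matches donor's intercept+phylo mean; spread only
        # from sigma_s (marginalized u*)
        assert pred.mean == pytest.approx(donor_lat.mean(), abs=0.03)

    def test_interval_width_monotone_in_se(self, fit_without_target, world):
        cfg, tree, records, traits, truth = world
        target, res = fit_without_target
        widths = []
        for se in (0.5, 0.1, 0.001):
            p = phylo_outlier_test(res, tree, target, traits.loc[target],
                                   se_target=se, seed=11)
            widths.append(p.ci_high - p.ci_low)
        assert widths[0] > widths[1] > widths[2]


class TestOutlierTest:
    def test_target_in_fit_rejected(self, world):
        cfg, tree, records, traits, truth = world
        m = PhyloMetaModel.from_data(records, traits, tree, [], "MHI")
        res = m.fit(chains=2, iterations=400, warmup=150, seed=2)
        sp = res.frame.species[0]
        with pytest.raises(ValueError, match="already in the fitted data"):
            phylo_outlier_test(res, tree, sp, traits.loc[sp], 0.1)

    def test_percentile_and_flag_attached(self, fit_without_target, world):
        cfg, tree, records, traits, truth = world
        target, res = fit_without_target
        pred = phylo_outlier_test(res, tree, target, traits.loc[target],
                                  se_target=0.1, observed=0.0, seed=3)
        assert pred.percentile_of_observed is not None
        assert 0 <= pred.percentile_of_observed <= 1
        assert pred.outlier_flag in (True, False)
        assert pred.ci_low <= pred.ci_high

    def test_injected_shift_detected(self, world):
        """A gross (human-scale) shift on one tip is flagged as a
        phylogenetic outlier; rate calibration lives in the acceptance suite."""
        cfg, tree, records, traits, truth = world
        target = sorted(tree.tips)[5]
        cfg2 = SimConfig(
            n_species=12, seed=29, covariates=("BM", "ECV"),
            sigma_p=0.1, sigma_s=0.05, tau=0.05,
            outlier_species=(target, 0.9),
        )
        rec2, tr2, truth2 = simulate_dataset(cfg2, tree)
        m = PhyloMetaModel.from_data(rec2, tr2, tree, ["ECV"], "MHI",
                                     exclude_species=target)
        res = m.fit(chains=2, iterations=1200, warmup=400, seed=31)
        sub = rec2[rec2.species == target]
        obs = float(np.average(sub.effect, weights=1 / sub.se**2))
        pred = phylo_outlier_test(res, tree, target, tr2.loc[target],
                                  pooled_human_se(rec2, "MHI", target),
                                  observed=obs, seed=7)
        assert pred.outlier_flag


class TestFossilPrediction:
    def test_fossil_near_human_predicts_human_value(self, world):
        cfg, tree, records, traits, truth = world
        focal = sorted(tree.tips)[2]
        grafted, _ = attach_near(tree, focal, rel=0.01, depth_frac=0.9)
        m = PhyloMetaModel.from_data(records, traits, tree, ["ECV"], "MHI")
        res = m.fit(chains=2, iterations=1200, warmup=400, seed=37)
        fossil_traits = traits.loc[[focal]].copy()
        fossil_traits.index = ["NewTip"]
        preds = predict_fossils(res, grafted, fossil_traits, se_assumption=0.05,
                                seed=9)
        a, _u = res.species_effects
        di = res.frame.species.index(focal)
        x_f = res.frame.species_design[di]
        # same covariates, near-zero divergence: prediction tracks the focal
        # species' intercept + phylogenetic effect (u* is marginalized)
        expected = float((res.beta @ x_f + a[:, di]).mean())
        assert preds[0].mean == pytest.approx(expected, abs=0.1)

    def test_joint_prediction_returns_all_taxa(self, world):
        cfg, tree, records, traits, truth = world
        focal = sorted(tree.tips)[2]
        pc = phylo_correlation(tree)
        i = pc.labels.index(focal)
        off = pc.C[i].copy()
        off[i] = -np.inf
        sister = pc.labels[int(np.argmax(off))]
        h = (1.0 - off.max()) * pc.max_depth
        addon = Phylogeny.from_newick(
            f"((FossilA:{0.4 * h:.6f},FossilB:{0.5 * h:.6f}):{0.2 * h:.6f},"
            f"({focal.replace(' ', '_')}:{0.6 * h:.6f},"
            f"{sister.replace(' ', '_')}:{0.6 * h:.6f}):{0.1 * h:.6f});"
        )
        grafted = graft(tree, addon, [focal, sister])
        assert not grafted.is_ultrametric()
        m = PhyloMetaModel.from_data(records, traits, tree, ["ECV"], "MHI")
        res = m.fit(chains=2, iterations=600, warmup=200, seed=41)
        ft = traits.loc[[focal, focal]].copy()
        ft.index = ["FossilA", "FossilB"]
        preds = predict_fossils(res, grafted, ft, se_assumption=0.05, seed=13)
        assert [p.taxon for p in preds] == ["FossilA", "FossilB"]
        for p in preds:
            assert np.isfinite(p.mean)
            assert p.ci_low < p.ci_high

    def test_missing_covariate_is_error(self, world):
        cfg, tree, records, traits, truth = world
        target = sorted(tree.tips)[0]
        m = PhyloMetaModel.from_data(
            records, traits, tree, ["ECV"], "MHI", exclude_species=target)
        res = m.fit(chains=2, iterations=300, warmup=100, seed=1)
        bad = traits.loc[[target]].drop(columns=["ECV"])
        with pytest.raises(KeyError, match="ECV"):
            phylo_outlier_test(res, tree, target, bad.iloc[0], 0.1)

    def test_pooled_human_se(self, world):
        cfg, tree, records, traits, truth = world
        sp = records["species"].iloc[0]
        sub = records[(records.species == sp) & (records.response == "MHI")]
        expected = float(np.sqrt(1 / (1 / sub.se**2).sum()))
        assert pooled_human_se(records, "MHI", sp) == pytest.approx(expected)
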