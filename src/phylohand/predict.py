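"""Posterior prediction for held-out and fossil taxa.

Both operations condition the Brownian-motion phylogenetic effect of unseen
tips on the fitted species effects: per posterior draw,

    a* | a ~ Normal(C_fo C_oo^-1 a,  sigma_p^2 (C_ff - C_fo C_oo^-1 C_of))

where C is the phylogenetic correlation matrix of the tree containing both
the fitted (o) and new (f) tips, scaled by the maximum extant depth so
fossil diagonal entries are < 1. The predictive response adds the fixed
effects of the new taxon's covariates (transformed with the *fit's* stored
constants), a fresh non-phylogenetic species effect u* ~ Normal(0,
sigma_s^2), and meta-analytic measurement noise at the assumed standard
error. An observed value outside the 95% predictive interval marks the
taxon as a phylogenetic outlier — evolution beyond what tree position and
covariates explain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PhyloMetaResults
from .trees import Phylogeny, normalize_label, phylo_correlation

__all__ = ["PredictiveDistribution", "phylo_outlier_test", "predict_fossils"]


@dataclass
class PredictiveDistribution:
    """Posterior predictive sample of the response for one taxon."""

    taxon: str
    draws: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    observed: float | None = None
    percentile_of_observed: float | None = None
    outlier_flag: bool | None = None

    @classmethod
    def from_draws(cls, taxon, draws, observed=None, ci=0.95):
        lo, hi = np.quantile(draws, [(1 - ci) / 2, 1 - (1 - ci) / 2])
        pct = flag = None
        if observed is not None:
            pct = float(np.mean(draws <= observed))
            flag = bool(observed < lo or observed > hi)
        return cls(
            taxon=taxon, draws=draws, mean=float(draws.mean()),
            ci_low=float(lo), ci_high=float(hi), observed=observed,
            percentile_of_observed=pct, outlier_flag=flag,
        )

    def to_row(self) -> dict:
        return {
            "taxon": self.taxon, "mean": self.mean,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "observed": self.observed,
            "percentile_of_observed": self.percentile_of_observed,
            "outlier_flag": self.outlier_flag,
        }


def _design_rows(results: PhyloMetaResults, traits: pd.DataFrame) -> np.ndarray:
    """Intercept + transformed covariate rows on the fit's scale.

    Warns (extrapolation) when a transformed value falls outside the range
    spanned by the training species.
    """
    tf = results.frame.transform
    design = tf.apply(traits)
    train = results.frame.species_design[:, 1:]
    cols = results.frame.colnames[1:]
    vals = design[cols].to_numpy(float)
    for j, c in enumerate(cols):
        lo, hi = train[:, j].min(), train[:, j].max()
        out = (vals[:, j] < lo) | (vals[:, j] > hi)
        if out.any() and tf.columns[c]["kind"] in ("log10", "logit"):
            warnings.warn(
                f"covariate {c} outside the training range for "
                f"{list(traits.index[out])}: extrapolating", stacklevel=2,
            )
    return np.column_stack([np.ones(len(traits)), vals])


def _conditional_kriging(results, tree, new_taxa):
    """Per-draw conditional mean matrix and shared covariance factor."""
    fit_species = results.frame.species
    pc = phylo_correlation(tree, fit_species + new_taxa)
    n_o = len(fit_species)
    C_oo = pc.C[:n_o, :n_o]
    C_fo = pc.C[n_o:, :n_o]
    C_ff = pc.C[n_o:, n_o:]
    jit = results.model.jitter
    K = np.linalg.solve(C_oo + jit * np.eye(n_o), C_fo.T).T
    cov_base = C_ff - K @ C_fo.T
    cov_base = 0.5 * (cov_base + cov_base.T)
    return K, cov_base


def _predict(
    results: PhyloMetaResults,
    tree: Phylogeny,
    traits: pd.DataFrame,
    se: float,
    joint: bool,
    seed: int | None,
    observed: dict[str, float] | None = None,
) -> list[PredictiveDistribution]:
    new_taxa = [normalize_label(str(t)) for t in traits.index]
    overlap = set(new_taxa) & set(results.frame.species)
    if overlap:
        raise ValueError(f"target taxa already in the fitted data: {sorted(overlap)}")
    missing = set(new_taxa) - set(tree.tips)
    if missing:
        raise KeyError(f"target taxa absent from tree: {sorted(missing)}")
    if se < 0:
        raise ValueError("assumed standard error must be nonnegative")

    X_new = _design_rows(results, traits)
    K, cov_base = _conditional_kriging(results, tree, new_taxa)
    a, _ = results.species_effects
    ndraw = a.shape[0]
    n_f = len(new_taxa)
    rng = np.random.default_rng(seed)

    cond_mean = a @ K.T  # (draws, n_f)
    if joint and n_f > 1:
        L = np.linalg.cholesky(cov_base + 1e-12 * np.eye(n_f))
        a_star = cond_mean + results.sigma_p[:, None] * (
            rng.standard_normal((ndraw, n_f)) @ L.T
        )
    else:
        var = np.clip(np.diag(cov_base), 0.0, None)
        a_star = cond_mean + results.sigma_p[:, None] * np.sqrt(var) * \
            rng.standard_normal((ndraw, n_f))

    u_star = results.sigma_s[:, None] * rng.standard_normal((ndraw, n_f))
    eps = se * rng.standard_normal((ndraw, n_f))
    fixed = results.beta @ X_new.T
    y_tilde = fixed + a_star + u_star + eps

    out = []
    for j, taxon in enumerate(new_taxa):
        obs = None if observed is None else observed.get(taxon)
        out.append(PredictiveDistribution.from_draws(taxon, y_tilde[:, j], obs))
    return out


def phylo_outlier_test(
    results: PhyloMetaResults,
    tree: Phylogeny,
    target: str,
    target_traits: pd.Series | pd.DataFrame,
    se_target: float,
    observed: float | None = None,
    seed: int | None = None,
) -> PredictiveDistribution:
    """Phylogenetic outlier test with a meta-analytical component.

    ``results`` must come from a fit that *excluded* the target species;
    ``tree`` must contain the target tip alongside the fitted species. The
    predictive distribution marginalizes the non-phylogenetic species effect
    and the study-level measurement error at ``se_target``; the observed
    value's percentile and a 95%-interval outlier flag are attached when an
    observed value is supplied.
    """
    target = normalize_label(target)
    if isinstance(target_traits, pd.Series):
        target_traits = target_traits.to_frame().T
    target_traits = target_traits.copy()
    target_traits.index = [target]
    preds = _predict(
        results, tree, target_traits, se_target, joint=False, seed=seed,
        observed=None if observed is None else {target: observed},
    )
    return preds[0]


def predict_fossils(
    results: PhyloMetaResults,
    grafted_tree: Phylogeny,
    fossil_traits: pd.DataFrame,
    se_assumption: float,
    joint: bool = True,
    seed: int | None = None,
) -> list[PredictiveDistribution]:
    """Predict the response for fossil tips of a grafted tree.

    Fossil phylogenetic effects are drawn jointly (conditioned on all extant
    fitted effects, honouring the reduced fossil diagonal of C); fixed
    effects come from the fossil covariates on the fit's transform scale;
    the non-phylogenetic species effect is marginalized and measurement
    error uses the supplied (human-level) standard error.
    """
    return _predict(
        results, grafted_tree, fossil_traits, se_assumption, joint=joint, seed=seed,
    )


def pooled_human_se(records: pd.DataFrame, response: str,
                    species: str = "Homo sapiens") -> float:
    """Precision-weighted pooled SE of one species' records (default human)."""
    sub = records[(records["response"] == response)
                  & (records["species"] == normalize_label(species))]
    if len(sub) == 0:
        raise KeyError(f"no {response} records for {species}")
    prec = (1.0 / sub["se"] ** 2).sum()
    return float(np.sqrt(1.0 / prec))
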