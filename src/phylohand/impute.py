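"""Phylogenetic imputation of missing species covariates.

Missing trait values (here typically IMI and body-mass dimorphism) are
filled by maximum-likelihood multivariate Brownian motion on the tree, with
body mass as the auxiliary trait: trait values across species and traits are
jointly Gaussian with covariance ``kron(C, R_bm)`` where ``C`` holds shared
root-to-MRCA path lengths (unscaled, in time units) and ``R_bm`` is the
evolutionary trait covariance per unit branch length. Missing cells are
imputed by their conditional expectation given all observed cells under the
fitted model; conditional variances are recorded.

Imputation is done on the log10 scale (the modelling scale) and on the MCC
tree only; the completed table is then reused across the full tree set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .trees import Phylogeny, phylo_correlation

__all__ = ["BMModel", "ImputationResult", "bm_loglik", "fit_and_impute", "impute_traits"]

LOG2PI = np.log(2 * np.pi)


@dataclass
class BMModel:
    """Multivariate Brownian motion: trait rate matrix + ancestral means."""

    traits: list[str]
    R_bm: np.ndarray
    root_mean: np.ndarray

    def __post_init__(self):
        self.R_bm = np.asarray(self.R_bm, float)
        self.root_mean = np.asarray(self.root_mean, float)
        p = len(self.traits)
        if self.R_bm.shape != (p, p) or self.root_mean.shape != (p,):
            raise ValueError("R_bm / root_mean shapes do not match trait count")
        if not np.allclose(self.R_bm, self.R_bm.T):
            raise ValueError("R_bm must be symmetric")
        if np.any(np.linalg.eigvalsh(self.R_bm) <= 0):
            raise ValueError("R_bm must be positive definite")


@dataclass
class ImputationResult:
    completed: pd.DataFrame
    predictive_variance: pd.DataFrame
    loglik: float
    model: BMModel


def _time_cov(tree: Phylogeny, species: list[str]) -> np.ndarray:
    """Shared path lengths in time units (the unscaled Brownian covariance)."""
    pc = phylo_correlation(tree, species)
    return pc.C * pc.max_depth


def _joint_moments(C: np.ndarray, model: BMModel):
    # cell ordering is species-major: (s0,t0), (s0,t1), ..., (s1,t0), ...
    Sigma = np.kron(C, model.R_bm)
    mu = np.tile(model.root_mean, C.shape[0])
    return mu, Sigma

def bm_loglik(tree: Phylogeny, X: pd.DataFrame, model: BMModel) -> float:
    """Log-likelihood of the observed cells of ``X`` under the BM model.

    ``X`` is species x trait with NaN for missing cells; species must be tree
    tips. Missing cells are marginalized by row/column deletion from the
    joint Gaussian.
    """
    if list(X.columns) != list(model.traits):
        raise ValueError("X columns must match model traits")
    vals = X.to_numpy(float)
    obs = ~np.isnan(vals)
    if not obs.any(axis=0).all():
        raise ValueError("at least one trait has no observed values")
    C = _time_cov(tree, list(X.index))
    mu, Sigma = _joint_moments(C, model)
    v = vals.ravel()
    m = obs.ravel()
    r = v[m] - mu[m]
    S = Sigma[np.ix_(m, m)]
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("observed-cell covariance not PD")
    return float(-0.5 * (m.sum() * LOG2PI + logdet + r @ np.linalg.solve(S, r)))


def _chol_from_packed(theta: np.ndarray, p: int) -> np.ndarray:
    L = np.zeros((p, p))
    idx = np.tril_indices(p)
    L[idx] = theta
    L[np.diag_indices(p)] = np.exp(np.diag(L))
    return L


def _pack_chol(R: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(R)
    M = L.copy()
    M[np.diag_indices(len(R))] = np.log(np.diag(L))
    return M[np.tril_indices(len(R))]


def fit_and_impute(
    tree: Phylogeny,
    X: pd.DataFrame,
    max_restarts: int = 3,
) -> ImputationResult:
    """ML fit of (R_bm, root_mean) and conditional-mean imputation.

    Optimizes the log-Cholesky parameterization of R_bm with L-BFGS-B from a
    moment-based start; observed cells pass through unchanged, with zero
    predictive variance.
    """
    species = list(X.index)
    traits = list(X.columns)
    p = len(traits)
    vals = X.to_numpy(float)
    obs = ~np.isnan(vals)
    if not obs.any(axis=0).all():
        raise ValueError("at least one trait has no observed values")
    C = _time_cov(tree, species)
    mean_depth = float(np.mean(np.diag(C)))

    # moment start: trait covariance of (pairwise-complete) tip values per
    # unit depth, ridge-regularized
    df = pd.DataFrame(vals, columns=traits)
    R0 = df.cov(min_periods=2).to_numpy()
    R0 = np.where(np.isnan(R0), 0.0, R0) / max(mean_depth, 1e-8)
    R0 += (0.1 * max(np.trace(R0) / p, 1e-3) + 1e-6) * np.eye(p)
    mu0 = np.nanmean(vals, axis=0)

    def neg_loglik(theta):
        L = _chol_from_packed(theta[: p * (p + 1) // 2], p)
        model = BMModel.__new__(BMModel)
        model.traits = traits
        model.R_bm = L @ L.T
        model.root_mean = theta[p * (p + 1) // 2 :]
        try:
            ll = bm_loglik(tree, X, model)
        except np.linalg.LinAlgError:
            return 1e10
        return -ll if np.isfinite(ll) else 1e10

    theta0 = np.concatenate([_pack_chol(R0), mu0])
    # keep the log-Cholesky diagonal bounded so line searches cannot overflow
    diag_pos = np.cumsum(np.arange(1, p + 1)) - 1
    n_chol = p * (p + 1) // 2
    bounds = []
    for i in range(len(theta0)):
        if i in diag_pos:
            bounds.append((-15.0, 15.0))
        elif i < n_chol:
            bounds.append((-1e3, 1e3))
        else:
            bounds.append((None, None))
    best = None
    rng = np.random.default_rng(0)
    for attempt in range(max_restarts + 1):
        start = theta0 if attempt == 0 else theta0 + 0.3 * rng.standard_normal(len(theta0))
        res = optimize.minimize(neg_loglik, start, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("BM imputation optimizer failed to converge")

    L = _chol_from_packed(best.x[: p * (p + 1) // 2], p)
    model = BMModel(traits, L @ L.T, best.x[p * (p + 1) // 2 :])
    loglik = -float(best.fun)

    mu, Sigma = _joint_moments(C, model)
    m = obs.ravel()
    completed = vals.copy().ravel()
    pred_var = np.zeros_like(completed)
    if (~m).any():
        So = Sigma[np.ix_(m, m)]
        Smo = Sigma[np.ix_(~m, m)]
        Smm = Sigma[np.ix_(~m, ~m)]
        # relative ridge: the ML fit can drive R_bm arbitrarily close to singular
        So = So + 1e-9 * np.mean(np.diag(So)) * np.eye(So.shape[0])
        K = np.linalg.solve(So, Smo.T).T
        completed[~m] = mu[~m] + K @ (completed[m] - mu[m])
        pred_var[~m] = np.diag(Smm - K @ Smo.T)
    n_sp = len(species)
    return ImputationResult(
        completed=pd.DataFrame(completed.reshape(n_sp, p), index=species, columns=traits),
        predictive_variance=pd.DataFrame(
            pred_var.reshape(n_sp, p), index=species, columns=traits
        ),
        loglik=loglik,
        model=model,
    )


def impute_traits(
    traits: pd.DataFrame,
    tree: Phylogeny,
    targets: tuple[str, ...] = ("IMI", "DIM"),
    auxiliary: str = "BM",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing target covariates using the auxiliary trait, on log10 scale.

    Returns the completed trait table (other columns untouched) and a report
    with one row per imputed cell (species, trait, value, variance on the
    log10 scale).
    """
    targets = tuple(t for t in targets if t in traits.columns)
    cols = [auxiliary, *targets]
    sub = traits[cols].astype(float)
    if (sub <= 0).any().any() and not sub.isna().all().all():
        bad = sub[(sub <= 0).any(axis=1)].index.tolist()
        raise ValueError(f"non-positive values for {bad}: cannot impute on log10 scale")
    logsub = np.log10(sub)
    if not logsub.isna().any().any():
        return traits.copy(), pd.DataFrame(
            columns=["species", "trait", "value", "log10_variance"]
        )
    result = fit_and_impute(tree, logsub)
    completed = traits.copy()
    rows = []
    for sp in logsub.index:
        for t in targets:
            if np.isnan(logsub.loc[sp, t]):
                val = 10 ** result.completed.loc[sp, t]
                completed.loc[sp, t] = val
                rows.append(
                    {"species": sp, "trait": t, "value": val,
                     "log10_variance": result.predictive_variance.loc[sp, t]}
                )
    return completed, pd.DataFrame(rows)
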