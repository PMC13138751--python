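"""The Gaussian phylogenetic meta-analytic multilevel model.

Record k (one published tube-task effect size) is modeled as

    y_k ~ Normal(eta_k, se_k^2)
    eta_k = x_{s(k)} . beta + a_{s(k)} + u_{s(k)} + b_{g(k)}

with species-level fixed effects beta, phylogenetic species effects
a ~ MVN(0, sigma_p^2 C) (C the phylogenetic correlation matrix),
non-phylogenetic species effects u ~ iid Normal(0, sigma_s^2), and study
effects b ~ iid Normal(0, tau^2) capturing between-study heterogeneity.
Priors: beta ~ Normal(0, 1) per coefficient (responses live in [-1, 1] so
this is weakly informative), half-Cauchy(0, 0.05) on each of the three
random-effect standard deviations.

Posterior sampling is Gibbs for the conditionally Gaussian blocks
(beta, a, u, b all have closed-form multivariate normal conditionals) with
univariate stepping-out slice updates on log sigma_p, log sigma_s, log tau.
Phylogenetic signal is Lynch's h^2 = sigma_p^2 / (sigma_p^2 + sigma_s^2 +
tau^2), the share of latent among-species variance attributable to
phylogeny (equivalent to Pagel's lambda in this model class).

Usage follows the statsmodels pattern::

    model = PhyloMetaModel(frame, phylo_cov)
    results = model.fit(chains=2, iterations=12000, warmup=4000, seed=1)
    print(results.summary())
    results.lynch_h2()
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ModelFrame, build_model_frame
from .diagnostics import ess, rhat
from .trees import PhyloCov, Phylogeny, phylo_correlation

__all__ = ["PhyloMetaModel", "PhyloMetaResults", "TEST_SETTINGS", "FULL_SETTINGS"]

# the study's sampler settings, and a reduced mode for test-scale runs
FULL_SETTINGS = dict(chains=2, iterations=12000, warmup=4000)
TEST_SETTINGS = dict(chains=2, iterations=2000, warmup=500)

LOG2PI = math.log(2 * math.pi)
SD_NAMES = ("sigma_p", "sigma_s", "tau")


def cho_solve_tri(L: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve (L L^T) X = B given the lower Cholesky factor L."""
    from scipy.linalg import solve_triangular

    return solve_triangular(L, solve_triangular(L, B, lower=True), lower=True, trans="T")


def _log_half_cauchy(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return math.log(2.0 / (math.pi * scale * (1.0 + (x / scale) ** 2)))


def _slice_sample(logpost, x0: float, lp0: float, rng, w: float = 0.5, max_steps: int = 50):
    """One stepping-out slice-sampling update (Neal 2003) on the real line."""
    logy = lp0 + math.log(rng.uniform(1e-300, 1.0))
    L = x0 - w * rng.uniform(0.0, 1.0)
    R = L + w
    j = int(rng.integers(0, max_steps))
    k = max_steps - 1 - j
    while j > 0 and logpost(L) > logy:
        L -= w
        j -= 1
    while k > 0 and logpost(R) > logy:
        R += w
        k -= 1
    for _ in range(1000):
        x1 = rng.uniform(L, R)
        lp1 = logpost(x1)
        if lp1 > logy:
            return x1, lp1
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0, lp0  # pragma: no cover


@dataclass
class _ChainDraws:
    beta: np.ndarray
    sd: np.ndarray       # columns sigma_p, sigma_s, tau
    a: np.ndarray
    u: np.ndarray
    b: np.ndarray
    loglik: np.ndarray   # pointwise per record


class PhyloMetaModel:
    """Phylogenetic meta-analytic multilevel model for one response.

    Parameters
    ----------
    frame : ModelFrame
        Design matrix, responses, standard errors and grouping indices.
    phylo_cov : PhyloCov
        Phylogenetic correlation matrix; its labels must cover (and are
        subset/reordered to) the species in ``frame``.
    prior_beta_sd : float
        Prior SD for each fixed-effect coefficient (default 1).
    prior_sd_scale : float
        Half-Cauchy scale for the random-effect SDs (default 0.05).
    jitter : float
        Diagonal jitter added to C before factorization.
    """

    def __init__(
        self,
        frame: ModelFrame,
        phylo_cov: PhyloCov,
        prior_beta_sd: float = 1.0,
        prior_sd_scale: float = 0.05,
        jitter: float = 1e-8,
    ):
        if set(frame.species) - set(phylo_cov.labels):
            missing = sorted(set(frame.species) - set(phylo_cov.labels))
            raise KeyError(f"species missing from phylogenetic matrix: {missing}")
        self.frame = frame
        self.phylo_cov = phylo_cov.subset(frame.species)
        self.prior_beta_sd = float(prior_beta_sd)
        self.prior_sd_scale = float(prior_sd_scale)
        self.jitter = jitter
        C = self.phylo_cov.C + jitter * np.eye(frame.n_species)
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "phylogenetic matrix is not positive definite; increase jitter"
            ) from exc
        Linv = np.linalg.inv(L)
        self._Cinv = Linv.T @ Linv
        if not np.all(self.frame.se > 0):
            raise ValueError("all record standard errors must be > 0")

    @classmethod
    def from_data(
        cls,
        records: pd.DataFrame,
        traits: pd.DataFrame,
        tree: Phylogeny,
        covariates: list[str],
        response: str,
        exclude_species: str | None = None,
        study_group: str = "study",
        **kwargs,
    ) -> "PhyloMetaModel":
        """Build frame and phylogenetic matrix from raw tables and a tree."""
        frame = build_model_frame(
            records, traits, covariates, response,
            exclude_species=exclude_species, study_group=study_group,
        )
        pc = phylo_correlation(tree, frame.species)
        return cls(frame, pc, **kwargs)

    # ------------------------------------------------------------------ fit

    def fit(
        self,
        chains: int = 2,
        iterations: int = 12000,
        warmup: int = 4000,
        seed: int | None = None,
        fixed: dict[str, float] | None = None,
        init_sd: float = 0.05,
    ) -> "PhyloMetaResults":
        """Run the Gibbs-within-slice sampler.

        ``fixed`` pins named variance components (``sigma_p``, ``sigma_s``,
        ``tau``) at given values; a component fixed at 0 degenerates its
        effects to exactly zero (used for conjugate-oracle testing).
        """
        if warmup >= iterations:
            raise ValueError("warmup must be below iterations")
        fixed = dict(fixed or {})
        for k in fixed:
            if k not in SD_NAMES:
                raise KeyError(f"unknown component {k!r}")
        ss = np.random.SeedSequence(seed)
        chain_draws = [
            self._run_chain(iterations, warmup, np.random.default_rng(s), fixed, init_sd)
            for s in ss.spawn(chains)
        ]
        return PhyloMetaResults(self, chain_draws, dict(
            chains=chains, iterations=iterations, warmup=warmup, seed=seed,
            fixed=fixed,
        ))

    def _run_chain(self, iterations, warmup, rng, fixed, init_sd) -> _ChainDraws:
        f = self.frame
        y, se, X = f.y, f.se, f.X
        K, p = X.shape
        S, G = f.n_species, len(f.studies)
        sidx, gidx = f.species_idx, f.study_idx
        w = 1.0 / se**2
        Cinv = self._Cinv
        XtW = X.T * w
        prior_prec_beta = np.eye(p) / self.prior_beta_sd**2
        beta_prec = XtW @ X + prior_prec_beta
        beta_prec_chol = np.linalg.cholesky(beta_prec)

        w_s = np.bincount(sidx, weights=w, minlength=S)
        w_g = np.bincount(gidx, weights=w, minlength=G)
        C = self.phylo_cov.C + self.jitter * np.eye(S)

        sd = {name: float(fixed.get(name, init_sd)) for name in SD_NAMES}
        active = {name: name not in fixed for name in SD_NAMES}
        use = {name: sd[name] > 0 or active[name] for name in SD_NAMES}

        # init: ridge WLS for beta; zero effects
        beta = np.linalg.solve(beta_prec, XtW @ y)
        a = np.zeros(S)
        u = np.zeros(S)
        b = np.zeros(G)

        kept = iterations - warmup
        out = _ChainDraws(
            beta=np.empty((kept, p)), sd=np.empty((kept, 3)),
            a=np.empty((kept, S)), u=np.empty((kept, S)), b=np.empty((kept, G)),
            loglik=np.empty((kept, K)),
        )
        const_ll = -0.5 * (LOG2PI + 2 * np.log(se))
        scale = self.prior_sd_scale
        C_rec = C[np.ix_(sidx, sidx)]  # species covariance expanded to records
        same_sp = (sidx[:, None] == sidx[None, :]).astype(float)

        def marginal_cov(sp, ss):
            """Cov(y - X beta - b) with the species effects integrated out."""
            V = sp**2 * C_rec + ss**2 * same_sp
            return V + np.diag(se**2)

        def marginal_loglik(Lv, resid):
            z = np.linalg.solve(Lv, resid)
            return float(-np.log(np.diag(Lv)).sum() - 0.5 * z @ z)

        def log_prior_sd(name, value):
            # half-Cauchy on sigma plus the log-sigma Jacobian
            return _log_half_cauchy(value, scale) + math.log(value)

        mh_step = 0.25
        XXt = self.prior_beta_sd**2 * (X @ X.T)  # beta collapsed under prior

        for it in range(iterations):
            r = y - b[gidx]

            # (sigma_p, sigma_s) | b, y with beta AND the species effects
            # integrated out: joint random-walk Metropolis on the log scale.
            # The conditional-on-effects update alone mixes very slowly
            # because the effects and their scales are strongly coupled.
            mh_names = [n for n in ("sigma_p", "sigma_s") if active[n]]
            if mh_names:
                def mh_logpost(sdvals):
                    V = marginal_cov(sdvals["sigma_p"] if use["sigma_p"] else 0.0,
                                     sdvals["sigma_s"] if use["sigma_s"] else 0.0)
                    Lm = np.linalg.cholesky(V + XXt)
                    return marginal_loglik(Lm, r) + sum(
                        log_prior_sd(n, sdvals[n]) for n in mh_names
                    )

                cur_ll = mh_logpost(sd)
                prop = dict(sd)
                for n in mh_names:
                    prop[n] = math.exp(math.log(sd[n]) + mh_step * rng.standard_normal())
                if math.log(rng.uniform(1e-300, 1.0)) < mh_logpost(prop) - cur_ll:
                    sd.update({n: prop[n] for n in mh_names})
            use_a = use["sigma_p"] and sd["sigma_p"] > 0
            use_u = use["sigma_s"] and sd["sigma_s"] > 0

            # beta | b, sds (species effects a+u marginalized out: collapsed
            # update, which decorrelates the intercept from the species means)
            if use_a or use_u:
                Lv = np.linalg.cholesky(
                    marginal_cov(sd["sigma_p"] if use_a else 0.0,
                                 sd["sigma_s"] if use_u else 0.0)
                )
                Vinv_X = cho_solve_tri(Lv, X)
                prec = X.T @ Vinv_X + prior_prec_beta
                Lb = np.linalg.cholesky(prec)
                mean = np.linalg.solve(prec, Vinv_X.T @ r)
            else:
                Lb = beta_prec_chol
                mean = np.linalg.solve(beta_prec, XtW @ r)
            beta = mean + np.linalg.solve(Lb.T, rng.standard_normal(p))
            xb = X @ beta

            # (a, u) | beta, b jointly (their conditionals are strongly coupled)
            r = y - xb - b[gidx]
            t_s = np.bincount(sidx, weights=w * r, minlength=S)
            if use_a and use_u:
                P = np.zeros((2 * S, 2 * S))
                P[:S, :S] = Cinv / sd["sigma_p"] ** 2 + np.diag(w_s)
                P[S:, S:] = np.diag(1.0 / sd["sigma_s"] ** 2 + w_s)
                P[:S, S:] = np.diag(w_s)
                P[S:, :S] = np.diag(w_s)
                Lp = np.linalg.cholesky(P)
                t2 = np.concatenate([t_s, t_s])
                mean = np.linalg.solve(Lp.T, np.linalg.solve(Lp, t2))
                draw = mean + np.linalg.solve(Lp.T, rng.standard_normal(2 * S))
                a, u = draw[:S], draw[S:]
            elif use_a:
                A = Cinv / sd["sigma_p"] ** 2 + np.diag(w_s)
                La = np.linalg.cholesky(A)
                mean = np.linalg.solve(La.T, np.linalg.solve(La, t_s))
                a = mean + np.linalg.solve(La.T, rng.standard_normal(S))
                u = np.zeros(S)
            elif use_u:
                var = 1.0 / (1.0 / sd["sigma_s"] ** 2 + w_s)
                u = var * t_s + np.sqrt(var) * rng.standard_normal(S)
                a = np.zeros(S)
            else:
                a = np.zeros(S)
                u = np.zeros(S)

            # tau | beta, a, u with the study effects b integrated out
            # (rank-1 Sherman-Morrison per study), via slice sampling on
            # log tau; then b | tau, rest
            r = y - xb - a[sidx] - u[sidx]
            if active["tau"] or (use["tau"] and sd["tau"] > 0):
                t_g = np.bincount(gidx, weights=w * r, minlength=G)
                if active["tau"]:
                    def logpost_tau(theta, t_g=t_g):
                        t2 = math.exp(2 * theta)
                        denom = 1.0 + t2 * w_g
                        ll = -0.5 * np.log(denom).sum() + 0.5 * (
                            t2 * t_g**2 / denom
                        ).sum()
                        return ll + _log_half_cauchy(math.exp(theta), scale) + theta

                    theta0 = math.log(max(sd["tau"], 1e-8))
                    theta1, _ = _slice_sample(logpost_tau, theta0,
                                              logpost_tau(theta0), rng)
                    sd["tau"] = math.exp(theta1)
                var = 1.0 / (1.0 / sd["tau"] ** 2 + w_g)
                b = var * t_g + np.sqrt(var) * rng.standard_normal(G)
            else:
                b = np.zeros(G)

            # extra conditional slice refresh of sigma_p / sigma_s given the
            # drawn effects (cheap; supplements the marginal MH step)
            for name, vec in (("sigma_p", a), ("sigma_s", u)):
                if not active[name]:
                    continue
                q = float(vec @ Cinv @ vec) if name == "sigma_p" else float(vec @ vec)

                def logpost(theta, q=q):
                    sig = math.exp(theta)
                    return (
                        -S * theta - q / (2 * sig * sig)
                        + _log_half_cauchy(sig, scale) + theta
                    )

                theta0 = math.log(max(sd[name], 1e-8))
                theta1, _ = _slice_sample(logpost, theta0, logpost(theta0), rng)
                sd[name] = math.exp(theta1)

            if it >= warmup:
                j = it - warmup
                eta = xb + a[sidx] + u[sidx] + b[gidx]
                out.beta[j] = beta
                out.sd[j] = (sd["sigma_p"], sd["sigma_s"], sd["tau"])
                out.a[j], out.u[j], out.b[j] = a, u, b
                out.loglik[j] = const_ll - 0.5 * ((y - eta) / se) ** 2
        return out


class PhyloMetaResults:
    """Posterior draws plus diagnostics, summaries and derived quantities."""

    def __init__(self, model: PhyloMetaModel, chain_draws: list[_ChainDraws], settings: dict):
        self.model = model
        self.frame = model.frame
        self._chains = chain_draws
        self.settings = settings

    # ------------------------------------------------------------- accessors

    @property
    def n_chains(self) -> int:
        return len(self._chains)

    @property
    def n_kept(self) -> int:
        return self._chains[0].beta.shape[0]

    def _stack(self, attr: str) -> np.ndarray:
        """(chains, kept, ...) array for one block."""
        return np.stack([getattr(c, attr) for c in self._chains])

    @property
    def beta(self) -> np.ndarray:
        """Fixed-effect draws, flattened over chains: (draws, p)."""
        return self._stack("beta").reshape(-1, len(self.frame.colnames))

    @property
    def sigma_p(self) -> np.ndarray:
        return self._stack("sd")[..., 0].ravel()

    @property
    def sigma_s(self) -> np.ndarray:
        return self._stack("sd")[..., 1].ravel()

    @property
    def tau(self) -> np.ndarray:
        return self._stack("sd")[..., 2].ravel()

    @property
    def species_effects(self) -> tuple[np.ndarray, np.ndarray]:
        """(a, u) draws flattened over chains: each (draws, n_species)."""
        S = self.frame.n_species
        return (self._stack("a").reshape(-1, S), self._stack("u").reshape(-1, S))

    @property
    def pointwise_loglik(self) -> np.ndarray:
        """(draws, n_records) pointwise log-likelihood."""
        return self._stack("loglik").reshape(-1, self.frame.n_records)

    def _param_chains(self) -> dict[str, np.ndarray]:
        out = {}
        betas = self._stack("beta")
        for i, name in enumerate(self.frame.colnames):
            out[f"b_{name}"] = betas[..., i]
        sds = self._stack("sd")
        for i, name in enumerate(SD_NAMES):
            if name not in self.settings["fixed"]:
                out[name] = sds[..., i]
        return out

    # ------------------------------------------------------------- summaries

    def summary(self, ci: float = 0.95) -> pd.DataFrame:
        """Posterior summary table with convergence diagnostics.

        One row per fixed effect and free variance component: mean, median,
        sd, CI bounds, a ``credible`` flag (CI excludes zero), split R-hat
        and bulk/tail ESS.
        """
        lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
        rows = []
        for name, ch in self._param_chains().items():
            flat = ch.ravel()
            lo, hi = np.quantile(flat, [lo_q, hi_q])
            rows.append({
                "param": name,
                "mean": flat.mean(),
                "median": float(np.median(flat)),
                "sd": flat.std(ddof=1),
                f"ci_{lo_q:.3f}": lo,
                f"ci_{hi_q:.3f}": hi,
                "credible": bool(lo > 0 or hi < 0),
                "rhat": rhat(ch) if ch.shape[0] >= 2 and ch.shape[1] >= 4 else np.nan,
                "ess_bulk": ess(ch, "bulk") if ch.shape[0] >= 2 and ch.shape[1] >= 4 else np.nan,
                "ess_tail": ess(ch, "tail") if ch.shape[0] >= 2 and ch.shape[1] >= 4 else np.nan,
            })
        return pd.DataFrame(rows).set_index("param")

    def fixed_effect_summary(self, ci: float = 0.95) -> pd.DataFrame:
        s = self.summary(ci)
        return s.loc[[f"b_{c}" for c in self.frame.colnames]]

    def lynch_h2(self, include_tau: bool = True) -> np.ndarray:
        """Posterior draws of phylogenetic signal h^2.

        h^2 = sigma_p^2 / (sigma_p^2 + sigma_s^2 [+ tau^2]); the known
        per-study measurement-error variances are excluded from the
        denominator (lambda-equivalence holds among the latent components).
        """
        num = self.sigma_p**2
        den = num + self.sigma_s**2 + (self.tau**2 if include_tau else 0.0)
        with np.errstate(invalid="ignore"):
            h2 = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        return h2

    def bayes_r2(self, mode: str = "fixed_only") -> np.ndarray:
        """Posterior draws of Bayesian multilevel R^2.

        ``fixed_only``: per draw, Var_k(x.beta) over that plus all latent
        variance components plus the mean squared measurement error.
        ``conditional``: Var_k(eta) over that plus mean squared measurement
        error.
        """
        f = self.frame
        if f.n_records < 2:
            raise ValueError("R^2 undefined for fewer than 2 records")
        mean_se2 = float(np.mean(f.se**2))
        betas = self.beta
        pred_fixed = betas @ f.X.T  # (draws, K)
        if mode == "fixed_only":
            var_pred = pred_fixed.var(axis=1)
            resid = self.sigma_p**2 + self.sigma_s**2 + self.tau**2 + mean_se2
        elif mode == "conditional":
            a, u = self.species_effects
            b = self._stack("b").reshape(-1, len(f.studies))
            eta = pred_fixed + a[:, f.species_idx] + u[:, f.species_idx] + b[:, f.study_idx]
            var_pred = eta.var(axis=1)
            resid = mean_se2
        else:
            raise ValueError(f"unknown R^2 mode {mode!r}")
        return var_pred / (var_pred + resid)

    def species_estimates(self, ci: float = 0.95) -> pd.DataFrame:
        """Per-species posterior of the species-level trait x_s.beta + a_s + u_s.

        Sorted by posterior mean; ``credible`` flags a CI excluding zero
        (meaningful for MHI, where sign is direction).
        """
        f = self.frame
        a, u = self.species_effects
        est = self.beta @ f.species_design.T + a + u  # (draws, S)
        lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
        lo, hi = np.quantile(est, [lo_q, hi_q], axis=0)
        df = pd.DataFrame({
            "species": f.species,
            "estimate": est.mean(axis=0),
            "ci_low": lo,
            "ci_high": hi,
            "credible": (lo > 0) | (hi < 0),
        })
        return df.sort_values("estimate").reset_index(drop=True)

    # ------------------------------------------------------------ predictive

    def linear_predictor(self) -> np.ndarray:
        """(draws, K) posterior draws of eta for every record."""
        f = self.frame
        a, u = self.species_effects
        b = self._stack("b").reshape(-1, len(f.studies))
        return (
            self.beta @ f.X.T
            + a[:, f.species_idx] + u[:, f.species_idx] + b[:, f.study_idx]
        )

    def posterior_predictive(self, n_datasets: int = 1000, seed: int | None = None) -> np.ndarray:
        """Simulate replicate datasets y_rep (n_datasets, K) from the fit."""
        rng = np.random.default_rng(seed)
        eta = self.linear_predictor()
        idx = rng.integers(0, eta.shape[0], size=n_datasets)
        return eta[idx] + self.frame.se * rng.standard_normal((n_datasets, self.frame.n_records))

    def ppc_check(self, n_datasets: int = 1000, seed: int | None = None) -> dict:
        """Posterior predictive check on the data mean and SD.

        Returns the simulated 2.5-97.5% bands and whether the observed
        statistics fall inside them.
        """
        yrep = self.posterior_predictive(n_datasets, seed)
        obs_mean, obs_sd = float(self.frame.y.mean()), float(self.frame.y.std(ddof=1))
        means, sds = yrep.mean(axis=1), yrep.std(axis=1, ddof=1)
        m_lo, m_hi = np.quantile(means, [0.025, 0.975])
        s_lo, s_hi = np.quantile(sds, [0.025, 0.975])
        return {
            "mean": {"observed": obs_mean, "band": (m_lo, m_hi),
                     "inside": bool(m_lo <= obs_mean <= m_hi)},
            "sd": {"observed": obs_sd, "band": (s_lo, s_hi),
                   "inside": bool(s_lo <= obs_sd <= s_hi)},
        }

    def loo(self, refit: bool = True, **kwargs):
        """PSIS-LOO with exact refits for influential records (see loo module)."""
        from .loo import psis_loo

        hook = self._exact_elpd if refit else None
        return psis_loo(self.pointwise_loglik, refit_hook=hook, **kwargs)

    def _exact_elpd(self, k: int) -> float:
        """Exact leave-one-out elpd for record k by refitting without it."""
        f = self.frame
        keep = np.arange(f.n_records) != k
        sub_records = f.records.iloc[keep]
        sub_frame = build_model_frame(
            sub_records, _traits_from_design(f), f.transform.covariates,
            f.response,
        )
        sub_model = PhyloMetaModel(
            sub_frame,
            self.model.phylo_cov if set(sub_frame.species) == set(f.species)
            else self.model.phylo_cov.subset(sub_frame.species),
            prior_beta_sd=self.model.prior_beta_sd,
            prior_sd_scale=self.model.prior_sd_scale,
            jitter=self.model.jitter,
        )
        st = self.settings
        res = sub_model.fit(
            chains=st["chains"], iterations=st["iterations"], warmup=st["warmup"],
            seed=None if st["seed"] is None else st["seed"] + 10007 * (k + 1),
            fixed=st["fixed"],
        )
        # predictive density of the held-out record under the refit
        sp = f.species[f.species_idx[k]]
        a, u = res.species_effects
        ndraw = a.shape[0]
        rng = np.random.default_rng(0 if st["seed"] is None else st["seed"] + k)
        if sp in sub_frame.species:
            si = sub_frame.species.index(sp)
            x_k = sub_frame.species_design[si]
            lat = a[:, si] + u[:, si]
        else:
            # species vanished with its only record: marginal species effect
            x_k = np.concatenate(
                [[1.0], sub_frame.transform.apply(_traits_from_design(f).loc[[sp]])
                 .to_numpy(float)[0]]
            )
            lat = res.sigma_p * rng.standard_normal(ndraw) + \
                res.sigma_s * rng.standard_normal(ndraw)
        study = f.studies[f.study_idx[k]]
        if study in sub_frame.studies:
            gi = sub_frame.studies.index(study)
            b = res._stack("b").reshape(-1, len(sub_frame.studies))[:, gi]
            var = f.se[k] ** 2 * np.ones(ndraw)
            lat = lat + b
        else:
            var = f.se[k] ** 2 + res.tau**2  # marginal over the new study effect
        mu = res.beta @ x_k + lat
        lpd = -0.5 * (LOG2PI + np.log(var) + (f.y[k] - mu) ** 2 / var)
        m = lpd.max()
        return float(m + np.log(np.mean(np.exp(lpd - m))))


def _traits_from_design(frame: ModelFrame) -> pd.DataFrame:
    """Reconstruct a raw trait table from the frame's stored transform."""
    design = pd.DataFrame(
        frame.species_design[:, 1:], index=frame.species,
        columns=frame.colnames[1:],
    )
    raw = frame.transform.inverse(design)
    # dummies invert to their indicator columns; rebuild categorical sources
    from .data import CATEGORICAL_COVARIATES

    for cov, (levels, ref) in CATEGORICAL_COVARIATES.items():
        dummy_cols = [c for c in raw.columns if c.startswith(f"{cov}:")]
        if not dummy_cols:
            continue
        vals = pd.Series(ref, index=raw.index)
        for c in dummy_cols:
            vals[raw[c] > 0.5] = c.split(":", 1)[1]
        raw = raw.drop(columns=dummy_cols)
        raw[cov] = vals
    raw.insert(0, "species", raw.index)
    return raw
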