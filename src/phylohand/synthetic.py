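"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the structure of the real study corpus: a set of
time-calibrated anthropoid trees, per-species covariates evolving on the
tree (continuous traits as Brownian motion, categorical traits as Markov
switches along branches), latent species handedness values composed of
fixed effects plus phylogenetic and non-phylogenetic species effects, and
per-study effect-size records with study heterogeneity and sampling error
se = c / sqrt(n). Defaults target the published data scale: 41 species and
an expected ~2,050 individuals in total (the study pooled 2,025), with
responses clipped to their bounds (clip events are logged in the truth
ledger — rare under defaults, so the Gaussian likelihood stays a fair
approximation).

Every latent quantity is recorded in a truth ledger so recovery, coverage
and outlier-detection behaviour can be tested against known values.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .data import CATEGORICAL_COVARIATES, transform_covariates
from .trees import Phylogeny, phylo_correlation

__all__ = ["SimConfig", "simulate_trees", "simulate_dataset", "make_missing"]


@dataclass
class SimConfig:
    """Generator settings; defaults state the emulated world.

    ``beta_true`` maps design-column names (e.g. ``"intercept"``, ``"ECV"``,
    ``"SUBS:terrestrial"``) to coefficients on the standardized scale;
    unnamed columns get 0.
    """

    n_species: int = 41
    n_trees: int = 100
    birth_rate: float = 0.2          # per lineage per My
    death_rate: float = 0.05
    root_depth: float = 40.0         # My, anthropoid-crown scale
    covariates: tuple[str, ...] = ("BM", "ECV", "IMI", "DIM", "FRUIT", "DIET",
                                   "TOOL", "SUBS", "SOC_SYS", "EXT")
    response: str = "MHI"
    beta_true: dict = field(default_factory=dict)
    sigma_p: float = 0.30
    sigma_s: float = 0.20
    tau: float = 0.15
    studies_per_species: tuple[int, int] = (1, 4)
    individuals_per_study: tuple[int, int] = (8, 32)
    se_scale: float = 0.6            # se = se_scale / sqrt(n)
    missing_fraction: dict = field(default_factory=dict)  # trait -> fraction
    outlier_species: tuple[str, float] | None = None
    markov_rate: float = 0.03        # categorical switch rate per My
    seed: int = 0

    def __post_init__(self):
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("rates must be nonnegative")
        for name in ("sigma_p", "sigma_s", "tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for t, f in self.missing_fraction.items():
            if not 0 <= f < 1:
                raise ValueError(f"missing fraction for {t} must be in [0, 1)")


def simulate_trees(cfg: SimConfig, n_trees: int | None = None) -> list[Phylogeny]:
    """Birth-death trees conditioned on the extant tip count, scaled to a
    fixed root depth, with stable tip labels Sp01..SpNN."""
    if cfg.birth_rate <= cfg.death_rate:
        raise ValueError("birth rate must exceed death rate")
    n_trees = cfg.n_trees if n_trees is None else n_trees
    out = []
    for i in range(n_trees):
        child = int(np.random.SeedSequence((cfg.seed, i)).generate_state(1)[0])
        rng = random.Random(child)
        for attempt in range(50):
            try:
                dt = treesim.birth_death_tree(
                    birth_rate=cfg.birth_rate, death_rate=cfg.death_rate,
                    num_extant_tips=cfg.n_species, rng=rng,
                )
                break
            except Exception:
                if attempt == 49:
                    raise RuntimeError("tree simulation failed after 50 retries")
        # the simulator stops exactly at the n-th birth, leaving a zero-length
        # cherry; extend every extant tip by a draw of the waiting time to the
        # next event so all pairwise divergences are positive
        extra = rng.expovariate(cfg.n_species * (cfg.birth_rate + cfg.death_rate))
        for leaf in dt.leaf_node_iter():
            leaf.edge.length = (leaf.edge.length or 0.0) + extra
        tree = Phylogeny(dt)
        depth = tree.max_depth
        if depth <= 0:
            raise RuntimeError("degenerate simulated tree")
        for edge in dt.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= cfg.root_depth / depth
        width = len(str(cfg.n_species))
        for j, leaf in enumerate(sorted(dt.leaf_node_iter(),
                                        key=lambda l: l.taxon.label), start=1):
            leaf.taxon.label = f"Sp{j:0{width}d}"
        out.append(Phylogeny(dt))
    return out


def _markov_states(tree: Phylogeny, levels: list[str], rate: float, rng) -> dict[str, str]:
    """Symmetric Markov switch among levels along branches; root uniform."""
    states = {}
    k = len(levels)
    root = tree.dendropy_tree.seed_node
    states[id(root)] = rng.integers(0, k)
    for node in tree.dendropy_tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        # k-state symmetric chain: P(stay) = 1/k + (1-1/k) exp(-k rate t)
        p_stay = 1.0 / k + (1 - 1.0 / k) * np.exp(-k * rate * t)
        if rng.uniform() < p_stay:
            states[id(node)] = parent_state
        else:
            others = [s for s in range(k) if s != parent_state]
            states[id(node)] = others[rng.integers(0, k - 1)]
    return {
        leaf.taxon.label: levels[states[id(leaf)]]
        for leaf in tree.dendropy_tree.leaf_node_iter()
    }


def _simulate_covariates(cfg: SimConfig, tree: Phylogeny, rng) -> pd.DataFrame:
    """Covariates on natural scales with phylogenetic structure."""
    species = sorted(tree.tips)
    pc = phylo_correlation(tree, species)
    L = pc.cholesky(1e-10)
    n = len(species)

    def bm(sd, mean=0.0, correlate_with=None, rho=0.0):
        z = L @ rng.standard_normal(n)
        if correlate_with is not None:
            z = rho * correlate_with + np.sqrt(1 - rho**2) * z
        return mean + sd * z

    latent_size = L @ rng.standard_normal(n)  # shared size axis
    cols: dict[str, np.ndarray | list] = {}
    for cov in cfg.covariates:
        if cov == "BM":
            cols[cov] = 10 ** (0.7 + 0.6 * latent_size)          # ~0.3-60 kg
        elif cov == "ECV":
            cols[cov] = 10 ** (1.9 + 0.5 * latent_size
                               + 0.15 * (L @ rng.standard_normal(n)))
        elif cov == "IMI":
            cols[cov] = 10 ** bm(0.05, mean=np.log10(95.0))      # ~75-120
        elif cov == "DIM":
            cols[cov] = 10 ** bm(0.06, mean=np.log10(1.3))
        elif cov in ("FRUIT", "DIET"):
            logits = bm(1.0, mean=0.3)
            cols[cov] = 1 / (1 + np.exp(-logits))
        elif cov in ("TOOL", "EXT", "SOC_LEARN"):
            st = _markov_states(tree, ["0", "1"], cfg.markov_rate, rng)
            cols[cov] = np.array([int(st[s]) for s in species])
        elif cov in CATEGORICAL_COVARIATES:
            levels, _ = CATEGORICAL_COVARIATES[cov]
            st = _markov_states(tree, levels, cfg.markov_rate, rng)
            cols[cov] = [st[s] for s in species]
        else:
            raise KeyError(f"cannot simulate covariate {cov!r}")
    traits = pd.DataFrame(cols, index=species)
    traits.insert(0, "species", species)
    return traits


def simulate_dataset(
    cfg: SimConfig, tree: Phylogeny,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """One complete record-level dataset plus covariates and a truth ledger.

    Species means are x . beta_true + a + u with a ~ MVN(0, sigma_p^2 C) and
    u ~ iid Normal(0, sigma_s^2); each study g of a species adds b_g ~
    Normal(0, tau^2) and sampling noise at se = se_scale / sqrt(n). The
    optional outlier species receives a fixed post-hoc shift. The ledger
    records every latent quantity, including clip events at the response
    bounds.
    """
    rng = np.random.default_rng(cfg.seed)
    traits = _simulate_covariates(cfg, tree, rng)
    species = list(traits.index)
    if cfg.n_species > tree.n_tips:
        raise ValueError("tree has fewer tips than n_species")

    design, tf = transform_covariates(traits, list(cfg.covariates))
    X = np.column_stack([np.ones(len(species))] + [design[c] for c in design.columns])
    colnames = ["intercept"] + list(design.columns)
    beta = np.array([cfg.beta_true.get(c, 0.0) for c in colnames])
    unknown = set(cfg.beta_true) - set(colnames)
    if unknown:
        raise KeyError(f"beta_true names not in the design: {sorted(unknown)}")

    pc = phylo_correlation(tree, species)
    a = cfg.sigma_p * (pc.cholesky(1e-10) @ rng.standard_normal(len(species)))
    u = cfg.sigma_s * rng.standard_normal(len(species))
    mu_species = X @ beta + a + u

    shift_target, shift = (None, 0.0)
    if cfg.outlier_species is not None:
        shift_target, shift = cfg.outlier_species
        if shift_target not in species:
            raise KeyError(f"outlier species {shift_target!r} not a tip")

    lo, hi = (-1.0, 1.0) if cfg.response == "MHI" else (0.0, 1.0)
    rows, b_ledger, clip_events = [], {}, []
    study_counter = 0
    for i, sp in enumerate(species):
        n_studies = int(rng.integers(cfg.studies_per_species[0],
                                     cfg.studies_per_species[1] + 1))
        target_mu = mu_species[i] + (shift if sp == shift_target else 0.0)
        for _ in range(n_studies):
            study_counter += 1
            sid = f"study{study_counter:04d}"
            b_g = cfg.tau * rng.standard_normal()
            b_ledger[sid] = b_g
            n_ind = int(rng.integers(cfg.individuals_per_study[0],
                                     cfg.individuals_per_study[1] + 1))
            se = cfg.se_scale / np.sqrt(n_ind)
            effect = target_mu + b_g + se * rng.standard_normal()
            clipped = np.clip(effect, lo, hi)
            if clipped != effect:
                clip_events.append({"species": sp, "study_id": sid,
                                    "raw": effect, "clipped": clipped})
            rows.append({
                "species": sp, "study_id": sid, "response": cfg.response,
                "effect": clipped, "se": se, "n": n_ind, "task": "tube",
            })
    records = pd.DataFrame(rows)
    truth = {
        "beta": dict(zip(colnames, beta)),
        "sigma_p": cfg.sigma_p, "sigma_s": cfg.sigma_s, "tau": cfg.tau,
        "h2": (cfg.sigma_p**2 /
               (cfg.sigma_p**2 + cfg.sigma_s**2 + cfg.tau**2)
               if cfg.sigma_p + cfg.sigma_s + cfg.tau > 0 else 0.0),
        "a": dict(zip(species, a)), "u": dict(zip(species, u)),
        "b": b_ledger,
        "species_mean": dict(zip(species, mu_species)),
        "outlier": (None if shift_target is None
                    else {"species": shift_target, "shift": shift}),
        "clip_events": clip_events,
        "total_individuals": int(records["n"].sum()),
        "transform": tf,
    }
    return records, traits, truth


def make_missing(
    traits: pd.DataFrame, cfg: SimConfig, seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Mask cells completely at random per configured trait.

    Body mass (the imputation anchor) is never masked. Raises if a fraction
    would leave fewer than 3 observed values for a trait.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    out = traits.copy()
    ledger: dict[str, list[str]] = {}
    for trait, frac in cfg.missing_fraction.items():
        if trait == "BM":
            raise ValueError("refusing to mask body mass, the imputation anchor")
        if trait not in out.columns:
            raise KeyError(f"trait {trait!r} not in table")
        n = len(out)
        k = int(round(frac * n))
        if n - k < 3:
            raise ValueError(f"masking {k}/{n} cells of {trait} leaves < 3 observed")
        idx = rng.choice(n, size=k, replace=False)
        masked = out.index[idx].tolist()
        out.loc[masked, trait] = np.nan
        ledger[trait] = masked
    return out, ledger
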