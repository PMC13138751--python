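"""Hypothesis-battery execution across trees, model comparison and
iterative model reduction.

The eco-evolutionary hypotheses are data, not code: each is a named covariate
set (editable YAML), fitted separately for each response, with and without
*Homo sapiens*, across a set of candidate trees whose per-tree posterior
summaries are averaged. Reduction iteratively removes the weakest
non-credible predictor (smallest |posterior median| / sd), treating a
categorical covariate as removable only when every one of its dummy levels
is non-credible.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .loo import LooResult, compare, psis_loo
from .model import PhyloMetaModel, PhyloMetaResults
from .trees import Phylogeny

log = logging.getLogger(__name__)

__all__ = [
    "HypothesisSet",
    "load_battery",
    "default_battery",
    "reduce_model",
    "run_battery",
    "average_summaries",
]


@dataclass
class HypothesisSet:
    """A named eco-evolutionary hypothesis: the covariates it implicates."""

    name: str
    covariates: list[str]
    applies_to: str = "both"  # MHI, MABSHI or both

    def __post_init__(self):
        if not self.covariates:
            raise ValueError(f"hypothesis {self.name!r} has no covariates")
        if self.applies_to not in ("MHI", "MABSHI", "both"):
            raise ValueError(f"bad applies_to {self.applies_to!r}")

    def applies(self, response: str) -> bool:
        return self.applies_to in ("both", response)


def load_battery(path) -> list[HypothesisSet]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [HypothesisSet(**h) for h in doc["hypotheses"]]


def default_battery() -> list[HypothesisSet]:
    """The packaged battery of eco-evolutionary hypothesis covariate sets."""
    ref = importlib.resources.files("phylohand") / "battery.yaml"
    doc = yaml.safe_load(ref.read_text())
    return [HypothesisSet(**h) for h in doc["hypotheses"]]


# ------------------------------------------------------------------ reduction

def _covariate_groups(results: PhyloMetaResults) -> dict[str, list[str]]:
    """Map each raw covariate to its design-column parameter names."""
    groups: dict[str, list[str]] = {}
    for col, info in results.frame.transform.columns.items():
        groups.setdefault(info["source"], []).append(f"b_{col}")
    return groups


def reduce_model(fit_fn, covariates: list[str]):
    """Iteratively drop non-credible predictors until all remaining are credible.

    ``fit_fn(covariates) -> PhyloMetaResults`` refits the model on a covariate
    subset. At each step the candidate removals are the continuous/binary
    predictors whose 95% CI covers zero and the categorical predictors all of
    whose levels are non-credible; among candidates, the one with the smallest
    strongest-level |median|/sd is removed. Returns the final results, the
    final covariate list (possibly empty: intercept-only), and the ordered
    removal trace.
    """
    current = list(covariates)
    trace: list[dict] = []
    results = fit_fn(current)
    while current:
        summ = results.fixed_effect_summary()
        groups = _covariate_groups(results)
        candidates = []
        for cov in current:
            params = groups.get(cov, [])
            rows = summ.loc[[p for p in params if p in summ.index]]
            if len(rows) == 0 or rows["credible"].any():
                continue
            score = float((rows["median"].abs() / rows["sd"]).max())
            candidates.append((score, cov))
        if not candidates:
            break
        candidates.sort()
        score, worst = candidates[0]
        current = [c for c in current if c != worst]
        trace.append({"removed": worst, "score": score, "remaining": list(current)})
        log.info("reduce_model: removed %s (|median|/sd = %.3f)", worst, score)
        results = fit_fn(current)
    return results, current, trace


# -------------------------------------------------------------------- battery

def average_summaries(summaries: list[pd.DataFrame]) -> pd.DataFrame:
    """Average per-tree posterior summary tables entrywise.

    Numeric columns are averaged across trees; the ``credible`` flag is
    recomputed from the averaged CI bounds (an effect is credible when the
    averaged interval excludes zero).
    """
    if not summaries:
        raise ValueError("no summaries to average")
    base = summaries[0]
    num = base.select_dtypes(float).copy()
    for s in summaries[1:]:
        num += s.loc[base.index, num.columns]
    num /= len(summaries)
    lo_col = [c for c in num.columns if c.startswith("ci_0.02")][0]
    hi_col = [c for c in num.columns if c.startswith("ci_0.97")][0]
    num["credible"] = (num[lo_col] > 0) | (num[hi_col] < 0)
    return num


@dataclass
class BatteryEntry:
    hypothesis: HypothesisSet
    summary: pd.DataFrame
    loo: LooResult
    h2_mean: float
    n_credible: int
    per_tree: list[pd.DataFrame] = field(repr=False, default_factory=list)


def run_battery(
    records: pd.DataFrame,
    traits: pd.DataFrame,
    trees: list[Phylogeny],
    hypotheses: list[HypothesisSet],
    response: str,
    exclude_species: str | None = None,
    seed: int | None = None,
    fit_kwargs: dict | None = None,
    pool_draws: bool = False,
) -> tuple[list[BatteryEntry], pd.DataFrame]:
    """Fit every applicable hypothesis across all trees and compare.

    Per-tree seeds are derived deterministically from the master seed. By
    default, reported values average the per-tree posterior *summaries*
    (set ``pool_draws=True`` to average pointwise log-likelihoods over trees
    before aggregation as well — the summary averaging is unaffected).
    Models with at least one credible predictor are compared by PSIS-LOO;
    the comparison table is empty when none qualifies.
    """
    fit_kwargs = dict(fit_kwargs or {})
    ss = np.random.SeedSequence(seed)
    entries: list[BatteryEntry] = []
    for h_i, hyp in enumerate(hypotheses):
        if not hyp.applies(response):
            continue
        per_tree_summ, per_tree_ll, h2s = [], [], []
        for t_i, tree in enumerate(trees):
            child_seed = int(
                np.random.SeedSequence(
                    entropy=ss.entropy if seed is not None else 0,
                    spawn_key=(h_i, t_i),
                ).generate_state(1)[0] % (2**31)
            )
            model = PhyloMetaModel.from_data(
                records, traits, tree, hyp.covariates, response,
                exclude_species=exclude_species,
            )
            res = model.fit(seed=child_seed, **fit_kwargs)
            per_tree_summ.append(res.summary())
            per_tree_ll.append(res.pointwise_loglik)
            h2s.append(float(res.lynch_h2().mean()))
        summ = average_summaries(per_tree_summ)
        ll = (
            np.mean(per_tree_ll, axis=0) if pool_draws and len(per_tree_ll) > 1
            else per_tree_ll[0]
        )
        loo = psis_loo(ll, name=hyp.name)
        fixed = summ.loc[[i for i in summ.index if i.startswith("b_") and i != "b_intercept"]]
        entries.append(BatteryEntry(
            hypothesis=hyp,
            summary=summ,
            loo=loo,
            h2_mean=float(np.mean(h2s)),
            n_credible=int(fixed["credible"].sum()),
            per_tree=per_tree_summ,
        ))
    contenders = [e for e in entries if e.n_credible > 0]
    if contenders:
        table = compare([e.loo for e in contenders], [e.hypothesis.name for e in contenders])
    else:
        table = pd.DataFrame()
    return entries, table
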