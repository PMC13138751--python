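"""Config-driven orchestration of the full analysis.

A run executes: data acquisition (files or fully synthetic) -> phylogenetic
imputation of missing covariates on the MCC tree -> hypothesis-battery fits
per response and human-inclusion setting across the tree set, averaging
per-tree summaries -> model reduction on the union of credible predictors ->
PSIS-LOO comparison -> phylogenetic outlier test for the focal species ->
fossil prediction on a grafted tree. Every artifact is a CSV/JSON file in
the output directory, and a manifest records the config hash, seeds,
package version and per-stage record counts so a run can be reproduced
exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import load_dataset
from .impute import impute_traits
from .model import PhyloMetaModel
from .predict import phylo_outlier_test, pooled_human_se, predict_fossils
from .selection import default_battery, load_battery, reduce_model, run_battery
from .synthetic import SimConfig, make_missing, simulate_dataset, simulate_trees
from .trees import Phylogeny, graft, mcc_tree, read_trees

log = logging.getLogger(__name__)

__all__ = ["run", "DEFAULT_CONFIG", "load_config"]

DEFAULT_CONFIG: dict = {
    "mode": "synthetic",
    "seed": 0,
    "output_dir": "phylohand_out",
    "responses": ["MHI"],
    "include_humans": "both",        # both | with | without
    "target_species": None,          # focal species for exclusion/outlier test
    "tree_count": 5,
    "battery": None,                 # path to a battery YAML, else packaged default
    "sampler": {"chains": 2, "iterations": 2000, "warmup": 500},
    "fossil_se": None,               # default: pooled SE of the focal species
    "synthetic": {},                 # SimConfig overrides
    "paths": {},                     # records, traits, trees, hominin_tree, hominin_traits
    "alias_map": {},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _child_seed(master: int, *key) -> int:
    import zlib

    parts = [zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in key]
    ss = np.random.SeedSequence((master, *parts))
    return int(ss.generate_state(1)[0] % (2**31))


def _synthetic_fossil_setup(tree: Phylogeny, target: str, traits: pd.DataFrame):
    """Build a grafted tree with a synthetic fossil tip inside a cherry of
    the base tree, plus fossil covariates copied from one cherry member."""
    depths = tree.tip_depths()
    # every rooted binary tree has a cherry (two-leaf clade); take the most
    # recent one so the graft perturbs as little of the tree as possible
    best = None
    for node in tree.dendropy_tree.postorder_node_iter():
        kids = node.child_nodes()
        if len(kids) == 2 and all(k.is_leaf() for k in kids):
            a, b = (k.taxon.label for k in kids)
            h = max(kids[0].edge.length or 0.0, kids[1].edge.length or 0.0)
            if h > 0 and (best is None or h < best[2]):
                best = (a, b, h)
    if best is None:
        raise RuntimeError("no cherry with positive depth found for grafting")
    a, b, h = best
    addon = Phylogeny.from_newick(
        f"(({a.replace(' ', '_')}:{0.5 * h:.9f},SynthFossil:{0.4 * h:.9f})"
        f":{0.5 * h:.9f},{b.replace(' ', '_')}:{h:.9f});"
    )
    grafted = graft(tree, addon, [a, b])
    fossil_traits = traits.loc[[a]].copy()
    fossil_traits.index = ["SynthFossil"]
    fossil_traits["species"] = fossil_traits.index
    return grafted, fossil_traits


def run(cfg: dict, outdir: str | Path | None = None) -> Path:
    """Execute the full pipeline and return the output directory."""
    cfg = {**json.loads(json.dumps(DEFAULT_CONFIG)), **cfg}
    seed = int(cfg["seed"])
    outdir = Path(outdir or cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "stages": {},
        "artifacts": [],
    }

    def save(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, index=False)
        manifest["artifacts"].append(name)

    stage = "acquire"
    try:
        if cfg["mode"] == "synthetic":
            sim = SimConfig(seed=seed, **cfg["synthetic"])
            trees = simulate_trees(sim, n_trees=int(cfg["tree_count"]))
            mcc = mcc_tree(trees)
            records, traits, truth = simulate_dataset(sim, mcc)
            target = cfg["target_species"] or traits.index[0]
            if sim.missing_fraction:
                traits, _ = make_missing(traits, sim, seed=_child_seed(seed, "mask"))
            with open(outdir / "truth.json", "w") as fh:
                json.dump({k: v for k, v in truth.items() if k != "transform"},
                          fh, indent=2, default=str)
            manifest["artifacts"].append("truth.json")
        else:
            paths = cfg["paths"]
            records, traits = load_dataset(paths["records"], paths["traits"],
                                           cfg.get("alias_map") or None)
            trees = read_trees(paths["trees"])[: int(cfg["tree_count"])]
            mcc = mcc_tree(trees)
            target = cfg["target_species"] or "Homo sapiens"
        manifest["stages"][stage] = {
            "n_records": len(records), "n_species": traits.shape[0],
            "n_trees": len(trees), "target_species": target,
        }
        log.info("%s: %d records, %d species, %d trees", stage,
                 len(records), traits.shape[0], len(trees))

        stage = "impute"
        imput_targets = [t for t in ("IMI", "DIM")
                         if t in traits.columns and traits[t].isna().any()]
        if imput_targets:
            traits, report = impute_traits(traits, mcc, tuple(imput_targets))
            save(report, "imputation_report.csv")
            manifest["stages"][stage] = {"n_imputed": len(report)}
        else:
            manifest["stages"][stage] = {"n_imputed": 0}

        battery = (load_battery(cfg["battery"]) if cfg["battery"]
                   else default_battery())
        battery = [h for h in battery
                   if all(c in traits.columns for c in h.covariates)]
        sampler = cfg["sampler"]
        inclusion = {"both": [False, True], "with": [False], "without": [True]}[
            cfg["include_humans"]]

        for response in cfg["responses"]:
            for exclude in inclusion:
                tag = f"{response}_{'excl' if exclude else 'incl'}"
                stage = f"battery_{tag}"
                excl = target if exclude else None
                if exclude and target not in set(
                        records.loc[records["response"] == response, "species"]):
                    manifest["stages"][stage] = {"skipped": "target absent"}
                    continue
                entries, table = run_battery(
                    records, traits, trees, battery, response,
                    exclude_species=excl,
                    seed=_child_seed(seed, "battery", tag),
                    fit_kwargs=sampler,
                )
                rows = []
                for e in entries:
                    s = e.summary.reset_index()
                    s.insert(0, "hypothesis", e.hypothesis.name)
                    rows.append(s)
                save(pd.concat(rows, ignore_index=True), f"battery_{tag}.csv")
                if len(table):
                    save(table.reset_index(), f"loo_comparison_{tag}.csv")
                manifest["stages"][stage] = {
                    "n_hypotheses": len(entries),
                    "n_with_credible": int(sum(e.n_credible > 0 for e in entries)),
                }

                stage = f"reduce_{tag}"
                credible_covs: list[str] = []
                for e in entries:
                    summ = e.summary
                    for col in summ.index:
                        if not col.startswith("b_") or col == "b_intercept":
                            continue
                        if summ.loc[col, "credible"]:
                            name = col[2:].split(":", 1)[0]
                            if name not in credible_covs:
                                credible_covs.append(name)
                credible_covs = [c for c in credible_covs if c in traits.columns]
                start_covs = credible_covs or [battery[0].covariates[0]]

                def fit_fn(covs, _excl=excl, _resp=response, _tag=tag):
                    model = PhyloMetaModel.from_data(
                        records, traits, mcc, covs, _resp, exclude_species=_excl)
                    return model.fit(seed=_child_seed(seed, "reduce", _tag), **sampler)

                reduced_res, final_covs, trace = reduce_model(fit_fn, start_covs)
                save(reduced_res.summary().reset_index(), f"reduced_{tag}.csv")
                manifest["stages"][stage] = {
                    "start": start_covs, "final": final_covs,
                    "trace": [t["removed"] for t in trace],
                }

                if exclude:
                    stage = f"outlier_{tag}"
                    sub = records[(records["response"] == response)
                                  & (records["species"] == target)]
                    obs = float(np.average(sub["effect"], weights=1 / sub["se"] ** 2))
                    se_t = pooled_human_se(records, response, target)
                    pred = phylo_outlier_test(
                        reduced_res, mcc, target, traits.loc[target],
                        se_t, observed=obs,
                        seed=_child_seed(seed, "outlier", tag),
                    )
                    save(pd.DataFrame([pred.to_row()]), f"outlier_{tag}.csv")
                    manifest["stages"][stage] = {"outlier_flag": pred.outlier_flag}
                else:
                    stage = f"fossils_{tag}"
                    paths = cfg["paths"]
                    if cfg["mode"] == "files" and paths.get("hominin_tree"):
                        addon = read_trees(paths["hominin_tree"])[0]
                        fossil_traits = pd.read_csv(paths["hominin_traits"]
                                                    ).set_index("species", drop=False)
                        shared = sorted(set(addon.tips) & set(mcc.tips))
                        grafted = graft(mcc, addon, shared)
                        fossils = fossil_traits.loc[
                            [s for s in fossil_traits.index if s not in mcc.tips]]
                    else:
                        grafted, fossils = _synthetic_fossil_setup(mcc, target, traits)
                    se_f = cfg["fossil_se"] or pooled_human_se(records, response, target)
                    preds = predict_fossils(
                        reduced_res, grafted, fossils, se_f,
                        seed=_child_seed(seed, "fossils", tag),
                    )
                    save(pd.DataFrame([p.to_row() for p in preds]),
                         f"fossil_predictions_{tag}.csv")
                    manifest["stages"][stage] = {"n_fossils": len(preds)}
    except Exception as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
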