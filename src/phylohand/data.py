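"""Record-level handedness data and species covariates.

The meta-analytic unit is one published tube-task measurement of MHI (mean
handedness index, direction, in [-1, 1]) or MABSHI (mean absolute handedness
index, strength, in [0, 1]) for one species, with its standard error and
sample size. Species covariates follow the comparative literature: BM (body
mass, kg), ECV (endocranial volume, cm^3), FRUIT / DIET (diet proportions),
IMI (intermembral index), DIM (body-mass sexual dimorphism), TOOL, SUBS
(substrate), SOC_SYS (social system), CL (intrasexual competition level),
EXT (extractive foraging), SOC_LEARN (social learning).

Continuous covariates enter models log10-transformed and z-scored; diet
proportions are logit-transformed then z-scored; categorical covariates are
dummy-coded against declared reference levels (arboreal, solitary, absence).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "RECORD_COLUMNS",
    "CONTINUOUS_COVARIATES",
    "PROPORTION_COVARIATES",
    "CATEGORICAL_COVARIATES",
    "BINARY_COVARIATES",
    "CovariateTransform",
    "ModelFrame",
    "load_dataset",
    "validate_records",
    "transform_covariates",
    "build_model_frame",
]

RECORD_COLUMNS = ["species", "study_id", "response", "effect", "se", "n", "task"]

CONTINUOUS_COVARIATES = ["BM", "ECV", "IMI", "DIM"]
PROPORTION_COVARIATES = ["FRUIT", "DIET"]
BINARY_COVARIATES = ["TOOL", "EXT", "SOC_LEARN"]
# categorical covariate -> (ordered levels, reference level)
CATEGORICAL_COVARIATES = {
    "SUBS": (["arboreal", "both", "terrestrial"], "arboreal"),
    "SOC_SYS": (["solitary", "pair", "group"], "solitary"),
    "CL": (["low", "medium", "high"], "low"),
}

RESPONSE_BOUNDS = {"MHI": (-1.0, 1.0), "MABSHI": (0.0, 1.0)}


class SchemaError(ValueError):
    """A required column is missing or a value violates the schema."""


def _normalize_species(s: pd.Series, alias_map: dict[str, str] | None) -> pd.Series:
    from .trees import normalize_label

    out = s.astype(str).map(normalize_label)
    if alias_map:
        amap = {normalize_label(k): normalize_label(v) for k, v in alias_map.items()}
        out = out.map(lambda x: amap.get(x, x))
    return out


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check record invariants: se > 0, n >= 1, effects within response bounds."""
    if (records["se"] <= 0).any():
        bad = records.loc[records["se"] <= 0, "species"].tolist()
        raise SchemaError(f"non-positive standard errors for {bad}")
    if (records["n"] < 1).any():
        raise SchemaError("sample sizes below 1")
    for resp, (lo, hi) in RESPONSE_BOUNDS.items():
        sub = records[records["response"] == resp]
        out = sub[(sub["effect"] < lo) | (sub["effect"] > hi)]
        if len(out):
            raise SchemaError(
                f"{resp} effects outside [{lo}, {hi}] for {out['species'].tolist()}"
            )
    return records


def load_dataset(
    records_csv,
    traits_csv,
    alias_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and standardize the record-level CSV and the species-covariate CSV.

    Rows that are not tube-task measurements, or that lack an effect size or
    standard error, are dropped with a logged count. Duplicate
    (study, species, response) rows — probable double-counting across the two
    source compilations — are dropped keeping the first, with a logged count.
    """
    records = pd.read_csv(records_csv)
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"records CSV missing required columns: {missing}")
    records["species"] = _normalize_species(records["species"], alias_map)

    n0 = len(records)
    records = records[records["task"].astype(str).str.strip().str.lower() == "tube"]
    n_task = n0 - len(records)
    records = records.dropna(subset=["effect", "se"])
    n_na = n0 - n_task - len(records)
    dup = records.duplicated(subset=["study_id", "species", "response"], keep="first")
    n_dup = int(dup.sum())
    records = records[~dup].reset_index(drop=True)
    if n_task or n_na or n_dup:
        log.info(
            "load_dataset: dropped %d non-tube, %d missing effect/se, %d duplicate rows",
            n_task, n_na, n_dup,
        )
    if len(records) == 0:
        raise SchemaError("no records survived filtering")
    records["n"] = records["n"].astype(int)
    validate_records(records)

    traits = pd.read_csv(traits_csv)
    if "species" not in traits.columns:
        raise SchemaError("traits CSV missing 'species' column")
    traits["species"] = _normalize_species(traits["species"], alias_map)
    traits = traits.set_index("species", drop=False)
    return records, traits


@dataclass
class CovariateTransform:
    """Per-column transform constants, reusable on new species (fossils).

    ``columns`` maps design-column name -> dict with keys ``source`` (raw
    trait), ``kind`` ("log10", "logit", "dummy", "binary"), ``mean``/``sd``
    (z-scoring constants on the transformed scale) and, for dummies, the
    ``level`` it indicates.
    """

    columns: dict[str, dict] = field(default_factory=dict)
    covariates: list[str] = field(default_factory=list)
    clamp_eps: float = 1e-3

    def apply(self, traits: pd.DataFrame) -> pd.DataFrame:
        """Transform a raw trait table with the stored constants."""
        out = {}
        for col, info in self.columns.items():
            src = info["source"]
            if src not in traits.columns:
                raise KeyError(f"trait {src!r} required by the design is missing")
            x = traits[src]
            kind = info["kind"]
            if kind == "log10":
                vals = x.astype(float)
                if (vals <= 0).any():
                    bad = traits.loc[vals <= 0, "species"].tolist() if "species" in traits else vals.index[vals <= 0].tolist()
                    raise ValueError(f"non-positive {src} for {bad}: cannot log10")
                z = (np.log10(vals) - info["mean"]) / info["sd"]
            elif kind == "logit":
                vals = x.astype(float).clip(self.clamp_eps, 1 - self.clamp_eps)
                z = (np.log(vals / (1 - vals)) - info["mean"]) / info["sd"]
            elif kind == "binary":
                z = x.astype(float)
            elif kind == "dummy":
                z = (x.astype(str) == info["level"]).astype(float)
            else:  # pragma: no cover
                raise ValueError(kind)
            out[col] = np.asarray(z)
        return pd.DataFrame(out, index=traits.index)

    def inverse(self, design: pd.DataFrame) -> pd.DataFrame:
        """Invert continuous columns back to raw scale (dummies pass through)."""
        out = {}
        for col in design.columns:
            info = self.columns[col]
            z = design[col].astype(float)
            if info["kind"] == "log10":
                out[info["source"]] = 10 ** (z * info["sd"] + info["mean"])
            elif info["kind"] == "logit":
                t = z * info["sd"] + info["mean"]
                out[info["source"]] = 1 / (1 + np.exp(-t))
            else:
                out[col] = z
        return pd.DataFrame(out, index=design.index)

    def to_json(self) -> str:
        return json.dumps(
            {"columns": self.columns, "covariates": self.covariates,
             "clamp_eps": self.clamp_eps},
            indent=2,
        )

    @classmethod
    def from_json(cls, s: str) -> "CovariateTransform":
        d = json.loads(s)
        return cls(columns=d["columns"], covariates=d["covariates"],
                   clamp_eps=d["clamp_eps"])


def transform_covariates(
    traits: pd.DataFrame,
    covariates: list[str],
    clamp_eps: float | None = None,
    max_n: int | None = None,
) -> tuple[pd.DataFrame, CovariateTransform]:
    """Build standardized design columns from raw species covariates.

    Continuous traits are log10-transformed then z-scored on the supplied
    analysis set; proportions are clamped to [eps, 1-eps] (eps = 1/(2 max n)
    when a sample-size ceiling is given), logit-transformed, then z-scored;
    categorical traits become 0/1 dummies against their reference level.
    Returns the design columns and the reusable transform.
    """
    unknown = [
        c for c in covariates
        if c not in CONTINUOUS_COVARIATES + PROPORTION_COVARIATES + BINARY_COVARIATES
        and c not in CATEGORICAL_COVARIATES
    ]
    if unknown:
        raise KeyError(f"unknown covariates: {unknown}")
    if clamp_eps is None:
        clamp_eps = 1.0 / (2 * max_n) if max_n else 1e-3

    tf = CovariateTransform(covariates=list(covariates), clamp_eps=clamp_eps)
    for cov in covariates:
        if cov not in traits.columns:
            raise KeyError(f"covariate {cov!r} not present in traits table")
        if cov in CONTINUOUS_COVARIATES:
            vals = traits[cov].astype(float)
            if (vals <= 0).any():
                bad = traits.index[vals <= 0].tolist()
                raise ValueError(f"non-positive {cov} for {bad}: cannot log10")
            t = np.log10(vals)
            sd = float(t.std(ddof=0))
            tf.columns[cov] = {
                "source": cov, "kind": "log10", "mean": float(t.mean()),
                "sd": sd if sd > 0 else 1.0,
            }
        elif cov in PROPORTION_COVARIATES:
            vals = traits[cov].astype(float).clip(clamp_eps, 1 - clamp_eps)
            t = np.log(vals / (1 - vals))
            sd = float(t.std(ddof=0))
            tf.columns[cov] = {
                "source": cov, "kind": "logit", "mean": float(t.mean()),
                "sd": sd if sd > 0 else 1.0,
            }
        elif cov in BINARY_COVARIATES:
            tf.columns[cov] = {"source": cov, "kind": "binary"}
        else:
            levels, ref = CATEGORICAL_COVARIATES[cov]
            present = set(traits[cov].astype(str))
            for lev in levels:
                if lev == ref or lev not in present:
                    continue
                tf.columns[f"{cov}:{lev}"] = {
                    "source": cov, "kind": "dummy", "level": lev,
                }
    design = tf.apply(traits)
    return design, tf


@dataclass
class ModelFrame:
    """Everything the sampler needs, with record -> species/study index maps.

    ``X`` has one row per record (intercept first); ``species_design`` holds
    one row per species in ``species`` order, used for species-level estimates
    and prediction.
    """

    response: str
    y: np.ndarray
    se: np.ndarray
    X: np.ndarray
    colnames: list[str]
    species: list[str]
    species_idx: np.ndarray
    studies: list[str]
    study_idx: np.ndarray
    species_design: np.ndarray
    transform: CovariateTransform
    records: pd.DataFrame

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_species(self) -> int:
        return len(self.species)


def build_model_frame(
    records: pd.DataFrame,
    traits: pd.DataFrame,
    covariates: list[str],
    response: str,
    exclude_species: str | None = None,
    study_group: str = "study",
) -> ModelFrame:
    """Assemble the design matrix and grouping indices for one model.

    Excluding a species removes its records *and* drops it from the species
    index (and hence from the phylogenetic covariance); standardization
    constants are recomputed on the remaining analysis set.
    """
    if response not in RESPONSE_BOUNDS:
        raise ValueError(f"unknown response {response!r}")
    sub = records[records["response"] == response].copy()
    if exclude_species is not None:
        from .trees import normalize_label

        excl = normalize_label(exclude_species)
        if excl not in set(sub["species"]):
            raise KeyError(f"cannot exclude {excl!r}: not present in the data")
        sub = sub[sub["species"] != excl]
    if len(sub) == 0:
        raise ValueError("no records for this response after filtering")
    sub = sub.reset_index(drop=True)

    species = sorted(sub["species"].unique())
    traits_sub = traits.loc[species]
    design_sp, tf = transform_covariates(
        traits_sub, covariates, max_n=int(sub["n"].max())
    )

    sp_pos = {s: i for i, s in enumerate(species)}
    species_idx = sub["species"].map(sp_pos).to_numpy()
    if study_group == "study":
        key = sub["study_id"].astype(str)
    elif study_group == "study_species":
        key = sub["study_id"].astype(str) + "::" + sub["species"]
    else:
        raise ValueError(f"unknown study grouping {study_group!r}")
    studies = sorted(key.unique())
    st_pos = {s: i for i, s in enumerate(studies)}
    study_idx = key.map(st_pos).to_numpy()

    sp_design = np.column_stack(
        [np.ones(len(species))] + [design_sp[c].to_numpy() for c in design_sp.columns]
    )
    X = sp_design[species_idx]
    colnames = ["intercept"] + list(design_sp.columns)
    return ModelFrame(
        response=response,
        y=sub["effect"].to_numpy(float),
        se=sub["se"].to_numpy(float),
        X=X,
        colnames=colnames,
        species=species,
        species_idx=species_idx,
        studies=studies,
        study_idx=study_idx,
        species_design=sp_design,
        transform=tf,
        records=sub,
    )
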