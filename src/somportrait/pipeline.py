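"""End-to-end pipeline: preprocess -> SOM -> spots -> strata -> mining -> phenotypes.

Each stage reads its inputs either from the in-memory ``state`` dict (when
run as part of ``run_pipeline``) or from the artifacts a previous stage
wrote into the output directory (when run individually through the CLI),
so that stage-by-stage runs compose to the same result as ``run-all``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as spio
from .enrichment import enrich_spots
from .phenotype import correlation_map, spot_regression, type_enrichment
from .preprocess import center_genes, log2_transform, quantile_normalize
from .som import SOMPortrait
from .spots import SpotDetector, SpotModule, spot_correlation_network, spot_profile_matrix
from .stratify import (TypeStratifier, pairwise_correlation,
                       similarity_network, validate_types)
from .synthetic import CohortConfig, generate_cohort

log = logging.getLogger("somportrait")

STAGES = ("preprocess", "som", "spots", "stratification", "enrichment",
          "phenotypes")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of a full portrayal run (YAML-serializable)."""

    # inputs; expression may be omitted when simulate=True
    expression: str | None = None
    phenotypes: str | None = None
    gene_sets: str | None = None
    simulate: bool = False
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides

    # preprocessing
    log2: bool = False
    quantile: bool = True
    center: bool = True

    # SOM
    grid_rows: int = 16
    grid_cols: int = 16
    n_epochs: int = 20

    # spots
    top_quantile: float = 0.975
    ridge_quantile: float = 0.60
    min_units: int = 4
    max_spots: int = 25

    # stratification
    n_types: int | None = None
    n_subtypes: int = 3
    z_threshold: float = 1.0
    min_cpat_count: int = 15
    r_threshold: float = 0.5
    validation_rounds: int = 10

    seed: int = 0
    out_dir: str = "somportrait_out"

    def validate(self) -> None:
        if not self.simulate and self.expression is None:
            raise ValueError("either an expression path or simulate=true "
                             "is required")
        for name in ("top_quantile", "ridge_quantile"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not 0.0 < self.z_threshold < 10.0:
            raise ValueError("z_threshold out of range (0, 10)")
        if min(self.grid_rows, self.grid_cols, self.n_epochs) < 1:
            raise ValueError("grid dimensions and epochs must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory for the stochastic stages")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    model: SOMPortrait
    spots: list[SpotModule]
    assignment: pd.DataFrame
    enrichment: pd.DataFrame | None
    phenotype_maps: dict
    summary: dict


# ------------------------------- stages -------------------------------- #

def _out(config: PipelineConfig) -> Path:
    d = Path(config.out_dir)
    d.mkdir(parents=True, exist_ok=True)
    return d


def stage_simulate(config: PipelineConfig, state: dict) -> dict:
    overrides = dict(config.cohort)
    overrides.setdefault("seed", config.seed)
    cc = CohortConfig(**overrides)
    expr, phen, truth = generate_cohort(cc)
    d = _out(config)
    spio.write_expression(expr, d / "expression.tsv")
    spio.write_phenotypes(phen, d / "phenotypes.csv")
    spio.write_ground_truth(truth, d / "ground_truth.json")
    with open(d / "cohort_config.yaml", "w") as fh:
        cfg = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
               for k, v in dataclasses.asdict(cc).items()}
        yaml.safe_dump(cfg, fh, sort_keys=True)
    state.update(expression=expr, phenotypes=phen, truth=truth)
    log.info("simulate: %d genes x %d samples, %d modules",
             cc.n_genes, cc.n_samples, cc.n_modules)
    state.setdefault("summary", {})["data"] = {
        "n_genes": int(expr.shape[0]), "n_samples": int(expr.shape[1]),
        "simulated": True, "n_planted_modules": cc.n_modules,
    }
    return state


def _load_expression(config: PipelineConfig, state: dict) -> pd.DataFrame:
    if "expression" in state:
        return state["expression"]
    path = config.expression or Path(config.out_dir) / "expression.tsv"
    expr = spio.read_expression(path)
    state["expression"] = expr
    return expr


def _load_phenotypes(config: PipelineConfig, state: dict) -> pd.DataFrame | None:
    if "phenotypes" in state:
        return state["phenotypes"]
    path = config.phenotypes
    if path is None:
        cand = Path(config.out_dir) / "phenotypes.csv"
        path = cand if cand.exists() else None
    if path is None:
        return None
    phen = spio.read_phenotypes(path)
    state["phenotypes"] = phen
    return phen


def stage_preprocess(config: PipelineConfig, state: dict) -> dict:
    expr = _load_expression(config, state)
    if "summary" not in state:
        state["summary"] = {"data": {
            "n_genes": int(expr.shape[0]), "n_samples": int(expr.shape[1]),
            "simulated": False,
        }}
    if config.log2:
        expr = log2_transform(expr)
    if config.quantile:
        expr = quantile_normalize(expr)
    if config.center:
        expr = center_genes(expr)
    d = _out(config)
    spio.write_expression(expr, d / "expression_preprocessed.tsv")
    state["preprocessed"] = expr
    log.info("preprocess: log2=%s quantile=%s center=%s",
             config.log2, config.quantile, config.center)
    state["summary"]["preprocess"] = {
        "log2": config.log2, "quantile": config.quantile,
        "center": config.center,
    }
    return state


def _load_preprocessed(config: PipelineConfig, state: dict) -> pd.DataFrame:
    if "preprocessed" in state:
        return state["preprocessed"]
    path = Path(config.out_dir) / "expression_preprocessed.tsv"
    if not path.exists():
        raise PipelineError("som", "no preprocessed matrix; run the "
                            "preprocess stage first")
    X = spio.read_expression(path)
    state["preprocessed"] = X
    return X


def stage_som(config: PipelineConfig, state: dict) -> dict:
    X = _load_preprocessed(config, state)
    model = SOMPortrait(
        grid_rows=config.grid_rows, grid_cols=config.grid_cols,
        n_epochs=config.n_epochs, random_state=config.seed,
    ).fit(X)
    spio.save_model(model, Path(config.out_dir) / "som_model")
    state["model"] = model
    log.info("som: %dx%d grid, %d epochs, final QE %.3f",
             config.grid_rows, config.grid_cols, config.n_epochs,
             model.quantization_errors_[-1])
    state.setdefault("summary", {})["som"] = {
        "grid_rows": config.grid_rows, "grid_cols": config.grid_cols,
        "n_epochs": config.n_epochs,
        "quantization_error": round(float(model.quantization_errors_[-1]), 6),
    }
    return state


def _load_model(config: PipelineConfig, state: dict) -> SOMPortrait:
    if "model" in state:
        return state["model"]
    d = Path(config.out_dir) / "som_model"
    if not d.exists():
        raise PipelineError("spots", "no trained model; run the train stage")
    model = spio.load_model(d)
    state["model"] = model
    return model


def stage_spots(config: PipelineConfig, state: dict) -> dict:
    model = _load_model(config, state)
    det = SpotDetector(
        top_quantile=config.top_quantile, ridge_quantile=config.ridge_quantile,
        min_units=config.min_units, max_spots=config.max_spots,
    ).fit(model)
    spots = det.spots_
    d = _out(config)
    rows = [{"spot_id": s.spot_id, "gene_id": g} for s in spots for g in s.genes]
    pd.DataFrame(rows, columns=["spot_id", "gene_id"]).to_csv(
        d / "spot_genes.tsv", sep="\t", index=False)
    spot_profile_matrix(spots).to_csv(d / "spot_profiles.tsv", sep="\t",
                                      index_label="sample_id")
    units = [{"spot_id": s.spot_id, "row": r, "col": c}
             for s in spots for (r, c) in s.units]
    pd.DataFrame(units, columns=["spot_id", "row", "col"]).to_csv(
        d / "spot_units.tsv", sep="\t", index=False)
    if len(spots) >= 2:
        G = spot_correlation_network(spots, r_threshold=config.r_threshold)
        edges = [{"source": u, "target": v, "r": round(dd["r"], 6)}
                 for u, v, dd in G.edges(data=True)]
        pd.DataFrame(edges, columns=["source", "target", "r"]).to_csv(
            d / "spot_network.tsv", sep="\t", index=False)
    state["spots"] = spots
    log.info("spots: %d detected (threshold %.3f)", len(spots), det.threshold_)
    state.setdefault("summary", {})["spots"] = {
        "n_spots": len(spots),
        "spot_ids": [s.spot_id for s in spots],
        "genes_per_spot": {s.spot_id: s.n_genes for s in spots},
        "top_quantile": config.top_quantile,
        "ridge_quantile": config.ridge_quantile,
    }
    return state


def _load_spot_profiles(config: PipelineConfig, state: dict) -> pd.DataFrame:
    if "spots" in state:
        return spot_profile_matrix(state["spots"])
    path = Path(config.out_dir) / "spot_profiles.tsv"
    if not path.exists():
        raise PipelineError("stratify", "no spot profiles; run the spots stage")
    return pd.read_csv(path, sep="\t", index_col=0)


def stage_stratify(config: PipelineConfig, state: dict) -> dict:
    model = _load_model(config, state)
    profiles = _load_spot_profiles(config, state)
    portraits = model.sample_portrait_matrix()
    strat = TypeStratifier(
        n_types=config.n_types, n_subtypes=config.n_subtypes,
        z_threshold=config.z_threshold, min_cpat_count=config.min_cpat_count,
        random_state=config.seed,
    ).fit(portraits, profiles)
    assignment = strat.assignment_
    mis = np.nan
    if assignment["type"].nunique() >= 2:
        mis = validate_types(portraits, assignment["type"],
                             n_rounds=config.validation_rounds,
                             seed=config.seed)
    d = _out(config)
    assignment.to_csv(d / "type_assignment.csv", index_label="sample_id")
    corr = pairwise_correlation(portraits)
    corr.round(4).to_csv(d / "sample_correlation.tsv", sep="\t")
    G = similarity_network(corr, threshold=config.r_threshold)
    pd.DataFrame(
        [{"source": u, "target": v, "r": round(dd["r"], 4)}
         for u, v, dd in G.edges(data=True)],
        columns=["source", "target", "r"],
    ).to_csv(d / "sample_similarity_network.tsv", sep="\t", index=False)
    strat.cpat_table_.to_csv(d / "cpat_table.tsv", sep="\t", index=False)
    state["stratifier"] = strat
    state["assignment"] = assignment
    log.info("stratify: %d cPATs (%d major), k=%d, misclassification %.3f",
             len(strat.cpat_table_), int(strat.cpat_table_["major"].sum()),
             strat.n_types_, mis)
    state.setdefault("summary", {})["stratification"] = {
        "n_cpats": int(len(strat.cpat_table_)),
        "n_major_cpats": int(strat.cpat_table_["major"].sum()),
        "n_types": int(strat.n_types_),
        "n_subtypes": int(assignment["subtype"].nunique()),
        "type_counts": assignment["type"].value_counts().sort_index()
        .to_dict(),
        "misclassification": None if np.isnan(mis) else round(float(mis), 4),
    }
    return state


def stage_enrich(config: PipelineConfig, state: dict) -> dict:
    summary = state.setdefault("summary", {})
    if config.gene_sets is None:
        summary["enrichment"] = {"n_gene_sets": 0, "skipped": True}
        return state
    model = _load_model(config, state)
    if "spots" not in state:
        raise PipelineError("enrich", "no spots in state; run spots first "
                            "in the same invocation or use run-all")
    gene_sets = spio.read_gmt(config.gene_sets)
    table = enrich_spots(state["spots"], gene_sets, model.gene_ids_)
    table.to_csv(Path(config.out_dir) / "enrichment.tsv", sep="\t",
                 index=False)
    n_sig = int((table["fdr"] < 0.05).sum()) if len(table) else 0
    log.info("enrich: %d gene sets, %d significant (FDR<0.05)",
             len(gene_sets), n_sig)
    summary["enrichment"] = {
        "n_gene_sets": len(gene_sets),
        "n_tests": int(len(table)),
        "n_significant_fdr05": n_sig,
    }
    return state


def _feature_kind(col: pd.Series) -> str:
    vals = col.dropna().unique()
    if col.dtype == object or str(col.dtype) == "category":
        return "categorical"
    if set(np.unique(vals.astype(float))) <= {0.0, 1.0}:
        return "binary"
    return "continuous"


def stage_phenotype(config: PipelineConfig, state: dict) -> dict:
    summary = state.setdefault("summary", {})
    phen = _load_phenotypes(config, state)
    if phen is None:
        summary["phenotypes"] = {"n_features": 0, "skipped": True}
        return state
    model = _load_model(config, state)
    maps: dict = {}
    overview = []
    for col in phen.columns:
        kind = _feature_kind(phen[col])
        try:
            cm = correlation_map(model, phen[col], kind=kind)
        except ValueError as e:
            log.warning("phenotype %s skipped: %s", col, e)
            continue
        for feat, m in (cm.items() if isinstance(cm, dict)
                        else [(col, cm)]):
            maps[feat] = m
            overview.append({
                "feature": feat, "kind": kind,
                "argmax_row": m.argmax_unit[0], "argmax_col": m.argmax_unit[1],
                "r_max": round(m.r_max, 4), "n_samples": m.n_samples,
            })
    d = _out(config)
    pd.DataFrame(overview).to_csv(d / "phenotype_overview.tsv", sep="\t",
                                  index=False)
    for feat, m in maps.items():
        pd.DataFrame(m.grid).round(5).to_csv(
            d / f"phenotype_map_{feat.replace('=', '_')}.csv", index=False,
            header=False)

    enr = None
    if "assignment" in state:
        cats = [c for c in phen.columns
                if _feature_kind(phen[c]) in ("binary", "categorical")]
        tables = []
        for c in cats:
            try:
                t = type_enrichment(state["assignment"]["type"], phen[c])
                t.insert(0, "feature", c)
                tables.append(t)
            except ValueError:
                continue
        if tables:
            enr = pd.concat(tables, ignore_index=True)
            enr.to_csv(d / "phenotype_type_enrichment.tsv", sep="\t",
                       index=False)

    reg = None
    if "spots" in state and len(state["spots"]) > 0:
        numeric = phen.select_dtypes(include=[np.number])
        if numeric.shape[1] >= 1:
            reg = spot_regression(spot_profile_matrix(state["spots"]), numeric)
            reg.to_csv(d / "spot_phenotype_regression.tsv", sep="\t",
                       index=False)

    state["phenotype_maps"] = maps
    log.info("phenotypes: %d correlation maps", len(maps))
    summary["phenotypes"] = {
        "n_features": int(phen.shape[1]),
        "n_maps": len(maps),
        "type_enrichment_rows": 0 if enr is None else int(len(enr)),
        "regression_rows": 0 if reg is None else int(len(reg)),
    }
    return state


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order and write a JSON summary.

    Deterministic given ``config.seed``; the summary contains one block
    per stage plus the full parameter set.
    """
    config.validate()
    state: dict = {}
    if config.simulate:
        stage_simulate(config, state)
    stage_preprocess(config, state)
    stage_som(config, state)
    stage_spots(config, state)
    stage_stratify(config, state)
    stage_enrich(config, state)
    stage_phenotype(config, state)

    summary = state["summary"]
    summary["parameters"] = dataclasses.asdict(config)
    with open(Path(config.out_dir) / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return PipelineResult(
        model=state["model"],
        spots=state["spots"],
        assignment=state["assignment"],
        enrichment=None,
        phenotype_maps=state.get("phenotype_maps", {}),
        summary=summary,
    )
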