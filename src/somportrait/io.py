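"""Plain-text I/O: expression TSV, phenotype CSV, GMT gene sets, model dirs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .enrichment import GeneSet
from .som import SOMPortrait
from .synthetic import GroundTruth

__all__ = [
    "read_expression", "write_expression",
    "read_phenotypes", "write_phenotypes",
    "read_gmt", "write_gmt",
    "save_model", "load_model",
    "write_ground_truth",
]


class FormatError(ValueError):
    """Raised when an input file does not parse."""


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV with gene ids in the first column."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise FormatError(f"{path}: duplicate gene ids, e.g. {dups}")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    if df.isna().to_numpy().any():
        raise FormatError(f"{path}: missing expression values")
    try:
        df = df.astype(float)
    except ValueError as e:
        raise FormatError(f"{path}: non-numeric expression value ({e})") from e
    return df


def write_expression(X: pd.DataFrame, path) -> None:
    X.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_phenotypes(path) -> pd.DataFrame:
    """Samples x features CSV, sample ids in the first column.

    Missing cells are parsed as NaN; the total count is reported via the
    DataFrame attr ``n_missing``.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    df.attrs["n_missing"] = int(df.isna().to_numpy().sum())
    return df


def write_phenotypes(P: pd.DataFrame, path) -> None:
    P.to_csv(path, index_label="sample_id")


def read_gmt(path) -> list[GeneSet]:
    """Standard GMT: name TAB description TAB gene TAB gene ..."""
    path = Path(path)
    sets, bad = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                bad.append(ln)
                continue
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if not genes:
                bad.append(ln)
                continue
            sets.append(GeneSet(name=name, genes=frozenset(genes), source=desc))
    if bad:
        raise FormatError(
            f"{path}: malformed GMT lines (need name, description and >=1 "
            f"gene): lines {bad}"
        )
    return sets


def write_gmt(gene_sets, path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.source or "na",
                                *sorted(gs.genes)]) + "\n")


# ------------------------------- model --------------------------------- #

def save_model(model: SOMPortrait, directory) -> None:
    """Persist a trained SOM as codebook TSV + gene_bmu TSV + meta YAML."""
    model._check_fitted()
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        model.codebook_, columns=model.sample_ids_,
        index=[f"u{k}" for k in range(model.n_units)],
    ).to_csv(d / "codebook.tsv", sep="\t", index_label="unit")
    model.gene_bmu_.to_frame().to_csv(d / "gene_bmu.tsv", sep="\t",
                                      index_label="gene_id")
    meta = {
        "grid_rows": model.grid_rows,
        "grid_cols": model.grid_cols,
        "n_epochs": model.n_epochs,
        "training_meta": {k: (float(v) if isinstance(v, np.floating) else v)
                          for k, v in model.training_meta_.items()},
        "quantization_errors": [float(q) for q in model.quantization_errors_],
    }
    with open(d / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def load_model(directory) -> SOMPortrait:
    d = Path(directory)
    with open(d / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    cb = pd.read_csv(d / "codebook.tsv", sep="\t", index_col=0)
    bmu = pd.read_csv(d / "gene_bmu.tsv", sep="\t", index_col=0)["bmu"]
    model = SOMPortrait(grid_rows=meta["grid_rows"],
                        grid_cols=meta["grid_cols"],
                        n_epochs=meta["n_epochs"])
    model.codebook_ = cb.to_numpy(dtype=float)
    model.sample_ids_ = list(cb.columns)
    model.gene_ids_ = list(bmu.index)
    model.gene_bmu_ = bmu.astype(int)
    model.labels_ = model.gene_bmu_.to_numpy()
    model.quantization_errors_ = np.asarray(meta["quantization_errors"])
    model.training_meta_ = meta["training_meta"]
    return model


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "gene_module": {g: (m if m is not None else None)
                        for g, m in truth.gene_module.items()},
        "sample_type": truth.sample_type.to_dict(orient="index"),
        "module_activation": {
            s: [float(x) for x in row]
            for s, row in zip(truth.module_activation.index,
                              truth.module_activation.to_numpy())
        },
        "modules": list(truth.module_activation.columns),
        "subtype_modules": {k: sorted(v)
                            for k, v in truth.subtype_modules.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
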