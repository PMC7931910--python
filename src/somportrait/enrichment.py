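"""Function mining: Fisher overrepresentation, GSZ scores, gene-set maps."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .som import SOMPortrait

__all__ = [
    "GeneSet",
    "fisher_enrichment",
    "gsz",
    "gsz_matrix",
    "gene_set_map",
    "enrich_spots",
]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (e.g. one GMT line)."""

    name: str
    genes: frozenset
    source: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


def fisher_enrichment(spot_genes, gene_set, universe) -> tuple[int, float]:
    """Right-tailed Fisher's exact test for gene-set overrepresentation.

    Returns ``(overlap, p)`` with ``p = P(X >= overlap)`` for
    ``X ~ Hypergeometric(|universe|, |gene_set|, |spot_genes|)``; the exact
    upper tail sum, identical to a one-sided 2x2 Fisher test.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    spot_genes = set(spot_genes) & universe
    gene_set = set(gene_set) & universe
    k = len(spot_genes & gene_set)
    N, K, n = len(universe), len(gene_set), len(spot_genes)
    # P(X >= k); sf(k-1) is the exact tail sum, and P(X >= 0) = 1
    p = float(hypergeom.sf(k - 1, N, K, n))
    return k, min(max(p, 0.0), 1.0)


def gsz(sample_expression: pd.Series, gene_set, universe=None,
        pool_weight: float = 0.5) -> float:
    """Gene-set enrichment z-score of one sample.

    The set's mean expression contrast against the universe, normalized by
    a pooled variance term::

        GSZ = sqrt(n_S) * (mean_S - mean_U)
              / sqrt(w * var_S + (1 - w) * var_U)

    with population variances and pooling weight ``w`` (default 0.5).  A
    singleton set has no within-set variance; its var_S term falls back to
    var_U.  Returns 0 when the denominator vanishes.  Expression is
    expected to be centered (log-ratio scale).
    """
    expr = sample_expression
    if universe is not None:
        expr = expr.loc[expr.index.intersection(set(universe))]
    members = expr.index.intersection(set(gene_set))
    if len(members) == 0:
        raise ValueError("gene set does not intersect the universe")
    vals_u = expr.to_numpy(dtype=float)
    vals_s = expr.loc[members].to_numpy(dtype=float)
    mean_s, mean_u = vals_s.mean(), vals_u.mean()
    var_u = vals_u.var()
    var_s = vals_s.var() if len(vals_s) > 1 else var_u
    denom = pool_weight * var_s + (1.0 - pool_weight) * var_u
    if denom <= 0:
        return 0.0
    return float(np.sqrt(len(vals_s)) * (mean_s - mean_u) / np.sqrt(denom))


def gsz_matrix(expression: pd.DataFrame, gene_sets, universe=None,
               pool_weight: float = 0.5) -> pd.DataFrame:
    """GSZ of every gene set (rows) in every sample (columns)."""
    out = {}
    for gs in gene_sets:
        out[gs.name] = [
            gsz(expression[c], gs.genes, universe, pool_weight)
            for c in expression.columns
        ]
    return pd.DataFrame(out, index=expression.columns).T


def gene_set_map(model: SOMPortrait, gene_set) -> np.ndarray:
    """Per-unit counts of set genes, localized by their BMU."""
    model._check_fitted()
    members = set(gene_set) & set(model.gene_ids_)
    counts = np.zeros(model.n_units, dtype=int)
    if not members:
        warnings.warn("no gene of the set is present in the model",
                      stacklevel=2)
    else:
        bmus = model.gene_bmu_.loc[sorted(members)].to_numpy()
        counts = np.bincount(bmus, minlength=model.n_units)
    return counts.reshape(model.grid_rows, model.grid_cols)


def enrich_spots(spots, gene_sets, universe) -> pd.DataFrame:
    """Fisher overrepresentation of each gene set in each spot.

    Returns one row per (spot, set) with overlap, raw p, and
    Benjamini-Hochberg FDR across all tested pairs.
    """
    rows = []
    for spot in spots:
        for gs in gene_sets:
            k, p = fisher_enrichment(spot.genes, gs.genes, universe)
            rows.append(
                {"spot_id": spot.spot_id, "gene_set": gs.name,
                 "set_size": len(gs), "spot_size": len(spot.genes),
                 "overlap": k, "p": p}
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
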