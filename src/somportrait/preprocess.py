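"""Expression-matrix preprocessing: quantile normalization and gene centering.

Input matrices are genes x samples on log2 scale (a ``log2_transform`` is
provided for raw intensities).  Quantile normalization forces every sample
column onto the common distribution of across-sample mean order statistics;
centering removes each gene's row mean so that downstream SOM training and
gene-set scores operate on differential expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "quantile_normalize",
    "center_genes",
    "log2_transform",
    "ExpressionPreprocessor",
]


def _check_no_missing(X: pd.DataFrame) -> None:
    if X.isna().to_numpy().any():
        raise ValueError(
            "expression matrix contains missing values; impute or remove "
            "them before preprocessing"
        )


def quantile_normalize(X: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize sample columns.

    After the operation every column holds the same sorted values: the
    across-sample mean of the order statistics.  Ties within a column
    receive the mean of the order-statistic means their rank range spans,
    which keeps the result deterministic and permutation-equivariant.
    """
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    _check_no_missing(X)
    arr = X.to_numpy(dtype=float)
    target = np.sort(arr, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(target)])
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        lo = rankdata(col, method="min").astype(int)
        hi = rankdata(col, method="max").astype(int)
        out[:, j] = (csum[hi] - csum[lo - 1]) / (hi - lo + 1)
    return pd.DataFrame(out, index=X.index, columns=X.columns)


def center_genes(X: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's row mean (idempotent)."""
    _check_no_missing(X)
    arr = X.to_numpy(dtype=float)
    out = arr - arr.mean(axis=1, keepdims=True)
    res = pd.DataFrame(out, index=X.index, columns=X.columns)
    res.attrs["centered"] = True
    return res


def log2_transform(X: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount) for raw (non-log) intensities."""
    _check_no_missing(X)
    if (X.to_numpy() + pseudocount <= 0).any():
        raise ValueError("log2_transform requires x + pseudocount > 0")
    return pd.DataFrame(
        np.log2(X.to_numpy(dtype=float) + pseudocount),
        index=X.index, columns=X.columns,
    )


def is_centered(X: pd.DataFrame, tol: float = 1e-9) -> bool:
    return bool(np.abs(X.to_numpy().mean(axis=1)).max() <= tol)


class ExpressionPreprocessor(BaseEstimator, TransformerMixin):
    """Transformer applying log2 / quantile normalization / gene centering.

    Operates on genes x samples DataFrames (columns are the cohort
    samples).  Quantile normalization is a within-matrix operation, so
    ``fit`` only validates; the class exists to compose with pipelines.

    Parameters
    ----------
    with_log2 : bool, default False
        Apply ``log2(x+1)`` first (for raw intensities).
    with_quantile : bool, default True
    with_center : bool, default True
    """

    def __init__(self, with_log2: bool = False, with_quantile: bool = True,
                 with_center: bool = True):
        self.with_log2 = with_log2
        self.with_quantile = with_quantile
        self.with_center = with_center

    def fit(self, X: pd.DataFrame, y=None):
        _check_no_missing(pd.DataFrame(X))
        self.n_genes_in_ = X.shape[0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        if self.with_log2:
            X = log2_transform(X)
        if self.with_quantile:
            X = quantile_normalize(X)
        if self.with_center:
            X = center_genes(X)
        return X
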