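"""Batch self-organizing map over gene expression profiles.

The SOM translates an N-gene cohort into K metagenes arranged on a planar
rectangular grid.  Data points are *gene* profiles (dimension = number of
samples); each trained unit's codebook vector is a metagene — the profile
of a micro-cluster of co-expressed genes — and reading the codebook
column of one sample across the grid yields that sample's expression
*portrait*.

Training is batch-mode: every epoch assigns all genes to their nearest
codebook vector (Euclidean; ties broken toward the lowest unit index) and
then replaces each unit by the Gaussian-neighborhood-weighted mean of the
assigned gene profiles.  The neighborhood radius decays linearly from
max(rows, cols)/2 to 1 over the epochs.  The codebook is initialized on
the plane spanned by the first two principal components of the gene
profiles, falling back to seeded random jitter for degenerate covariance,
so that a fixed seed yields a bit-reproducible map.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state

__all__ = ["SOMPortrait", "train_som", "portrait", "mean_portrait",
           "quantization_error"]


class SOMPortrait(BaseEstimator):
    """Batch SOM of gene expression profiles with per-sample portraits.

    Parameters
    ----------
    grid_rows, grid_cols : int, default 16
        Map dimensions; K = grid_rows * grid_cols metagenes.  Population
        scale work uses 100x100; desk-scale analyses use 12-20 per side.
    n_epochs : int, default 20
        Batch epochs of the assign/update cycle.
    initial_radius : float, optional
        Gaussian neighborhood radius at epoch 0; defaults to
        ``max(grid_rows, grid_cols) / 2``.
    final_radius : float, default 1.0
    random_state : int or RandomState, optional
        Used only by the random fallback initialization; PCA
        initialization is deterministic.

    Attributes
    ----------
    codebook_ : ndarray of shape (K, n_samples)
        Metagene profiles, row-major over the grid.
    gene_bmu_ : pandas.Series
        Best-matching unit index per training gene (alias ``labels_``).
    quantization_errors_ : ndarray of shape (n_epochs + 1,)
        Mean gene-to-BMU distance before training and after each epoch.
    """

    def __init__(self, grid_rows: int = 16, grid_cols: int = 16,
                 n_epochs: int = 20, initial_radius: float | None = None,
                 final_radius: float = 0.5, random_state=None):
        self.grid_rows = grid_rows
        self.grid_cols = grid_cols
        self.n_epochs = n_epochs
        self.initial_radius = initial_radius
        self.final_radius = final_radius
        self.random_state = random_state

    # ------------------------------------------------------------------ #

    @property
    def n_units(self) -> int:
        return self.grid_rows * self.grid_cols

    def _grid_coords(self) -> np.ndarray:
        rr, cc = np.meshgrid(
            np.arange(self.grid_rows), np.arange(self.grid_cols),
            indexing="ij",
        )
        return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)

    def _init_codebook(self, arr: np.ndarray, rng) -> np.ndarray:
        K, (g, s) = self.n_units, arr.shape
        mu = arr.mean(axis=0)
        Xc = arr - mu
        scale = arr.std()
        if g < 3 or not np.isfinite(Xc).all() or np.allclose(Xc, 0):
            return mu + rng.normal(0.0, 1e-4 * (scale or 1.0), (K, s))
        _, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
        # deterministic sign: largest-magnitude loading positive
        for i in range(min(2, Vt.shape[0])):
            j = int(np.argmax(np.abs(Vt[i])))
            if Vt[i, j] < 0:
                Vt[i] = -Vt[i]
        sd = sv / np.sqrt(max(g - 1, 1))
        u = np.linspace(-2, 2, self.grid_rows) if self.grid_rows > 1 else np.zeros(1)
        v = np.linspace(-2, 2, self.grid_cols) if self.grid_cols > 1 else np.zeros(1)
        cb = (mu[None, :]
              + np.kron(u, np.ones(self.grid_cols))[:, None] * sd[0] * Vt[0]
              + np.kron(np.ones(self.grid_rows), v)[:, None]
              * (sd[1] * Vt[1] if len(sd) > 1 else 0.0))
        return np.ascontiguousarray(cb)

    def fit(self, X, y=None):
        """Train on a genes x samples matrix (DataFrame or ndarray)."""
        if isinstance(X, pd.DataFrame):
            arr = X.to_numpy(dtype=float)
            gene_ids = list(X.index)
            sample_ids = list(X.columns)
        else:
            arr = np.asarray(X, dtype=float)
            gene_ids = list(range(arr.shape[0]))
            sample_ids = list(range(arr.shape[1]))
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("expression matrix must be non-empty and 2-D")
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.n_units < 1:
            raise ValueError("grid must contain at least one unit")
        g, s = arr.shape
        if g < self.n_units:
            warnings.warn(
                f"{g} genes for {self.n_units} units: over-parameterized map",
                stacklevel=2,
            )
        rng = check_random_state(self.random_state)

        codebook = self._init_codebook(arr, rng)
        coords = self._grid_coords()
        D2 = cdist(coords, coords, "sqeuclidean")
        r0 = self.initial_radius
        if r0 is None:
            r0 = max(self.grid_rows, self.grid_cols) / 2.0
        r0 = max(float(r0), 1e-6)
        r1 = max(float(self.final_radius), 1e-6)

        qe: list[float] = []
        bmu = np.zeros(g, dtype=int)
        for epoch in range(self.n_epochs):
            frac = epoch / (self.n_epochs - 1) if self.n_epochs > 1 else 1.0
            radius = r0 + (r1 - r0) * frac
            d = cdist(arr, codebook)
            bmu = d.argmin(axis=1)
            qe.append(float(d[np.arange(g), bmu].mean()))
            sums = np.zeros((self.n_units, s))
            np.add.at(sums, bmu, arr)
            counts = np.bincount(bmu, minlength=self.n_units).astype(float)
            H = np.exp(-D2 / (2.0 * radius * radius))
            num = H @ sums
            den = H @ counts
            upd = den > 1e-12
            codebook[upd] = num[upd] / den[upd, None]

        d = cdist(arr, codebook)
        bmu = d.argmin(axis=1)
        qe.append(float(d[np.arange(g), bmu].mean()))

        self.codebook_ = codebook
        self.sample_ids_ = sample_ids
        self.gene_ids_ = gene_ids
        self.gene_bmu_ = pd.Series(bmu, index=gene_ids, name="bmu")
        self.labels_ = bmu
        self.quantization_errors_ = np.asarray(qe)
        self.training_meta_ = {
            "n_epochs": self.n_epochs,
            "initial_radius": r0,
            "final_radius": r1,
            "n_genes": g,
        }
        return self

    # ------------------------------------------------------------------ #

    def _check_fitted(self):
        if not hasattr(self, "codebook_"):
            raise AttributeError("SOMPortrait instance is not fitted yet")

    def predict(self, X) -> np.ndarray:
        """Best-matching unit index for each row (gene profile) of X."""
        self._check_fitted()
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.shape[1] != self.codebook_.shape[1]:
            raise ValueError(
                f"profiles of length {arr.shape[1]} incompatible with "
                f"{self.codebook_.shape[1]}-sample codebook"
            )
        return cdist(arr, self.codebook_).argmin(axis=1)

    def _sample_index(self, sample_id) -> int:
        try:
            return self.sample_ids_.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def portrait(self, sample_id) -> np.ndarray:
        """Row-major reshape of one sample's codebook column."""
        self._check_fitted()
        col = self.codebook_[:, self._sample_index(sample_id)]
        return col.reshape(self.grid_rows, self.grid_cols)

    def mean_portrait(self, sample_ids) -> np.ndarray:
        """Element-wise mean of member portraits."""
        self._check_fitted()
        ids = list(sample_ids)
        if not ids:
            raise ValueError("mean_portrait of an empty sample subset")
        idx = [self._sample_index(s) for s in ids]
        return self.codebook_[:, idx].mean(axis=1).reshape(
            self.grid_rows, self.grid_cols
        )

    def sample_portrait_matrix(self) -> pd.DataFrame:
        """Samples x units matrix (one flattened portrait per row)."""
        self._check_fitted()
        return pd.DataFrame(
            self.codebook_.T,
            index=self.sample_ids_,
            columns=[f"u{k}" for k in range(self.n_units)],
        )

    def quantization_error(self, X) -> float:
        """Mean Euclidean distance of gene profiles to their BMU."""
        self._check_fitted()
        arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) \
            else np.asarray(X, dtype=float)
        if arr.shape[1] != self.codebook_.shape[1]:
            raise ValueError("sample dimension mismatch with trained codebook")
        d = cdist(arr, self.codebook_)
        return float(d.min(axis=1).mean())


# -------------------------- functional wrappers ------------------------ #

def train_som(X, grid_rows: int = 16, grid_cols: int = 16,
              n_epochs: int = 20, seed=None, **kwargs) -> SOMPortrait:
    return SOMPortrait(
        grid_rows=grid_rows, grid_cols=grid_cols, n_epochs=n_epochs,
        random_state=seed, **kwargs,
    ).fit(X)


def portrait(model: SOMPortrait, sample_id) -> np.ndarray:
    return model.portrait(sample_id)


def mean_portrait(model: SOMPortrait, sample_ids) -> np.ndarray:
    return model.mean_portrait(sample_ids)


def quantization_error(model: SOMPortrait, X) -> float:
    return model.quantization_error(X)
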