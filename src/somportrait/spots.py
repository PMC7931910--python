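"""Segmentation of the metagene grid into co-expression "spot" modules.

Spots are connected clusters of grid units that become strongly
over-expressed in at least part of the cohort; their member genes (all
genes whose best-matching unit falls inside the spot) form discrete
co-expression modules.  Detection combines an over-expression summary map
(per-unit upper percentile of the codebook across samples) with the
U-matrix: units of high neighbor distance form halo-like ridges around the
spots and act as segmentation barriers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

from .som import SOMPortrait

__all__ = [
    "SpotModule",
    "SpotDetector",
    "overexpression_summary",
    "compute_umatrix",
    "detect_spots",
    "spot_expression",
    "spot_correlation_network",
]

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class SpotModule:
    """A connected set of over-expressed grid units plus its member genes."""

    spot_id: str
    units: list  # [(row, col), ...]
    unit_indices: np.ndarray  # row-major indices into the codebook
    genes: list
    profile: pd.Series  # per-sample mean codebook value over the spot units

    @property
    def n_units(self) -> int:
        return len(self.unit_indices)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def overexpression_summary(model: SOMPortrait, percentile: float = 98.0) -> np.ndarray:
    """Per-unit upper percentile of codebook values across samples.

    A robust "maximum expression" map: high where a unit is strongly
    over-expressed in at least ~(100 - percentile)% of the cohort.
    """
    model._check_fitted()
    return np.percentile(model.codebook_, percentile, axis=1).reshape(
        model.grid_rows, model.grid_cols
    )


def compute_umatrix(model: SOMPortrait) -> np.ndarray:
    """Mean Euclidean distance of each unit's codebook vector to its
    8-neighbors (fewer at borders)."""
    model._check_fitted()
    R, C = model.grid_rows, model.grid_cols
    cb = model.codebook_.reshape(R, C, -1)
    total = np.zeros((R, C))
    count = np.zeros((R, C))
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            r0, r1 = max(dr, 0), R + min(dr, 0)
            s0, s1 = max(dc, 0), C + min(dc, 0)
            diff = cb[r0:r1, s0:s1] - cb[r0 - dr:r1 - dr, s0 - dc:s1 - dc]
            d = np.sqrt((diff * diff).sum(axis=-1))
            total[r0:r1, s0:s1] += d
            count[r0:r1, s0:s1] += 1
    return total / count


class SpotDetector:
    """Segment over-expression spots on a trained SOM.

    Candidate units are those whose over-expression summary exceeds the
    ``top_quantile`` quantile of all codebook expression values (an
    expression-level threshold that adapts to grid size).  Candidates
    sitting on U-matrix ridges — above the ``ridge_quantile`` of the
    U-matrix over the candidate units — act as *barriers*: they are masked
    out for the 8-connected component labeling, so the halo lines between
    adjacent co-expression domains split them into separate spots, and are
    then re-attached to a component when all their labeled neighbors
    agree (units between two different spots stay barriers).  Components
    smaller than ``min_units`` are dropped and at most ``max_spots``
    largest (by gene count) are kept, labeled A, B, C, ... in decreasing
    gene count.

    Set ``direction="under"`` to segment under-expression (blue) spots on
    the mirrored map instead; over-expression is the default analysis.
    """

    def __init__(self, top_quantile: float = 0.975,
                 ridge_quantile: float = 0.60, min_units: int = 4,
                 max_spots: int = 25, summary_percentile: float = 98.0,
                 direction: str = "over"):
        self.top_quantile = top_quantile
        self.ridge_quantile = ridge_quantile
        self.min_units = min_units
        self.max_spots = max_spots
        self.summary_percentile = summary_percentile
        self.direction = direction

    def get_params(self, deep: bool = True) -> dict:
        return {
            "top_quantile": self.top_quantile,
            "ridge_quantile": self.ridge_quantile,
            "min_units": self.min_units,
            "max_spots": self.max_spots,
            "summary_percentile": self.summary_percentile,
            "direction": self.direction,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------ #

    def fit(self, model: SOMPortrait):
        if self.direction not in ("over", "under"):
            raise ValueError("direction must be 'over' or 'under'")
        if not 0.0 < self.top_quantile < 1.0 or not 0.0 < self.ridge_quantile <= 1.0:
            raise ValueError("quantile thresholds must lie in (0, 1)")
        model._check_fitted()
        cb = model.codebook_ if self.direction == "over" else -model.codebook_
        R, C = model.grid_rows, model.grid_cols

        summary = np.percentile(cb, self.summary_percentile, axis=1).reshape(R, C)
        umatrix = compute_umatrix(model)
        threshold = float(np.quantile(cb, self.top_quantile))

        mask = summary > threshold
        ridge = float(np.quantile(umatrix[mask], self.ridge_quantile)) \
            if mask.any() else float("inf")
        core = mask & (umatrix <= ridge)
        labels, n_comp = ndimage.label(core, structure=np.ones((3, 3), int))
        # barrier units rejoin the unique adjacent component, if any
        changed = True
        while changed:
            changed = False
            for r in range(R):
                for c in range(C):
                    if mask[r, c] and labels[r, c] == 0:
                        nb = labels[max(0, r - 1):r + 2, max(0, c - 1):c + 2]
                        ids = np.unique(nb[nb > 0])
                        if len(ids) == 1:
                            labels[r, c] = ids[0]
                            changed = True
        # candidate clusters made entirely of halo units (small isolated
        # blobs have no low-U core) become components of their own; genuine
        # inter-spot bridges stay small and are dropped by min_units
        leftover, n_extra = ndimage.label(mask & (labels == 0),
                                          structure=np.ones((3, 3), int))
        labels[leftover > 0] = leftover[leftover > 0] + n_comp
        n_comp += n_extra

        bmu = model.gene_bmu_.to_numpy()
        gene_ids = np.asarray(model.gene_ids_, dtype=object)
        flat_labels = labels.ravel()

        comps = []
        for c in range(1, n_comp + 1):
            unit_idx = np.flatnonzero(flat_labels == c)
            if len(unit_idx) < self.min_units:
                continue
            genes = gene_ids[np.isin(bmu, unit_idx)]
            if len(genes) == 0:
                continue
            comps.append((unit_idx, list(genes)))
        comps.sort(key=lambda t: (-len(t[1]), t[0][0]))
        comps = comps[: self.max_spots]

        spots = []
        for i, (unit_idx, genes) in enumerate(comps):
            label = _LETTERS[i] if i < len(_LETTERS) else f"Z{i}"
            profile = pd.Series(
                model.codebook_[unit_idx].mean(axis=0),
                index=model.sample_ids_, name=label,
            )
            spots.append(
                SpotModule(
                    spot_id=label,
                    units=[(int(k // C), int(k % C)) for k in unit_idx],
                    unit_indices=unit_idx,
                    genes=genes,
                    profile=profile,
                )
            )

        self.summary_ = summary
        self.umatrix_ = umatrix
        self.threshold_ = threshold
        self.ridge_threshold_ = ridge
        self.spots_ = spots
        return self


def detect_spots(model: SOMPortrait, top_quantile: float = 0.975,
                 ridge_quantile: float = 0.60, min_units: int = 4,
                 max_spots: int = 25, **kwargs) -> list[SpotModule]:
    """Functional wrapper around :class:`SpotDetector`."""
    det = SpotDetector(
        top_quantile=top_quantile, ridge_quantile=ridge_quantile,
        min_units=min_units, max_spots=max_spots, **kwargs,
    ).fit(model)
    return det.spots_


def spot_expression(spot: SpotModule, model: SOMPortrait) -> pd.Series:
    """Mean codebook value over the spot's units, one value per sample."""
    model._check_fitted()
    if len(spot.unit_indices) == 0:
        raise ValueError("spot has no units")
    if spot.unit_indices.max() >= model.n_units:
        raise ValueError("spot units outside the model grid")
    return pd.Series(
        model.codebook_[spot.unit_indices].mean(axis=0),
        index=model.sample_ids_, name=spot.spot_id,
    )


def spot_profile_matrix(spots: list[SpotModule]) -> pd.DataFrame:
    """Samples x spots matrix of spot expression profiles."""
    if not spots:
        return pd.DataFrame()
    return pd.DataFrame({s.spot_id: s.profile for s in spots})


def spot_correlation_network(spots: list[SpotModule],
                             r_threshold: float = 0.5) -> nx.Graph:
    """Signed Pearson-correlation graph over spot profiles.

    Nodes are spot ids; an edge is drawn where |r| >= ``r_threshold`` and
    carries attributes ``r`` and ``sign``.  Zero-variance profiles never
    correlate (r taken as 0).
    """
    if len(spots) < 2:
        raise ValueError("need at least two spots for a correlation network")
    G = nx.Graph()
    for s in spots:
        G.add_node(s.spot_id, n_genes=s.n_genes, n_units=s.n_units)
    for i, a in enumerate(spots):
        va = a.profile.to_numpy()
        for b in spots[i + 1:]:
            vb = b.profile.to_numpy()
            if va.std() == 0 or vb.std() == 0:
                continue
            r = float(np.corrcoef(va, vb)[0, 1])
            if abs(r) >= r_threshold:
                G.add_edge(a.spot_id, b.spot_id, r=r,
                           sign=1 if r >= 0 else -1)
    return G
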