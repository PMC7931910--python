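"""Sample stratification: combinatorial spot patterns, types, and subtypes.

Each sample is first reduced to its combinatorial pattern (cPAT) — the set
of spots it over-expresses (spot z-score above a threshold).  Frequent
cPATs provide centroid portraits whose hierarchical clustering suggests
the number of transcriptome types; K-means on the full metagene portraits
then assigns types, and a second K-means within each type assigns
subtypes.  The resulting partition is validated by repeated stratified
holdout with a regularized linear classifier.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.utils import check_random_state

__all__ = [
    "assign_cpats",
    "enumerate_cpats",
    "estimate_type_count",
    "cluster_types",
    "pairwise_correlation",
    "validate_types",
    "TypeStratifier",
]

EMPTY_CPAT = "-"


# ---------------------------------------------------------------------- #
# cPATs
# ---------------------------------------------------------------------- #

def assign_cpats(spot_profiles: pd.DataFrame, z_threshold: float = 1.0) -> pd.Series:
    """Combinatorial pattern type per sample.

    A spot belongs to a sample's pattern iff the sample's spot expression,
    standardized across the cohort per spot, exceeds ``z_threshold``.
    Zero-variance spots are never over-expressed.  Patterns are encoded as
    '+'-joined sorted spot ids ('-' for the empty pattern).
    """
    P = spot_profiles.to_numpy(dtype=float)
    sd = P.std(axis=0, ddof=0)
    mu = P.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (P - mu) / np.where(sd > 0, sd, 1.0), -np.inf)
    over = z > z_threshold
    cols = list(spot_profiles.columns)
    pats = [
        "+".join(sorted(c for c, o in zip(cols, row) if o)) or EMPTY_CPAT
        for row in over
    ]
    return pd.Series(pats, index=spot_profiles.index, name="cpat")


def enumerate_cpats(cpats: pd.Series, min_count: int = 5) -> pd.DataFrame:
    """Unique-pattern counts; patterns with count >= min_count are 'major'."""
    counts = cpats.value_counts()
    return pd.DataFrame(
        {
            "cpat": counts.index,
            "count": counts.to_numpy(),
            "major": counts.to_numpy() >= min_count,
        }
    ).reset_index(drop=True)


def estimate_type_count(cpats: pd.Series, portraits: pd.DataFrame,
                        min_count: int = 5) -> int:
    """Tentative number of types from major-cPAT centroid portraits.

    Average-linkage hierarchical clustering of the centroid portraits of
    the major patterns; the cut is placed at the largest gap of the merge
    heights, and the result is bounded to [2, number of major cPATs].
    """
    table = enumerate_cpats(cpats, min_count=min_count)
    major = table.loc[table["major"], "cpat"].tolist()
    if len(major) == 0:
        raise ValueError("no major cPAT; lower min_count")
    if len(major) == 1:
        warnings.warn("single major cPAT; type count forced to 1", stacklevel=2)
        return 1
    centroids = np.vstack(
        [portraits.loc[cpats == p].to_numpy().mean(axis=0) for p in major]
    )
    Z = linkage(centroids, method="average", metric="euclidean")
    heights = Z[:, 2]
    if heights[-1] <= 1e-12:
        warnings.warn("all cPAT centroids identical; forcing k = 2", stacklevel=2)
        return 2
    if len(heights) == 1:
        return 2
    # largest gap between consecutive merge heights locates the cut
    gaps = np.diff(heights)
    i_star = int(np.argmax(gaps))
    k = len(major) - (i_star + 1)
    return int(min(max(k, 2), len(major)))


# ---------------------------------------------------------------------- #
# K-means typing
# ---------------------------------------------------------------------- #

def _relabel(portraits: np.ndarray, raw: np.ndarray, k: int,
             reference: np.ndarray | None) -> list[str]:
    """Deterministic mapping of K-means cluster ids to type names.

    Clusters are ordered along a reference score: by default the mean of
    the portrait dimension of highest variance, or — when a per-sample
    reference profile (e.g. a lymphocyte-associated spot) is supplied —
    the cluster mean of that profile, ascending, so that type "1" has the
    lowest reference expression.  For k = 3 the cluster whose centroid
    correlates least (in absolute mean) with the two extreme centroids is
    named "M".
    """
    centroids = np.vstack([portraits[raw == c].mean(axis=0) for c in range(k)])
    if reference is not None:
        score = np.array([reference[raw == c].mean() for c in range(k)])
    else:
        j = int(np.argmax(portraits.var(axis=0)))
        score = centroids[:, j]
    order = list(np.argsort(score, kind="stable"))

    names = [str(i + 1) for i in range(k)]
    if k == 3:
        cc = np.corrcoef(centroids)
        lo, hi = order[0], order[-1]
        mid = ({0, 1, 2} - {lo, hi}).pop()
        # intermediate = weakest mean |correlation| to the two poles
        strengths = {
            c: (abs(cc[c, a]) + abs(cc[c, b])) / 2
            for c in (lo, mid, hi)
            for a, b in [tuple(x for x in (lo, mid, hi) if x != c)[:2]]
        }
        m_cluster = min((mid, lo, hi), key=lambda c: (strengths[c], c))
        rest = [c for c in order if c != m_cluster]
        mapping = {rest[0]: "1", m_cluster: "M", rest[1]: "2"}
    else:
        mapping = {c: names[i] for i, c in enumerate(order)}
    return [mapping[c] for c in raw]


def cluster_types(portraits: pd.DataFrame, k: int, seed=None,
                  n_subtypes: int = 3, n_restarts: int = 25,
                  reference: pd.Series | None = None) -> pd.DataFrame:
    """K-means typing of portraits plus nested subtype K-means.

    Returns a DataFrame indexed by sample with columns ``type`` and
    ``subtype`` (subtype labels are ``"<type>.<i>"``).  K-means uses
    k-means++ initialization with ``n_restarts`` seeded restarts, so the
    result is deterministic given ``seed``.
    """
    n = len(portraits)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"cannot split {n} samples into {k} types")
    X = portraits.to_numpy(dtype=float)
    rng = check_random_state(seed)
    km = KMeans(n_clusters=k, n_init=n_restarts,
                random_state=rng.randint(2**31 - 1)).fit(X)
    ref = None
    if reference is not None:
        ref = reference.reindex(portraits.index).to_numpy(dtype=float)
    type_labels = np.array(_relabel(X, km.labels_, k, ref), dtype=object)

    subtype_labels = np.empty(n, dtype=object)
    for t in np.unique(type_labels):
        idx = np.flatnonzero(type_labels == t)
        n_sub = min(n_subtypes, len(idx))
        if n_sub <= 1:
            subtype_labels[idx] = f"{t}.1"
            continue
        km_sub = KMeans(n_clusters=n_sub, n_init=n_restarts,
                        random_state=rng.randint(2**31 - 1)).fit(X[idx])
        # order sub-clusters by size (desc), centroid norm as tie-break
        sizes = np.bincount(km_sub.labels_, minlength=n_sub)
        norms = np.linalg.norm(km_sub.cluster_centers_, axis=1)
        order = sorted(range(n_sub), key=lambda c: (-sizes[c], -norms[c], c))
        rename = {c: f"{t}.{i + 1}" for i, c in enumerate(order)}
        subtype_labels[idx] = [rename[c] for c in km_sub.labels_]

    return pd.DataFrame(
        {"type": type_labels, "subtype": subtype_labels}, index=portraits.index
    )


def pairwise_correlation(portraits: pd.DataFrame) -> pd.DataFrame:
    """Samples x samples Pearson correlation of expression portraits."""
    if len(portraits) < 2:
        raise ValueError("need at least two samples")
    X = portraits.to_numpy(dtype=float)
    sd = X.std(axis=1)
    Xs = np.where(sd[:, None] > 0, (X - X.mean(axis=1, keepdims=True)), 0.0)
    norm = np.where(sd > 0, np.linalg.norm(Xs, axis=1), 1.0)
    C = (Xs / norm[:, None]) @ (Xs / norm[:, None]).T
    C[sd == 0, :] = 0.0
    C[:, sd == 0] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    return pd.DataFrame(C, index=portraits.index, columns=portraits.index)


def similarity_network(correlation: pd.DataFrame,
                       threshold: float = 0.5):
    """Sample similarity graph: edges where portrait correlation exceeds
    the threshold (the network view of the pairwise correlation map)."""
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(correlation.index)
    cols = list(correlation.columns)
    arr = correlation.to_numpy()
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if arr[i, j] >= threshold:
                G.add_edge(cols[i], cols[j], r=float(arr[i, j]))
    return G


def validate_types(portraits: pd.DataFrame, labels: pd.Series,
                   n_rounds: int = 10, holdout: float = 0.3,
                   seed=None) -> float:
    """Mean held-out misclassification of the type partition.

    Repeated stratified holdout; a shrinkage linear discriminant (a
    regularized linear classifier suited to portrait dimension >> sample
    count) is trained on each split and scored on the held-out samples.
    Rounds whose training split misses a class are skipped with a warning.
    """
    y = labels.reindex(portraits.index).to_numpy(dtype=object)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("validation needs at least two type labels")
    X = portraits.to_numpy(dtype=float)
    splitter = StratifiedShuffleSplit(
        n_splits=n_rounds, test_size=holdout, random_state=seed
    )
    rates = []
    for train, test in splitter.split(X, y):
        if len(np.unique(y[train])) < len(classes):
            warnings.warn("class absent from a training split; round skipped",
                          stacklevel=2)
            continue
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        clf.fit(X[train], y[train])
        rates.append(float(np.mean(clf.predict(X[test]) != y[test])))
    if not rates:
        raise ValueError("no usable validation round")
    return float(np.mean(rates))


# ---------------------------------------------------------------------- #
# Estimator facade
# ---------------------------------------------------------------------- #

class TypeStratifier:
    """cPAT-guided typing of expression portraits.

    Parameters
    ----------
    n_types : int, optional
        Number of types; estimated from major-cPAT centroids when None.
    n_subtypes : int, default 3
        Nested K-means clusters within each type.
    z_threshold : float, default 1.0
        Spot over-expression criterion for cPAT membership.
    min_cpat_count : int, default 5
        A pattern is "major" from this many samples on.
    n_restarts : int, default 25
    random_state : int, optional

    Attributes (after ``fit``)
    --------------------------
    cpat_ : pandas.Series — pattern label per sample
    cpat_table_ : pandas.DataFrame — pattern counts and major flags
    n_types_ : int
    assignment_ : pandas.DataFrame with columns cpat, type, subtype
    """

    def __init__(self, n_types: int | None = None, n_subtypes: int = 3,
                 z_threshold: float = 1.0, min_cpat_count: int = 15,
                 n_restarts: int = 25, random_state=None):
        self.n_types = n_types
        self.n_subtypes = n_subtypes
        self.z_threshold = z_threshold
        self.min_cpat_count = min_cpat_count
        self.n_restarts = n_restarts
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_types": self.n_types, "n_subtypes": self.n_subtypes,
            "z_threshold": self.z_threshold,
            "min_cpat_count": self.min_cpat_count,
            "n_restarts": self.n_restarts, "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, portraits: pd.DataFrame,
            spot_profiles: pd.DataFrame | None = None,
            reference: pd.Series | None = None):
        if spot_profiles is not None and len(spot_profiles.columns) > 0:
            self.cpat_ = assign_cpats(spot_profiles, self.z_threshold)
        else:
            self.cpat_ = pd.Series(EMPTY_CPAT, index=portraits.index,
                                   name="cpat")
        self.cpat_table_ = enumerate_cpats(self.cpat_, self.min_cpat_count)
        if self.n_types is not None:
            self.n_types_ = int(self.n_types)
        else:
            self.n_types_ = estimate_type_count(
                self.cpat_, portraits, self.min_cpat_count
            )
        assignment = cluster_types(
            portraits, self.n_types_, seed=self.random_state,
            n_subtypes=self.n_subtypes, n_restarts=self.n_restarts,
            reference=reference,
        )
        assignment.insert(0, "cpat", self.cpat_)
        self.assignment_ = assignment
        self.type_labels_ = assignment["type"]
        self.subtype_labels_ = assignment["subtype"]
        return self

    def fit_predict(self, portraits, spot_profiles=None, **kw) -> np.ndarray:
        return self.fit(portraits, spot_profiles, **kw).type_labels_.to_numpy()
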