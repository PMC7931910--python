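"""Phenotype portrayal: correlation maps, type enrichment, regression, LOESS.

A phenotype *correlation map* correlates one phenotype feature across the
cohort with every metagene's expression profile, yielding a grid image in
the SOM coordinate system.  Binary features use the point-biserial
correlation, which is computed as Pearson correlation on the 0/1 coding
(the two are mathematically identical); categorical features expand into
one-vs-rest binary maps per level.  Additional views: Fisher enrichment of
categorical levels in the transcriptome types, standardized multiple
regression of spot expression on phenotypes, and LOESS trend curves of
spot expression against continuous covariates (age, BMI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .som import SOMPortrait

__all__ = [
    "CorrelationMap",
    "correlation_map",
    "type_enrichment",
    "spot_regression",
    "loess_trend",
]


@dataclass
class CorrelationMap:
    """Per-unit correlation of one phenotype with metagene expression."""

    feature: str
    grid: np.ndarray  # grid_rows x grid_cols, values in [-1, 1]
    n_samples: int  # samples used after pairwise-complete deletion

    @property
    def argmax_unit(self) -> tuple[int, int]:
        return tuple(np.unravel_index(np.argmax(self.grid), self.grid.shape))

    @property
    def argmin_unit(self) -> tuple[int, int]:
        return tuple(np.unravel_index(np.argmin(self.grid), self.grid.shape))

    @property
    def r_max(self) -> float:
        return float(self.grid.max())


def _pearson_rows(M: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of M against y; zero-variance rows -> 0."""
    yc = y - y.mean()
    sy = np.sqrt((yc * yc).sum())
    Mc = M - M.mean(axis=1, keepdims=True)
    sm_ = np.sqrt((Mc * Mc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Mc @ yc) / (sm_ * sy)
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


def correlation_map(model: SOMPortrait, values: pd.Series,
                    kind: str = "continuous", feature: str | None = None):
    """Correlation portrait(s) of one phenotype feature.

    ``kind='continuous'`` or ``'binary'`` return one :class:`CorrelationMap`
    (binary values must be 0/1 coded; the point-biserial correlation equals
    Pearson on the indicator).  ``kind='categorical'`` returns a dict of
    one-vs-rest maps per level.  Samples with missing values are dropped
    pairwise; at least 3 non-missing samples are required.
    """
    model._check_fitted()
    feature = feature or (values.name if values.name is not None else "feature")
    v = values.reindex(model.sample_ids_)

    if kind == "categorical":
        levels = sorted(v.dropna().unique())
        return {
            lev: correlation_map(
                model, (v == lev).astype(float).where(v.notna()),
                kind="binary", feature=f"{feature}={lev}",
            )
            for lev in levels
        }

    mask = v.notna().to_numpy()
    if mask.sum() < 3:
        raise ValueError(f"feature {feature!r}: fewer than 3 non-missing samples")
    y = v.to_numpy(dtype=float)[mask]
    if kind == "binary":
        lv = set(np.unique(y))
        if not lv <= {0.0, 1.0}:
            raise ValueError(f"binary feature {feature!r} must be 0/1 coded")
        if len(lv) < 2:
            raise ValueError(f"binary feature {feature!r} has a single level")
    if y.std() == 0:
        raise ValueError(f"feature {feature!r} has zero variance")
    r = _pearson_rows(model.codebook_[:, mask], y)
    return CorrelationMap(
        feature=feature,
        grid=r.reshape(model.grid_rows, model.grid_cols),
        n_samples=int(mask.sum()),
    )


def type_enrichment(type_labels: pd.Series, feature: pd.Series,
                    feature_name: str | None = None) -> pd.DataFrame:
    """One-tailed Fisher enrichment of categorical levels in each type.

    For every (type, level) cell the 2x2 table (in type / not, has level /
    not) is tested right-tailed (hypergeometric upper tail); an empty
    margin yields p = 1 with a flag.  BH-FDR is computed across all cells.
    The ``direction`` column marks whether the level is over- ('enriched')
    or under-represented ('depleted') relative to independence.
    """
    df = pd.DataFrame({"type": type_labels, "level": feature}).dropna()
    types = sorted(df["type"].unique())
    levels = sorted(df["level"].unique())
    if len(types) < 2 or len(levels) < 2:
        raise ValueError("need at least two types and two feature levels")
    N = len(df)
    rows = []
    for t in types:
        in_t = df["type"] == t
        for lev in levels:
            has = df["level"] == lev
            k = int((in_t & has).sum())
            K, n = int(has.sum()), int(in_t.sum())
            degenerate = K == 0 or n == 0 or K == N or n == N
            p = 1.0 if degenerate else float(stats.hypergeom.sf(k - 1, N, K, n))
            expected = K * n / N
            rows.append(
                {"type": t, "level": lev, "count": k,
                 "expected": expected,
                 "direction": "enriched" if k > expected else "depleted",
                 "p": min(p, 1.0), "degenerate": degenerate}
            )
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def spot_regression(spot_profiles: pd.DataFrame,
                    phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Standardized multiple regression of spot expression on phenotypes.

    Each spot profile (response) and each phenotype column (predictor) is
    z-scored; OLS then yields standardized coefficients with per-
    coefficient t-test p-values, one output row per (spot, phenotype).
    Collinear predictor columns are dropped with a warning and reported in
    the ``dropped`` DataFrame attribute of the result.
    """
    common = spot_profiles.index.intersection(phenotypes.index)
    P = phenotypes.loc[common].apply(pd.to_numeric, errors="raise")
    S = spot_profiles.loc[common]
    if P.isna().to_numpy().any():
        keep = P.notna().all(axis=1)
        P, S = P.loc[keep], S.loc[keep]

    def zscore(df):
        sd = df.std(ddof=0)
        return (df - df.mean()) / sd.replace(0.0, np.nan)

    Z = zscore(P)
    dropped = [c for c in Z.columns if Z[c].isna().all()]
    Z = Z.drop(columns=dropped)
    # drop collinear columns until full rank; later columns go first
    while Z.shape[1] > 0 and np.linalg.matrix_rank(Z.to_numpy()) < Z.shape[1]:
        for j in reversed(range(Z.shape[1])):
            sub = Z.drop(columns=Z.columns[j])
            if np.linalg.matrix_rank(sub.to_numpy()) == np.linalg.matrix_rank(Z.to_numpy()):
                dropped.append(Z.columns[j])
                Z = sub
                break
    if dropped:
        warnings.warn(f"collinear phenotype columns dropped: {dropped}",
                      stacklevel=2)

    rows = []
    X = sm.add_constant(Z.to_numpy())
    for spot_id in S.columns:
        y = S[spot_id].to_numpy(dtype=float)
        sd = y.std()
        yz = (y - y.mean()) / sd if sd > 0 else y - y.mean()
        fit = sm.OLS(yz, X).fit()
        for i, name in enumerate(Z.columns, start=1):
            rows.append(
                {"spot_id": spot_id, "phenotype": name,
                 "beta_std": float(fit.params[i]),
                 "p": float(fit.pvalues[i])}
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out.attrs["dropped"] = dropped
    out.attrs["n_samples"] = len(Z)
    return out


def loess_trend(x, y, span: float = 0.5, groups=None,
                n_points: int = 100) -> pd.DataFrame:
    """Tricube-weighted local linear (LOESS) trend on an even x-grid.

    Fits degree-1 LOESS with the given span and evaluates the curve on
    ``n_points`` evenly spaced x values (linear interpolation between
    fitted data points).  With ``groups`` given, one curve per group is
    returned (column ``group``); each group needs >= 10 points.  A span
    that leaves fewer than 4 points per local window is widened with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if groups is not None:
        groups = np.asarray(groups)
        out = []
        for g in pd.unique(groups):
            m = groups == g
            cur = loess_trend(x[m], y[m], span=span, n_points=n_points)
            cur.insert(0, "group", g)
            out.append(cur)
        return pd.concat(out, ignore_index=True)

    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 10:
        raise ValueError("LOESS needs at least 10 points per group")
    frac = span
    if frac * len(x) < 4:
        frac = min(1.0, 4.0 / len(x))
        warnings.warn(f"span widened to {frac:.3f} to keep >= 4 local points",
                      stacklevel=2)
    fitted = lowess(y, x, frac=frac, it=2, return_sorted=True)
    grid = np.linspace(x.min(), x.max(), n_points)
    curve = np.interp(grid, fitted[:, 0], fitted[:, 1])
    return pd.DataFrame({"x": grid, "y": curve})
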