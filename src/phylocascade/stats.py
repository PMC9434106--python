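"""Supporting multivariate statistics: PCA, PERMANOVA and NMDS.

PCA operates on z-scored environmental variables (i.e. on the correlation
structure). PERMANOVA is the one-factor partition of squared distances with a
permutation p-value ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``. NMDS
minimizes Kruskal stress-1 over random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA
from sklearn.manifold import MDS as _SkMDS

from .errors import InputFormatError, InvariantViolation
from .turnover import BetaMntdMatrix

__all__ = [
    "PcaResult",
    "PermanovaResult",
    "NmdsResult",
    "pca",
    "permanova",
    "nmds",
    "kruskal_stress",
]


@dataclass
class PcaResult:
    """Scores, loadings and explained-variance fractions of a PCA."""

    sample_ids: list[str]
    variable_names: list[str]
    scores: np.ndarray              # samples x components
    loadings: np.ndarray            # components x variables
    explained_variance_ratio: np.ndarray

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


@dataclass
class PermanovaResult:
    """One-factor PERMANOVA outcome."""

    grouping_name: str
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "grouping": self.grouping_name,
            "pseudo_F": self.pseudo_f,
            "R2": self.r_squared,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
        }


@dataclass
class NmdsResult:
    """NMDS configuration with its final Kruskal stress-1."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x k
    stress: float

    def coords_frame(self) -> pd.DataFrame:
        cols = [f"NMDS{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pca(env: pd.DataFrame) -> PcaResult:
    """PCA of standardized (z-scored) environmental variables.

    Constant columns are rejected by name: they carry no correlation
    information and make the z-score undefined.
    """
    if env.shape[0] < 2 or env.shape[1] < 2:
        raise InputFormatError("PCA needs at least 2 samples and 2 variables")
    if env.isna().any().any():
        col = env.columns[env.isna().any().to_numpy()][0]
        raise InputFormatError(f"PCA input has missing values (e.g. column {col!r})")
    X = env.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        name = env.columns[int(np.argmax(sd == 0))]
        raise InputFormatError(f"constant environmental variable: {name!r}")
    Z = (X - X.mean(axis=0)) / sd

    model = _SkPCA(n_components=min(Z.shape))
    scores = model.fit_transform(Z)
    loadings = model.components_
    # sign convention: each component's largest-|.| loading is positive
    for k in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1
    return PcaResult(
        list(map(str, env.index)),
        list(map(str, env.columns)),
        scores,
        loadings,
        model.explained_variance_ratio_,
    )


def _permanova_f(d2: np.ndarray, groups: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Pseudo-F and R² from a squared-distance matrix and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(groups == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    # Non-Euclidean dissimilarities (βMNTD is one) can make the raw
    # between-group component negative; floor the reported R² as variance
    # components conventionally are. F keeps the raw partition so the
    # permutation reference distribution stays comparable.
    r2 = np.clip(ss_between / ss_total, 0.0, 1.0) if ss_total > 0 else np.nan
    if df_within <= 0 or ss_within <= 0:
        return np.inf, r2
    f = (ss_between / df_between) / (ss_within / df_within)
    return f, r2


def permanova(
    dist: BetaMntdMatrix | pd.DataFrame,
    grouping: pd.Series | dict | list,
    n_perm: int = 999,
    seed: int = 0,
    grouping_name: str = "group",
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    ``grouping`` assigns each sample a label (aligned list, dict or Series
    indexed by sample id). Labels are permuted freely (no strata).
    """
    if isinstance(dist, BetaMntdMatrix):
        ids = dist.sample_ids
        d = dist.values
    else:
        ids = list(map(str, dist.index))
        d = dist.to_numpy(dtype=float)
    n = len(ids)
    if not np.allclose(d, d.T, equal_nan=True):
        raise InvariantViolation("distance matrix must be symmetric")
    if np.isnan(d).any():
        raise InputFormatError("distance matrix has missing entries")

    if isinstance(grouping, dict):
        labels = [grouping[s] for s in ids]
    elif isinstance(grouping, pd.Series):
        labels = [grouping.loc[s] for s in ids]
    else:
        labels = list(grouping)
        if len(labels) != n:
            raise InputFormatError("grouping length does not match sample count")
    uniq = sorted(set(map(str, labels)))
    if len(uniq) < 2:
        raise InputFormatError("PERMANOVA needs at least 2 groups")
    codes = np.array([uniq.index(str(l)) for l in labels])

    d2 = d**2
    f_obs, r2 = _permanova_f(d2, codes, len(uniq))
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    exceed = 0
    for _ in range(n_perm):
        f_perm, _ = _permanova_f(d2, codes[rng.permutation(n)], len(uniq))
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(grouping_name, float(f_obs), float(r2), float(p), n_perm)


def kruskal_stress(dissimilarities: np.ndarray, coordinates: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix.

    Disparities are the monotone (isotonic) regression of configuration
    distances on dissimilarity ranks;
    ``stress = sqrt(sum (dist - disparity)^2 / sum dist^2)``. Depends on the
    coordinates only through their pairwise distances, so it is invariant to
    rotation, reflection and translation of the configuration.
    """
    from scipy.spatial.distance import pdist
    from sklearn.isotonic import IsotonicRegression

    d = np.asarray(dissimilarities, dtype=float)
    iu = np.triu_indices(d.shape[0], 1)
    target = d[iu]
    conf = pdist(np.asarray(coordinates, dtype=float))
    order = np.argsort(target, kind="stable")
    disparities = np.empty_like(conf)
    disparities[order] = IsotonicRegression().fit_transform(
        np.arange(order.size), conf[order]
    )
    denom = float((conf**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((conf - disparities) ** 2).sum() / denom))


def nmds(
    dist: BetaMntdMatrix | pd.DataFrame,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NmdsResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Runs ``n_restarts`` random initializations of iterative monotone
    regression / gradient (SMACOF) steps and returns the best configuration.
    """
    if isinstance(dist, BetaMntdMatrix):
        ids = dist.sample_ids
        d = dist.values
    else:
        ids = list(map(str, dist.index))
        d = dist.to_numpy(dtype=float)
    n = len(ids)
    if k < 1:
        raise InputFormatError(f"k must be >= 1, got {k}")
    if k >= n:
        raise InputFormatError(f"k = {k} must be smaller than n_samples = {n}")
    if np.isnan(d).any():
        raise InputFormatError("distance matrix has missing entries")

    model = _SkMDS(
        n_components=k,
        metric="precomputed",
        metric_mds=False,
        init="random",
        n_init=n_restarts,
        max_iter=max_iter,
        eps=tol,
        random_state=int(seed) % (2**32),
        normalized_stress=True,
    )
    coords = model.fit_transform(d)
    return NmdsResult(list(ids), coords, float(model.stress_))
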