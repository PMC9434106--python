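"""Patristic distances and between-community mean-nearest-taxon distance.

The abundance-weighted beta mean nearest taxon distance (βMNTD) between two
communities A and B is

    βMNTD(A, B) = 0.5 * [ sum_{i in A} f_i * min_{j in B} d(i, j)
                        + sum_{j in B} f_j * min_{i in A} d(i, j) ]

where f are within-sample relative abundances, d is the patristic (cophenetic)
tip-to-tip distance on the phylogeny, and the minima run over taxa with
non-zero abundance in the other community. A taxon present in both communities
matches itself at distance zero, so βMNTD(A, A) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import InvariantViolation
from .io import OtuTable

__all__ = [
    "PatristicMatrix",
    "BetaMntdMatrix",
    "cophenetic_distances",
    "relative_abundances",
    "beta_mntd",
    "beta_mntd_pair",
]


@dataclass
class PatristicMatrix:
    """Symmetric tip-to-tip branch-length distance matrix."""

    taxon_ids: list[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = list(map(str, self.taxon_ids))
        self.distances = np.asarray(self.distances, dtype=float)
        n = len(self.taxon_ids)
        if self.distances.shape != (n, n):
            raise InvariantViolation("patristic matrix shape does not match ids")
        if not np.allclose(self.distances, self.distances.T):
            raise InvariantViolation("patristic matrix must be symmetric")
        if (self.distances < 0).any():
            raise InvariantViolation("patristic distances must be non-negative")
        if not np.allclose(np.diag(self.distances), 0):
            raise InvariantViolation("patristic matrix must have a zero diagonal")
        self._index = {t: i for i, t in enumerate(self.taxon_ids)}

    def indices_of(self, taxa: list[str]) -> np.ndarray:
        try:
            return np.array([self._index[t] for t in taxa], dtype=int)
        except KeyError as exc:
            raise InvariantViolation(f"taxon {exc.args[0]!r} not in patristic matrix")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=self.taxon_ids, columns=self.taxon_ids)


@dataclass
class BetaMntdMatrix:
    """Square βMNTD matrix over samples (symmetric, zero diagonal)."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise InvariantViolation("βMNTD matrix shape does not match sample ids")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


def cophenetic_distances(tree: TreeNode) -> PatristicMatrix:
    """Sum of branch lengths along the path between every pair of tips."""
    tips = [t.name for t in tree.tips()]
    if len(tips) < 2:
        raise InvariantViolation("tree must have at least 2 tips")
    dm = tree.tip_tip_distances()
    order = [dm.index(t) for t in tips]
    return PatristicMatrix(tips, dm.data[np.ix_(order, order)])


def relative_abundances(table: OtuTable) -> np.ndarray:
    """Per-sample proportions; every row sums to 1."""
    totals = table.sample_totals()
    if (totals <= 0).any():
        sid = table.sample_ids[int(np.argmax(totals <= 0))]
        raise InvariantViolation(f"sample {sid!r} has zero total abundance")
    return table.counts / totals[:, None]


def _nearest_taxon_terms(
    wa: np.ndarray, wb: np.ndarray, dsub: np.ndarray
) -> float:
    # dsub is the patristic submatrix restricted to A's taxa (rows) x B's (cols)
    return 0.5 * (wa @ dsub.min(axis=1) + wb @ dsub.min(axis=0))


def beta_mntd_pair(
    fa: np.ndarray,
    fb: np.ndarray,
    dist: np.ndarray,
) -> float:
    """βMNTD between two relative-abundance vectors over a shared taxon index."""
    a = np.flatnonzero(fa > 0)
    b = np.flatnonzero(fb > 0)
    if a.size == 0 or b.size == 0:
        raise InvariantViolation("βMNTD needs at least one taxon in each community")
    dsub = dist[np.ix_(a, b)]
    return float(_nearest_taxon_terms(fa[a], fb[b], dsub))


def beta_mntd(
    table: OtuTable,
    dist: PatristicMatrix,
    abundance_weighted: bool = True,
    pairs: list[tuple[str, str]] | None = None,
) -> BetaMntdMatrix:
    """Pairwise βMNTD over the samples of an OTU table.

    Parameters
    ----------
    table : OtuTable
        Abundances; taxa with non-zero abundance must appear in ``dist``.
    dist : PatristicMatrix
        Cophenetic distances; may contain extra taxa.
    abundance_weighted : bool
        Weight each taxon by its relative abundance (the pipeline default);
        otherwise each present taxon carries weight 1/richness.
    pairs : list of (sample_a, sample_b), optional
        Restrict computation to these pairs; other cells are NaN.

    Returns
    -------
    BetaMntdMatrix
        Symmetric with zero diagonal (NaN off-diagonal where not requested).
    """
    present = table.counts.sum(axis=0) > 0
    used_taxa = [t for t, p in zip(table.taxon_ids, present) if p]
    cols = dist.indices_of(used_taxa)
    dsub_all = dist.distances[np.ix_(cols, cols)]

    freq = relative_abundances(table)[:, present]
    if not abundance_weighted:
        freq = (freq > 0).astype(float)
        freq /= freq.sum(axis=1, keepdims=True)

    n = table.n_samples
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 0.0)
    if pairs is None:
        index_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        index_pairs = [
            (table.sample_index(a), table.sample_index(b)) for a, b in pairs
        ]
    for i, j in index_pairs:
        v = beta_mntd_pair(freq[i], freq[j], dsub_all)
        out[i, j] = out[j, i] = v
    return BetaMntdMatrix(list(table.sample_ids), out)
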