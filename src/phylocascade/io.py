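"""Readers, writers and table-level preprocessing.

External artifacts are plain text: OTU tables, sample metadata, taxonomy and
environmental tables are tab-separated; phylogenies are newick. The internal
orientation convention is samples as rows and taxa as columns; files using the
transposed dialect are handled with ``taxa_as_rows=True`` at the boundary.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import InputFormatError, InvariantViolation

logger = logging.getLogger(__name__)

SEASON_OF_EVENT_PREFIX = {"D": "dry", "R": "rainy"}


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class OtuTable:
    """Non-negative abundance matrix, samples x taxa, with aligned id lists.

    Parameters
    ----------
    sample_ids : list of str
        Unique row labels.
    taxon_ids : list of str
        Unique column labels.
    counts : ndarray of shape (n_samples, n_taxa)
        Non-negative abundances (counts or relative abundances).
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.taxon_ids = list(map(str, self.taxon_ids))
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise InvariantViolation("counts must be a 2-D matrix")
        n_s, n_t = self.counts.shape
        if n_s != len(self.sample_ids) or n_t != len(self.taxon_ids):
            raise InvariantViolation(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        for kind, ids in (("sample", self.sample_ids), ("taxon", self.taxon_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise InvariantViolation(f"duplicate {kind} id: {dup!r}")
        if not np.isfinite(self.counts).all():
            bad = np.argwhere(~np.isfinite(self.counts))[0]
            raise InvariantViolation(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"taxon {self.taxon_ids[bad[1]]!r}"
            )
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise InvariantViolation(
                f"negative abundance at sample {self.sample_ids[bad[0]]!r}, "
                f"taxon {self.taxon_ids[bad[1]]!r}"
            )

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise InputFormatError(f"unknown sample id: {sample_id!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OtuTable":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def select_samples(self, sample_ids: list[str]) -> "OtuTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return OtuTable(list(sample_ids), list(self.taxon_ids), self.counts[idx])

    def drop_empty_taxa(self) -> "OtuTable":
        keep = self.counts.sum(axis=0) > 0
        return OtuTable(
            list(self.sample_ids),
            [t for t, k in zip(self.taxon_ids, keep) if k],
            self.counts[:, keep],
        )


def _first_duplicate(ids: list[str]) -> str | None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            return i
        seen.add(i)
    return None


@dataclass
class SampleMetadata:
    """Per-sample design annotations for the cascade study.

    Wraps a DataFrame indexed by sample id with columns ``reservoir``,
    ``season``, ``event`` and optionally ``fraction`` / ``subcommunity``.
    The event code implies the season (D* -> dry, R* -> rainy); a mismatch is
    rejected at construction.
    """

    frame: pd.DataFrame

    REQUIRED = ("reservoir", "season", "event")

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise InvariantViolation(f"duplicate sample id in metadata: {dup!r}")
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise InputFormatError(f"metadata missing column(s): {', '.join(missing)}")
        for sid, row in self.frame.iterrows():
            implied = SEASON_OF_EVENT_PREFIX.get(str(row["event"])[:1])
            if implied is None:
                raise InvariantViolation(
                    f"sample {sid!r}: event {row['event']!r} must start with D or R"
                )
            if row["season"] != implied:
                raise InvariantViolation(
                    f"sample {sid!r}: event {row['event']!r} implies season "
                    f"{implied!r} but metadata says {row['season']!r}"
                )

    def require_samples(self, sample_ids: list[str]) -> None:
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise InvariantViolation(
                f"samples without metadata rows: {', '.join(map(repr, missing))}"
            )

    def subset(self, sample_ids: list[str]) -> "SampleMetadata":
        self.require_samples(sample_ids)
        return SampleMetadata(self.frame.loc[sample_ids].copy())


@dataclass
class TaxonomyTable:
    """Ranked lineage strings per taxon (domain ... genus), indexed by taxon id."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise InvariantViolation(f"duplicate taxon id in taxonomy: {dup!r}")

    def ranks(self) -> list[str]:
        return list(self.frame.columns)


# ---------------------------------------------------------------------------
# OTU table I/O
# ---------------------------------------------------------------------------


def read_otu_table(path: str | Path, taxa_as_rows: bool = False) -> OtuTable:
    """Read a tab-separated abundance matrix.

    First row holds taxon ids, first column sample ids (or the transpose with
    ``taxa_as_rows=True``). Every body cell must parse as a non-negative
    number; offending cells are reported by sample and taxon id.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                         keep_default_na=False)
    except Exception as exc:  # pandas raises several parser error types
        raise InputFormatError(f"{path}: cannot parse as TSV matrix: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise InputFormatError(f"{path}: empty table")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise InputFormatError(
            f"{path}: non-numeric or missing cell at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} (value {df.iloc[r, c]!r})"
        )
    if taxa_as_rows:
        numeric = numeric.T
    try:
        return OtuTable.from_dataframe(numeric)
    except InvariantViolation as exc:
        raise InputFormatError(f"{path}: {exc}") from exc


def write_otu_table(table: OtuTable, path: str | Path, taxa_as_rows: bool = False) -> None:
    df = table.to_dataframe()
    if taxa_as_rows:
        df = df.T
    df.to_csv(path, sep="\t", index_label="sample_id" if not taxa_as_rows else "taxon_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                         keep_default_na=False)
    except Exception as exc:
        raise InputFormatError(f"{path}: cannot parse metadata TSV: {exc}") from exc
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                         keep_default_na=False)
    except Exception as exc:
        raise InputFormatError(f"{path}: cannot parse taxonomy TSV: {exc}") from exc
    return TaxonomyTable(df)


def read_env_table(path: str | Path) -> pd.DataFrame:
    """Environmental variable matrix: samples x numeric variables."""
    try:
        # sample ids like "NA" must stay strings, not become missing values
        df = pd.read_csv(path, sep="\t", index_col=0,
                         keep_default_na=False, na_values=[""])
        df.index = df.index.astype(str)
    except Exception as exc:
        raise InputFormatError(f"{path}: cannot parse environment TSV: {exc}") from exc
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise InputFormatError(
            f"{path}: non-numeric environmental column(s): {', '.join(non_numeric)}"
        )
    return df


# ---------------------------------------------------------------------------
# Tree I/O
# ---------------------------------------------------------------------------


def _validate_tree(tree: TreeNode, origin: str) -> TreeNode:
    tips = [t.name for t in tree.tips()]
    if len(tips) < 2:
        raise InputFormatError(f"{origin}: tree must have at least 2 tips")
    dup = _first_duplicate(tips)
    if dup is not None:
        raise InputFormatError(f"{origin}: duplicate tip label {dup!r}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if node.is_tip():
                raise InputFormatError(
                    f"{origin}: tip {node.name!r} has no branch length"
                )
            node.length = 0.0  # unlabeled internal edges contribute no distance
        elif node.length < 0:
            raise InputFormatError(
                f"{origin}: negative branch length {node.length} "
                f"on edge above {node.name or 'an internal node'!r}"
            )
    return tree


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted newick tree with branch lengths on all tip edges."""
    path = Path(path)
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise InputFormatError(f"{path}: cannot parse newick: {exc}") from exc
    return _validate_tree(tree, str(path))


def parse_tree(newick: str) -> TreeNode:
    """Parse a newick string (same validation as :func:`read_tree`)."""
    try:
        tree = TreeNode.read(StringIO(newick), format="newick")
    except Exception as exc:
        raise InputFormatError(f"cannot parse newick string: {exc}") from exc
    return _validate_tree(tree, "<string>")


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Rarefaction and subcommunity extraction
# ---------------------------------------------------------------------------


def _sample_rng(master_seed: int, sample_id: str) -> np.random.Generator:
    # Per-sample stream keyed by a stable hash of the id, so dropping one
    # sample never perturbs the draws of the others.
    key = zlib.crc32(sample_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))


def rarefy(table: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Subsample every sample to a common depth without replacement.

    ``depth=None`` uses the minimum sample total (rounded down). Samples whose
    total is below the depth are dropped with a warning; taxa left with
    all-zero columns are removed. Deterministic given ``seed``.
    """
    totals = table.sample_totals()
    if depth is None:
        depth = int(np.floor(totals.min()))
    depth = int(depth)
    if depth <= 0:
        raise InputFormatError(f"rarefaction depth must be positive, got {depth}")
    if not np.allclose(table.counts, np.round(table.counts)):
        raise InputFormatError("rarefaction requires integer counts")

    keep_rows, new_counts = [], []
    for i, sid in enumerate(table.sample_ids):
        total = int(round(totals[i]))
        if total < depth:
            logger.warning(
                "rarefy: dropping sample %r (total %d < depth %d)", sid, total, depth
            )
            continue
        counts = np.round(table.counts[i]).astype(np.int64)
        if total == depth:
            new = counts
        else:
            rng = _sample_rng(seed, sid)
            new = rng.multivariate_hypergeometric(counts, depth)
        keep_rows.append(sid)
        new_counts.append(new)
    if not keep_rows:
        raise InvariantViolation(f"no sample reaches rarefaction depth {depth}")
    out = OtuTable(keep_rows, list(table.taxon_ids), np.array(new_counts, dtype=float))
    return out.drop_empty_taxa()


def extract_subcommunity(
    table: OtuTable, taxonomy: TaxonomyTable, rank: str, value: str
) -> OtuTable:
    """Restrict the table to taxa whose ``rank`` equals ``value``.

    Samples left with zero total are dropped with a warning. Output cells are
    copies of the corresponding input cells; nothing is rescaled.
    """
    if rank not in taxonomy.frame.columns:
        raise InputFormatError(
            f"rank {rank!r} not in taxonomy (has: {', '.join(taxonomy.ranks())})"
        )
    missing = [t for t in table.taxon_ids if t not in taxonomy.frame.index]
    if missing:
        raise InvariantViolation(
            f"taxa without taxonomy rows: {', '.join(map(repr, missing[:5]))}"
            + ("..." if len(missing) > 5 else "")
        )
    lineage = taxonomy.frame.loc[table.taxon_ids, rank]
    mask = (lineage == value).to_numpy()
    if not mask.any():
        raise InputFormatError(f"no taxon matches {rank} == {value!r}")
    taxa = [t for t, m in zip(table.taxon_ids, mask) if m]
    counts = table.counts[:, mask]
    row_ok = counts.sum(axis=1) > 0
    for sid, ok in zip(table.sample_ids, row_ok):
        if not ok:
            logger.warning(
                "extract_subcommunity: dropping sample %r (empty after %s == %s)",
                sid, rank, value,
            )
    samples = [s for s, ok in zip(table.sample_ids, row_ok) if ok]
    return OtuTable(samples, taxa, counts[row_ok])


def prune_table_to_tree(
    table: OtuTable, tree: TreeNode, allow_prune: bool = False
) -> OtuTable:
    """Reconcile table taxa with tree tips.

    Taxa absent from the tree are an error by default; with
    ``allow_prune=True`` they are dropped with a logged count instead.
    """
    tips = {t.name for t in tree.tips()}
    missing = [t for t in table.taxon_ids if t not in tips]
    if not missing:
        return table
    if not allow_prune:
        raise InvariantViolation(
            f"{len(missing)} table taxa are not tips of the tree "
            f"(first few: {', '.join(map(repr, missing[:5]))}); "
            "pass allow_prune/--prune-to-tree to drop them"
        )
    logger.warning("pruning %d taxa absent from the tree", len(missing))
    keep = np.array([t in tips for t in table.taxon_ids])
    return OtuTable(
        list(table.sample_ids),
        [t for t, k in zip(table.taxon_ids, keep) if k],
        table.counts[:, keep],
    )
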