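"""Randomization stages of the assembly-process framework.

Two nulls are computed per sample pair:

* **βNTI** — the observed βMNTD is compared against a null distribution built
  by shuffling taxon identities across the tips of the phylogeny (i.e. across
  the rows/columns of the patristic matrix) and recomputing βMNTD:
  ``βNTI = (βMNTD_obs - mean_null) / sd_null``. ``|βNTI| > 2`` marks pairs
  whose phylogenetic turnover departs from the null strongly enough to be
  attributed to selection.

* **RC_bray** — an abundance-based Raup-Crick index. Each null iteration
  reassembles both samples preserving observed richness (taxa drawn without
  replacement with probability proportional to occupancy across the analyzed
  table) and observed total abundance (each drawn taxon receives one
  individual, the rest are assigned multinomially with probability
  proportional to metacommunity relative abundance). With
  ``alpha = [#(BC_null < BC_obs) + 0.5 * #(BC_null == BC_obs)] / n_iter``,
  ``RC_bray = 2*alpha - 1``, bounded in [-1, 1].
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputFormatError, InvariantViolation
from .io import OtuTable
from .turnover import PatristicMatrix, relative_abundances

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "bray_curtis",
    "beta_nti",
    "raup_crick_bray",
]

#: floating-point tolerance below which two Bray-Curtis values count as tied
BC_TIE_TOL = 1e-12


@dataclass
class NullDistribution:
    """An observed statistic with its null draws."""

    observed: float
    null_values: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def sd(self) -> float:
        return float(np.std(self.null_values, ddof=1))

    @property
    def z(self) -> float:
        sd = self.sd
        if sd == 0 or not np.isfinite(sd):
            return float("nan")
        return (self.observed - self.mean) / sd


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity ``sum |x-y| / sum (x+y)`` in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise InvariantViolation("Bray-Curtis requires non-negative vectors")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise InvariantViolation("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def _pair_seed_sequence(seed: int, a: str, b: str) -> np.random.SeedSequence:
    # Stable per-pair substream: results do not depend on evaluation order.
    return np.random.SeedSequence(
        [int(seed), zlib.crc32(a.encode()), zlib.crc32(b.encode())]
    )


def _all_pairs(sample_ids: list[str]) -> list[tuple[str, str]]:
    return [
        (sample_ids[i], sample_ids[j])
        for i in range(len(sample_ids))
        for j in range(i + 1, len(sample_ids))
    ]


def beta_nti(
    table: OtuTable,
    dist: PatristicMatrix,
    n_iter: int = 999,
    seed: int = 0,
    pairs: list[tuple[str, str]] | None = None,
    abundance_weighted: bool = True,
    per_pair_shuffle: bool = False,
) -> pd.DataFrame:
    """Beta nearest taxon index for sample pairs of a table.

    By default one taxon-identity permutation per iteration is shared by all
    pairs (consistent nulls and a large speedup); ``per_pair_shuffle=True``
    draws independent permutations per pair from pair-keyed substreams.

    Returns a DataFrame with columns ``sample_a, sample_b, bmntd_obs,
    null_mean, null_sd, bnti, n_iter, seed``. Pairs whose null has zero
    spread get ``bnti = NaN`` with a warning (they fall through to the
    Raup-Crick stage of the pipeline).
    """
    if n_iter < 2:
        raise InputFormatError(f"n_iter must be >= 2, got {n_iter}")
    if table.n_samples < 2:
        raise InvariantViolation("βNTI needs at least 2 samples")
    if pairs is None:
        pairs = _all_pairs(table.sample_ids)

    pool_idx = dist.indices_of(table.taxon_ids)
    d_pool = dist.distances[np.ix_(pool_idx, pool_idx)]
    n_pool = len(pool_idx)

    freq = relative_abundances(table)
    if not abundance_weighted:
        freq = (freq > 0).astype(float)
        freq /= freq.sum(axis=1, keepdims=True)

    supports = [np.flatnonzero(freq[i] > 0) for i in range(table.n_samples)]
    weights = [freq[i][supports[i]] for i in range(table.n_samples)]
    pair_idx = [(table.sample_index(a), table.sample_index(b)) for a, b in pairs]

    def _pair_value(i: int, j: int, order: np.ndarray) -> float:
        dsub = d_pool[np.ix_(order[supports[i]], order[supports[j]])]
        return 0.5 * (weights[i] @ dsub.min(axis=1) + weights[j] @ dsub.min(axis=0))

    identity = np.arange(n_pool)
    obs = np.array([_pair_value(i, j, identity) for i, j in pair_idx])

    null = np.empty((len(pairs), n_iter))
    if per_pair_shuffle:
        for p, ((a, b), (i, j)) in enumerate(zip(pairs, pair_idx)):
            rng = np.random.default_rng(_pair_seed_sequence(seed, a, b))
            for r in range(n_iter):
                null[p, r] = _pair_value(i, j, rng.permutation(n_pool))
    else:
        rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
        for r in range(n_iter):
            order = rng.permutation(n_pool)
            for p, (i, j) in enumerate(pair_idx):
                null[p, r] = _pair_value(i, j, order)

    null_mean = null.mean(axis=1)
    null_sd = null.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = (obs - null_mean) / null_sd
    degenerate = null_sd == 0
    if degenerate.any():
        for p in np.flatnonzero(degenerate):
            logger.warning(
                "βNTI undefined for pair (%s, %s): null distribution has zero "
                "spread; forwarding to the Raup-Crick stage",
                pairs[p][0], pairs[p][1],
            )
        bnti[degenerate] = np.nan

    return pd.DataFrame(
        {
            "sample_a": [a for a, _ in pairs],
            "sample_b": [b for _, b in pairs],
            "bmntd_obs": obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "bnti": bnti,
            "n_iter": n_iter,
            "seed": seed,
        }
    )


def _weighted_sample_without_replacement(
    rng: np.random.Generator, log_w: np.ndarray, k: int
) -> np.ndarray:
    # Efraimidis-Spirakis via Gumbel keys: top-k of log(w) + Gumbel noise is a
    # weighted sample without replacement.
    keys = log_w + rng.gumbel(size=log_w.size)
    if k >= log_w.size:
        return np.arange(log_w.size)
    return np.argpartition(-keys, k)[:k]


def _null_assemble(
    rng: np.random.Generator,
    log_occ: np.ndarray,
    meta_p: np.ndarray,
    richness: int,
    total: int,
) -> np.ndarray:
    """One null community over the metacommunity taxon index."""
    support = _weighted_sample_without_replacement(rng, log_occ, richness)
    vec = np.zeros(meta_p.size)
    p = meta_p[support]
    vec[support] = 1.0
    remaining = total - support.size
    if remaining > 0:
        vec[support] += rng.multinomial(remaining, p / p.sum())
    return vec


def raup_crick_bray(
    table: OtuTable,
    pairs: list[tuple[str, str]] | None = None,
    n_iter: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Abundance-based Raup-Crick index (Bray-Curtis nulls) per sample pair.

    Occupancy and metacommunity abundance weights are taken from all samples
    of ``table`` — the table submitted here defines the metacommunity.
    Returns a DataFrame with columns ``sample_a, sample_b, bc_obs, rc_bray,
    n_iter, seed``; ``rc_bray`` lies in [-1, 1].
    """
    if n_iter < 2:
        raise InputFormatError(f"n_iter must be >= 2, got {n_iter}")
    if pairs is None:
        pairs = _all_pairs(table.sample_ids)
    totals = table.sample_totals()
    if (totals <= 0).any():
        sid = table.sample_ids[int(np.argmax(totals <= 0))]
        raise InvariantViolation(f"sample {sid!r} has zero total abundance")
    counts = np.round(table.counts)
    if not np.allclose(counts, table.counts):
        raise InputFormatError("Raup-Crick requires integer counts")

    occupancy = (counts > 0).sum(axis=0).astype(float)
    meta_abund = counts.sum(axis=0)
    in_meta = occupancy > 0
    occ = occupancy[in_meta]
    meta_p = meta_abund[in_meta] / meta_abund[in_meta].sum()
    log_occ = np.log(occ)
    sub_counts = counts[:, in_meta]

    rows = []
    for a, b in pairs:
        i, j = table.sample_index(a), table.sample_index(b)
        xa, xb = sub_counts[i], sub_counts[j]
        ka, kb = int((xa > 0).sum()), int((xb > 0).sum())
        ja, jb = int(xa.sum()), int(xb.sum())
        if ka > occ.size or kb > occ.size:  # impossible by construction; guarded
            raise InvariantViolation("sample richness exceeds metacommunity richness")
        bc_obs = bray_curtis(xa, xb)
        rng = np.random.default_rng(_pair_seed_sequence(seed, a, b))
        below = ties = 0
        for _ in range(n_iter):
            na = _null_assemble(rng, log_occ, meta_p, ka, ja)
            nb = _null_assemble(rng, log_occ, meta_p, kb, jb)
            bc_null = bray_curtis(na, nb)
            if bc_null < bc_obs - BC_TIE_TOL:
                below += 1
            elif abs(bc_null - bc_obs) <= BC_TIE_TOL:
                ties += 1
        alpha = (below + 0.5 * ties) / n_iter
        rows.append((a, b, bc_obs, 2.0 * alpha - 1.0))

    out = pd.DataFrame(rows, columns=["sample_a", "sample_b", "bc_obs", "rc_bray"])
    out["n_iter"] = n_iter
    out["seed"] = seed
    return out
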