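"""Calibration and recovery experiments for the null-model pipeline.

These functions generate synthetic data under known conditions, run the
package's own machinery on them, and report calibration quantities: the
false-positive rate of βNTI under a phylogeny-agnostic null, the centering
of RC_bray on neutral assemblies, end-to-end process-recovery rates, and the
empirical type-I error of the PERMANOVA permutation test. They exist so the
method's operating characteristics can be recomputed from scratch at any
time rather than asserted.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .inference import classify_pair
from .io import OtuTable
from .nulls import beta_nti, raup_crick_bray
from .pipeline import PipelineConfig, run_pipeline
from .simulate import (
    EVEN_POOL_LOGNORMAL_SIGMA,
    ScenarioSpec,
    generate_cascade_study,
    generate_scenario,
    simulate_tree,
)
from .stats import permanova
from .turnover import cophenetic_distances

__all__ = [
    "beta_nti_false_positive_rate",
    "neutral_rc_values",
    "identical_pair_rc",
    "process_recovery_rates",
    "cascade_classified_counts",
    "permanova_type_i_error",
]


def beta_nti_false_positive_rate(
    n_replicates: int = 100,
    n_iter: int = 999,
    seed: int = 0,
    n_taxa: int = 50,
    community_size: int = 500,
) -> float:
    """Fraction of neutral pairs with |βNTI| > 2.

    Each replicate metacommunity draws two communities multinomially from a
    lognormal pool generated independently of the phylogeny, so the
    tip-shuffle null holds and the nominal two-sided exceedance of a z-like
    score at ±2 should stay modest (≤ 10%).
    """
    root = np.random.SeedSequence([int(seed), 0xFB11])
    hits = 0
    for rep, child in enumerate(root.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        tree = simulate_tree(n_taxa, seed=int(child.generate_state(1)[0] % 2**31))
        dist = cophenetic_distances(tree)
        w = rng.lognormal(0.0, 1.0, n_taxa)
        pool = w / w.sum()
        counts = np.vstack([rng.multinomial(community_size, pool) for _ in range(2)])
        counts[:, 0] += counts.sum(axis=1) == 0
        table = OtuTable(["A", "B"], dist.taxon_ids, counts.astype(float))
        res = beta_nti(table, dist, n_iter=n_iter,
                       seed=int(child.generate_state(2)[1] % 2**31))
        b = res["bnti"].iloc[0]
        if np.isfinite(b) and abs(b) > 2:
            hits += 1
    return hits / n_replicates


def neutral_rc_values(
    n_replicates: int = 100,
    n_iter: int = 999,
    seed: int = 0,
    n_taxa: int = 200,
    community_size: int = 800,
    n_context: int = 8,
) -> np.ndarray:
    """RC_bray of one neutral same-pool pair per replicate metacommunity.

    Communities are multinomial draws from an even lognormal pool (the
    generator's drift conditions); the distribution over replicates should be
    centered near zero.
    """
    root = np.random.SeedSequence([int(seed), 0x2C09])
    out = np.empty(n_replicates)
    for rep, child in enumerate(root.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        w = rng.lognormal(0.0, EVEN_POOL_LOGNORMAL_SIGMA, n_taxa)
        pool = w / w.sum()
        ids = ["A", "B"] + [f"C{i}" for i in range(n_context)]
        counts = np.vstack(
            [rng.multinomial(community_size, pool) for _ in ids]
        ).astype(float)
        table = OtuTable(ids, [f"t{i}" for i in range(n_taxa)], counts)
        res = raup_crick_bray(table, pairs=[("A", "B")], n_iter=n_iter,
                              seed=int(child.generate_state(2)[1] % 2**31))
        out[rep] = res["rc_bray"].iloc[0]
    return out


def identical_pair_rc(seed: int = 0, n_iter: int = 999) -> float:
    """RC_bray of a pair of identical samples inside a varied metacommunity."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1D]))
    n = 60
    base = rng.integers(1, 40, n).astype(float)
    context = rng.integers(0, 40, size=(6, n)).astype(float)
    context[:, 0] += 1
    table = OtuTable(
        ["A", "B"] + [f"C{i}" for i in range(6)],
        [f"t{i}" for i in range(n)],
        np.vstack([base, base, context]),
    )
    res = raup_crick_bray(table, pairs=[("A", "B")], n_iter=n_iter, seed=int(seed))
    return float(res["rc_bray"].iloc[0])


def _classify_scenario_pair(ds, n_iter: int, seed: int) -> str:
    dist = cophenetic_distances(ds.tree)
    nti = beta_nti(ds.table, dist, n_iter=n_iter, seed=seed, pairs=[("A", "B")])
    b = nti["bnti"].iloc[0]
    if np.isfinite(b) and abs(b) > 2:
        return "S"
    rc = raup_crick_bray(ds.table, pairs=[("A", "B")], n_iter=n_iter, seed=seed)
    return classify_pair(float(b), float(rc["rc_bray"].iloc[0])).value


TRUE_LABEL = {
    "selection": "S",
    "homogenizing_dispersal": "HD",
    "dispersal_limitation": "DL",
    "drift": "D",
}


def process_recovery_rates(
    n_replicates: int = 50,
    n_iter: int = 999,
    seed: int = 0,
    **spec_overrides,
) -> dict[str, float]:
    """Fraction of simulated pairs receiving their generating process label.

    Scenarios run under the strong-effect defaults of :class:`ScenarioSpec`
    unless overridden.
    """
    rates = {}
    for process, truth in TRUE_LABEL.items():
        hits = 0
        for rep in range(n_replicates):
            spec = ScenarioSpec(
                process, seed=int(seed) * 100000 + rep * 7 + zlib.crc32(process.encode()) % 1000,
                **spec_overrides,
            )
            ds = generate_scenario(spec)
            label = _classify_scenario_pair(ds, n_iter=n_iter, seed=int(seed) + rep)
            hits += label == truth
        rates[process] = hits / n_replicates
    return rates


def cascade_classified_counts(
    seed: int = 0, n_iter: int = 299, n_taxa: int = 100, community_size: int = 2000
) -> dict[str, int]:
    """Classified adjacent-pair counts per season for a full synthetic study."""
    ds = generate_cascade_study(seed=seed, n_taxa=n_taxa, community_size=community_size)
    cfg = PipelineConfig(
        otu_table="", tree="", metadata="",
        n_iter_bnti=n_iter, n_iter_rc=n_iter, n_perm=99, nmds_restarts=4,
        seed=int(seed),
    )
    bundle = run_pipeline(cfg, table=ds.table, tree=ds.tree, metadata=ds.metadata,
                          env=ds.env)
    counts = bundle["per_pair"].groupby("season").size().to_dict()
    return {k: int(v) for k, v in counts.items()}


def permanova_type_i_error(
    n_simulations: int = 1000,
    n_perm: int = 199,
    seed: int = 0,
    n_samples: int = 12,
    n_features: int = 5,
    alpha: float = 0.05,
) -> float:
    """Empirical rejection rate of PERMANOVA under an exchangeable null.

    Distance matrices come from iid normal feature vectors; group labels are
    arbitrary, so the rejection rate should match the nominal level.
    """
    root = np.random.SeedSequence([int(seed), 0x9E12])
    labels = ["g1"] * (n_samples // 2) + ["g2"] * (n_samples - n_samples // 2)
    ids = [f"s{i}" for i in range(n_samples)]
    rejections = 0
    for child in root.spawn(n_simulations):
        rng = np.random.default_rng(child)
        pts = rng.normal(size=(n_samples, n_features))
        d = squareform(pdist(pts))
        res = permanova(
            pd.DataFrame(d, index=ids, columns=ids), labels, n_perm=n_perm,
            seed=int(child.generate_state(2)[1] % 2**31),
        )
        rejections += res.p_value <= alpha
    return rejections / n_simulations
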