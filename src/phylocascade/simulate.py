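"""Synthetic phylogenies, niche traits and communities with known assembly process.

The generators provide everything the downstream analysis consumes — a rooted
ultrametric tree, phylogenetically conserved habitat-preference traits
(Brownian motion along branches), and count tables assembled under each of
the four processes — so the whole pipeline is testable without sequence data.

Scenario constructions (``generate_scenario``):

* **selection** — two communities drawn from a shared species pool through
  Gaussian trait filters centered at environments ``-Δ/2`` and ``+Δ/2`` with
  width σ. Because traits are Brownian, filtering selects clades and the
  pair's phylogenetic turnover exceeds the tip-shuffle null (|βNTI| > 2).
* **homogenizing_dispersal** — the focal pair consists of two large draws
  (J ≥ 10·n_taxa) from one identical pool, embedded in a heterogeneous
  landscape of context samples from independent pools. Against that
  metacommunity the pair is far more similar than the Raup-Crick null
  (RC_bray → -1).
* **dispersal_limitation** — the two communities draw from phylogenetically
  random, mostly disjoint species pools (overlap controlled by
  ``pool_overlap``), so Bray-Curtis is near its maximum while βNTI stays
  null (RC_bray → +1).
* **drift** — independent moderate draws from one shared pool, embedded in a
  same-pool landscape; observed dissimilarity sits inside the null spread
  (|RC_bray| < 0.95, |βNTI| ≤ 2).

The context samples exist because the Raup-Crick null takes its occupancy
and metacommunity-abundance weights from the analyzed table: they play the
role of the other samples of a season x subcommunity table in the real
design. Species-abundance pools are lognormal, the common shape for
microbial communities; the drift pool is drawn with lower lognormal spread
so that essentially every pool taxon occurs in every sample — under a
strongly skewed pool, finite same-pool draws miss a random rare tail and the
richness-resampling null then makes any such pair look more similar than
chance (RC_bray → -1), which is a homogenizing-dispersal signature, not
drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import InputFormatError, InvariantViolation
from .io import OtuTable, SampleMetadata

__all__ = [
    "ScenarioSpec",
    "SyntheticDataset",
    "simulate_tree",
    "evolve_trait",
    "assemble_community",
    "generate_scenario",
    "generate_cascade_study",
    "PROCESSES",
]

PROCESSES = ("selection", "homogenizing_dispersal", "dispersal_limitation", "drift")

#: lognormal sigma of skewed species-abundance pools (natural-log scale)
POOL_LOGNORMAL_SIGMA = 1.5
#: lognormal sigma of even pools used for drift / neutral assembly
EVEN_POOL_LOGNORMAL_SIGMA = 0.5


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic assembly scenario with a known true process.

    Defaults are the strong-effect settings under which the pipeline is
    expected to recover the generating process for most pairs.
    """

    process: str
    n_taxa: int = 200
    community_size: int = 2000           # J, individuals per community
    filter_width: float = 0.5            # σ, trait units (selection)
    env_offset: float = 3.0              # Δ, trait units (selection)
    pool_overlap: float = 0.1            # shared support fraction (dispersal limitation)
    n_context: int | None = None         # landscape samples; per-process default
    duplicate_pair: bool = False         # reuse one stream for both focal samples
    seed: int = 0

    def __post_init__(self) -> None:
        if self.process not in PROCESSES:
            raise InputFormatError(
                f"unknown process {self.process!r}; expected one of {PROCESSES}"
            )
        if self.n_taxa < 4:
            raise InputFormatError("n_taxa must be >= 4")
        if self.community_size < 1:
            raise InputFormatError("community_size must be >= 1")
        if not 0 <= self.pool_overlap <= 1:
            raise InputFormatError("pool_overlap must lie in [0, 1]")
        if self.process == "selection" and not np.isfinite(self.filter_width):
            raise InputFormatError(
                "selection scenario requires a finite filter width (σ = inf "
                "disables the environmental filter)"
            )
        if self.filter_width <= 0:
            raise InputFormatError("filter_width must be positive")

    def resolved_context(self) -> int:
        if self.n_context is not None:
            return self.n_context
        return {"homogenizing_dispersal": 8, "drift": 8}.get(self.process, 0)


@dataclass
class SyntheticDataset:
    """A generated study: tree, traits, table, metadata, truth and environment."""

    tree: TreeNode
    traits: pd.Series
    table: OtuTable
    metadata: SampleMetadata
    truth: pd.DataFrame  # columns: sample_a, sample_b, process (plus event if present)
    env: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Primitive generators
# ---------------------------------------------------------------------------


def simulate_tree(n_taxa: int, seed: int = 0, birth_rate: float = 1.0) -> TreeNode:
    """Pure-birth (Yule) ultrametric tree with exponential waiting times.

    Tips are labeled ``t1 ... t<n>``; all branch lengths are positive.
    """
    if n_taxa < 2:
        raise InputFormatError(f"n_taxa must be >= 2, got {n_taxa}")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    root = TreeNode()
    t = 0.0
    active: list[tuple[TreeNode, float]] = [(root, 0.0)]
    while len(active) < n_taxa:
        n = len(active)
        t += rng.exponential(1.0 / (birth_rate * n))
        node, born = active.pop(int(rng.integers(n)))
        node.length = t - born
        children = [TreeNode(), TreeNode()]
        node.extend(children)
        active.extend((c, t) for c in children)
    # extend tips past the last split so every pendant edge has positive length
    t_end = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    for i, (node, born) in enumerate(active):
        node.length = t_end - born
        node.name = f"t{i + 1}"
    root.length = None
    return root


def evolve_trait(
    tree: TreeNode, sigma2: float = 1.0, root_value: float = 0.0, seed: int = 0
) -> pd.Series:
    """Brownian-motion trait along branches: child = parent + N(0, σ²·length).

    Returns the tip values indexed by tip label. ``sigma2 = 0`` leaves every
    tip at ``root_value``.
    """
    if sigma2 < 0:
        raise InputFormatError("sigma2 must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    values: dict[int, float] = {id(tree): float(root_value)}
    tips: dict[str, float] = {}
    for node in tree.preorder(include_self=False):
        parent_value = values[id(node.parent)]
        length = node.length or 0.0
        value = parent_value + rng.normal(0.0, np.sqrt(sigma2 * length))
        values[id(node)] = value
        if node.is_tip():
            tips[node.name] = value
    return pd.Series(tips, name="trait")


def _standardize(traits: pd.Series) -> pd.Series:
    sd = traits.std(ddof=0)
    if sd == 0:
        return traits - traits.mean()
    return (traits - traits.mean()) / sd


def assemble_community(
    pool: np.ndarray,
    traits: np.ndarray,
    env: float,
    sigma: float,
    community_size: int,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Multinomial draw of J individuals through a Gaussian environmental filter.

    Sampling probability is proportional to ``pool_i * exp(-(trait_i - env)^2
    / (2 σ^2))``; ``σ = inf`` disables the filter (neutral draw from the pool).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(np.random.SeedSequence(int(rng)))
    pool = np.asarray(pool, dtype=float)
    if pool.min() < 0 or not np.isclose(pool.sum(), 1.0):
        raise InputFormatError("pool must be a probability vector summing to 1")
    if community_size < 1:
        raise InputFormatError("community_size must be >= 1")
    if np.isinf(sigma):
        weights = pool.copy()
    else:
        traits = np.asarray(traits, dtype=float)
        weights = pool * np.exp(-((traits - env) ** 2) / (2.0 * sigma**2))
    total = weights.sum()
    if total <= 0 or not np.isfinite(total):
        raise InvariantViolation(
            "all filter weights vanished (environment too far from every trait)"
        )
    return rng.multinomial(community_size, weights / total)


def _lognormal_pool(
    rng: np.random.Generator, n: int, sigma: float = POOL_LOGNORMAL_SIGMA
) -> np.ndarray:
    w = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Scenario generation
# ---------------------------------------------------------------------------


def _scenario_metadata(sample_ids: list[str]) -> SampleMetadata:
    # scenarios are a single "event"; the cascade layout is irrelevant here
    frame = pd.DataFrame(
        {
            "reservoir": ["BB"] * len(sample_ids),
            "season": ["dry"] * len(sample_ids),
            "event": ["D1"] * len(sample_ids),
            "subcommunity": ["FL"] * len(sample_ids),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SampleMetadata(frame)


def generate_scenario(spec: ScenarioSpec) -> SyntheticDataset:
    """Generate the focal pair (samples ``A`` and ``B``) plus landscape context.

    The ground-truth process of the pair (A, B) is recorded in ``truth``.
    """
    root_seed = np.random.SeedSequence([int(spec.seed), 0x5CE7A210])
    s_tree, s_trait, s_pool, s_a, s_b, s_ctx = root_seed.spawn(6)
    rng_pool = np.random.default_rng(s_pool)
    rng_a = np.random.default_rng(s_a)
    rng_b = np.random.default_rng(s_a if spec.duplicate_pair else s_b)
    rng_ctx = np.random.default_rng(s_ctx)

    tree = simulate_tree(spec.n_taxa, seed=int(s_tree.generate_state(1)[0] % 2**31))
    taxa = [t.name for t in tree.tips()]
    traits = _standardize(
        evolve_trait(tree, sigma2=1.0, seed=int(s_trait.generate_state(1)[0] % 2**31))
    ).loc[taxa]
    trait_arr = traits.to_numpy()
    n = spec.n_taxa
    J = spec.community_size
    flat = np.inf  # no environmental filtering

    rows: list[np.ndarray] = []
    ids: list[str] = []

    def add(sample_id: str, counts: np.ndarray) -> None:
        ids.append(sample_id)
        rows.append(counts)

    if spec.process == "selection":
        pool = _lognormal_pool(rng_pool, n)
        half = spec.env_offset / 2.0
        add("A", assemble_community(pool, trait_arr, -half, spec.filter_width, J, rng_a))
        add("B", assemble_community(pool, trait_arr, +half, spec.filter_width, J, rng_b))
        for c in range(spec.resolved_context()):
            env_c = rng_ctx.uniform(-half, half)
            add(f"C{c+1}",
                assemble_community(pool, trait_arr, env_c, spec.filter_width, J, rng_ctx))

    elif spec.process == "homogenizing_dispersal":
        j_big = max(J, 10 * n)
        pool = _lognormal_pool(rng_pool, n)
        add("A", assemble_community(pool, trait_arr, 0.0, flat, j_big, rng_a))
        add("B", assemble_community(pool, trait_arr, 0.0, flat, j_big, rng_b))
        for c in range(spec.resolved_context()):
            ctx_pool = _lognormal_pool(rng_ctx, n)  # heterogeneous landscape
            add(f"C{c+1}", assemble_community(ctx_pool, trait_arr, 0.0, flat, J, rng_ctx))

    elif spec.process == "dispersal_limitation":
        support_size = max(2, n // 2)
        n_shared = int(round(spec.pool_overlap * support_size))
        order = rng_pool.permutation(n)
        shared = order[:n_shared]
        own = support_size - n_shared
        sup_a = np.concatenate([shared, order[n_shared : n_shared + own]])
        sup_b = np.concatenate([shared, order[n_shared + own : n_shared + 2 * own]])
        pool_a = np.zeros(n)
        pool_b = np.zeros(n)
        pool_a[sup_a] = _lognormal_pool(rng_pool, sup_a.size)
        pool_b[sup_b] = _lognormal_pool(rng_pool, sup_b.size)
        add("A", assemble_community(pool_a, trait_arr, 0.0, flat, J, rng_a))
        add("B", assemble_community(pool_b, trait_arr, 0.0, flat, J, rng_b))
        for c in range(spec.resolved_context()):
            mix = 0.5 * (pool_a + pool_b)
            add(f"C{c+1}", assemble_community(mix, trait_arr, 0.0, flat, J, rng_ctx))

    else:  # drift: moderate draws (4 individuals per pool taxon) from an even pool
        j_mod = max(1, min(J, 4 * n))
        pool = _lognormal_pool(rng_pool, n, sigma=EVEN_POOL_LOGNORMAL_SIGMA)
        add("A", assemble_community(pool, trait_arr, 0.0, flat, j_mod, rng_a))
        add("B", assemble_community(pool, trait_arr, 0.0, flat, j_mod, rng_b))
        for c in range(spec.resolved_context()):
            add(f"C{c+1}", assemble_community(pool, trait_arr, 0.0, flat, j_mod, rng_ctx))

    table = OtuTable(ids, taxa, np.array(rows, dtype=float))
    truth = pd.DataFrame(
        [{"sample_a": "A", "sample_b": "B", "process": spec.process}]
    )
    return SyntheticDataset(tree, traits, table, _scenario_metadata(ids), truth)


# ---------------------------------------------------------------------------
# Full cascade study
# ---------------------------------------------------------------------------


def generate_cascade_study(
    seed: int = 0,
    n_taxa: int = 150,
    community_size: int = 3000,
    reservoirs: tuple[str, ...] = ("BB", "Pr", "NA", "TI"),
    dry_events: tuple[str, ...] = ("D1", "D2", "D3"),
    rainy_events: tuple[str, ...] = ("R1", "R2", "R3"),
) -> SyntheticDataset:
    """A full synthetic study: 4 reservoirs x 6 events, one subcommunity.

    A trophic gradient decreases along the cascade. Dry-season events impose
    strong, reservoir-specific environmental filtering with little mixing
    (true process between adjacent reservoirs: selection); rainy-season
    events flatten the gradient and draw every reservoir's community from a
    common, well-mixed event pool (true process: homogenizing dispersal).
    An environmental table (trophic state, residence time, temperature, DOC,
    total nitrogen) is emitted alongside.
    """
    root_seed = np.random.SeedSequence([int(seed), 0xCA5CADE])
    s_tree, s_trait, s_pool, s_comm, s_env = root_seed.spawn(5)
    rng_pool = np.random.default_rng(s_pool)
    rng_comm = np.random.default_rng(s_comm)
    rng_env = np.random.default_rng(s_env)

    tree = simulate_tree(n_taxa, seed=int(s_tree.generate_state(1)[0] % 2**31))
    taxa = [t.name for t in tree.tips()]
    traits = _standardize(
        evolve_trait(tree, sigma2=1.0, seed=int(s_trait.generate_state(1)[0] % 2**31))
    ).loc[taxa]
    trait_arr = traits.to_numpy()
    pool = _lognormal_pool(rng_pool, n_taxa)

    # trophic gradient along the cascade, in trait units; shrunk in the rain
    base_env = np.linspace(1.5, -1.5, len(reservoirs))
    season_scale = {"dry": 1.0, "rainy": 0.35}
    sigma_dry = 0.6

    ids, rows, meta_rows, env_rows, truth_rows = [], [], [], [], []
    events = [(e, "dry") for e in dry_events] + [(e, "rainy") for e in rainy_events]
    for event, season in events:
        event_shift = rng_env.normal(0.0, 0.15)  # same for all reservoirs in the event
        env_values = base_env * season_scale[season] + event_shift
        if season == "rainy":
            # well-mixed event pool: mass effects overwhelm local filtering
            event_pool = pool * np.exp(
                -((trait_arr - event_shift) ** 2) / (2 * 2.5**2)
            )
            event_pool = event_pool / event_pool.sum()
        for r, res in enumerate(reservoirs):
            sid = f"{res}_{event}"
            if season == "dry":
                counts = assemble_community(
                    pool, trait_arr, env_values[r], sigma_dry, community_size, rng_comm
                )
            else:
                counts = assemble_community(
                    event_pool, trait_arr, 0.0, np.inf,
                    max(community_size, 10 * n_taxa), rng_comm,
                )
            ids.append(sid)
            rows.append(counts)
            meta_rows.append((sid, res, season, event, "FL"))
            env_rows.append(
                (
                    sid,
                    env_values[r],                                   # trophic state
                    8.0 + 4.0 * (season == "dry") + 0.5 * r
                    + rng_env.normal(0, 0.2),                        # residence time
                    24.0 + 3.0 * (season == "rainy")
                    + rng_env.normal(0, 0.3),                        # temperature
                    6.0 + 1.2 * env_values[r] + rng_env.normal(0, 0.2),   # DOC
                    2.0 + 0.6 * env_values[r] + rng_env.normal(0, 0.1),   # total N
                )
            )
        process = "selection" if season == "dry" else "homogenizing_dispersal"
        for ra, rb in zip(reservoirs[:-1], reservoirs[1:]):
            truth_rows.append(
                {
                    "event": event,
                    "season": season,
                    "sample_a": f"{ra}_{event}",
                    "sample_b": f"{rb}_{event}",
                    "process": process,
                }
            )

    table = OtuTable(ids, taxa, np.array(rows, dtype=float))
    metadata = SampleMetadata(
        pd.DataFrame(
            [r[1:] for r in meta_rows],
            columns=["reservoir", "season", "event", "subcommunity"],
            index=pd.Index([r[0] for r in meta_rows], name="sample_id"),
        )
    )
    env = pd.DataFrame(
        [r[1:] for r in env_rows],
        columns=["trophic_state", "residence_time", "temperature", "DOC", "total_nitrogen"],
        index=pd.Index([r[0] for r in env_rows], name="sample_id"),
    )
    truth = pd.DataFrame(truth_rows)
    return SyntheticDataset(tree, traits, table, metadata, truth, env=env)
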